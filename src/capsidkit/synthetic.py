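"""Synthetic fixtures with the statistical structure each analysis assumes.

Every generator is deterministic under a fixed seed and returns the ground
truth alongside the data, so downstream recovery (ring partitions, planted
cleavage sites, gel calibration coefficients, rigid transforms) can be tested
without any external downloads.  Noise is isotropic Gaussian throughout, and
random protein sequences are uniform over the 20 standard residues — the
contracts under test do not depend on residue composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    CapsomerLattice3D,
    DEFAULT_LATTICE_CONSTANT,
    build_prolate_lattice,
)
from .lattice import LatticeVectors
from .masses import AVERAGE_RESIDUE_MASSES, ProteinRecord, average_mass
from .superpose import ChainModel

__all__ = [
    "NoisyLattice",
    "PlantedCleavage",
    "GelLadder",
    "PerturbedStructure",
    "gen_noisy_lattice",
    "gen_protein_with_cleavage",
    "gen_gel_ladder",
    "gen_perturbed_structure",
    "random_chain",
]

_AA = "".join(sorted(AVERAGE_RESIDUE_MASSES))


@dataclass(frozen=True)
class NoisyLattice:
    points: np.ndarray  # displaced capsomer centers, (n, 3)
    kinds: tuple[str, ...]
    truth: CapsomerLattice3D
    sigma: float
    seed: int

    def displaced_lattice(self) -> CapsomerLattice3D:
        """Ground-truth lattice with centers replaced by the noisy cloud."""
        from dataclasses import replace

        caps = [
            replace(c, center=self.points[i])
            for i, c in enumerate(sorted(self.truth.capsomers, key=lambda cc: cc.id))
        ]
        return CapsomerLattice3D(
            architecture=self.truth.architecture,
            capsomers=caps,
            edges=set(self.truth.edges),
            lattice_constant=self.truth.lattice_constant,
            axis=self.truth.axis.copy(),
        )


def gen_noisy_lattice(
    v: LatticeVectors,
    sigma: float,
    seed: int,
    lattice_constant: float = DEFAULT_LATTICE_CONSTANT,
    portal: bool = False,
) -> NoisyLattice:
    """Ideal capsomer centers displaced by isotropic Gaussian noise.

    Stands in for capsomer positions measured from a cryo-EM map; labels and
    the ideal lattice are retained as ground truth.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lat = build_prolate_lattice(v, lattice_constant=lattice_constant, portal=portal)
    rng = np.random.default_rng(seed)
    caps = sorted(lat.capsomers, key=lambda c: c.id)
    pts = np.array([c.center for c in caps])
    pts = pts + rng.normal(0.0, sigma, size=pts.shape) if sigma > 0 else pts
    return NoisyLattice(
        points=pts,
        kinds=tuple(c.kind for c in caps),
        truth=lat,
        sigma=sigma,
        seed=seed,
    )


@dataclass(frozen=True)
class PlantedCleavage:
    protein: ProteinRecord
    cleavage_after: int  # delta domain = 1..cleavage_after
    observed_mass: float  # fragment (cleavage_after+1 .. length), with error
    true_fragment_mass: float
    mass_error_sigma: float
    seed: int


def gen_protein_with_cleavage(
    length: int,
    cleavage_after: int,
    seed: int,
    mass_error_sigma: float = 0.0,
) -> PlantedCleavage:
    """Random protein with a planted N-terminal cleavage site.

    The observed mass is the average mass of the C-terminal fragment
    starting at ``cleavage_after + 1``, optionally blurred with Gaussian
    measurement error.
    """
    if not (1 <= cleavage_after < length):
        raise ValueError("cleavage_after must satisfy 1 <= cleavage_after < length")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA), size=length))
    protein = ProteinRecord(id=f"synthetic-{seed}", sequence=seq)
    frag = average_mass(seq[cleavage_after:])
    observed = frag + (rng.normal(0.0, mass_error_sigma) if mass_error_sigma > 0 else 0.0)
    return PlantedCleavage(
        protein=protein,
        cleavage_after=cleavage_after,
        observed_mass=float(observed),
        true_fragment_mass=float(frag),
        mass_error_sigma=mass_error_sigma,
        seed=seed,
    )


@dataclass(frozen=True)
class GelLadder:
    marker_mw_kda: np.ndarray
    marker_distance: np.ndarray
    true_coefficients: np.ndarray  # quadratic in distance, highest power first
    noise_sigma: float
    seed: int


def gen_gel_ladder(
    coefficients,
    marker_mw_kda,
    noise_sigma: float,
    seed: int,
) -> GelLadder:
    """Marker ladder lying on a known quadratic log10(MW) = poly(distance).

    Distances are obtained by inverting the quadratic over its monotone
    branch, then blurred with Gaussian migration error of ``noise_sigma``.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.shape != (3,):
        raise ValueError("coefficients must be a quadratic (3 values)")
    mw = np.asarray(marker_mw_kda, dtype=float)
    y = np.log10(mw)
    a, b, c = coeffs
    disc = b * b - 4.0 * a * (c - y)
    if np.any(disc < 0):
        raise ValueError("marker MW outside the range of the quadratic")
    # monotone branch: larger proteins migrate less far
    dist = (-b - np.sqrt(disc)) / (2.0 * a)
    if np.any(dist < 0) or not np.all(np.isfinite(dist)):
        raise ValueError("marker MW outside the range of the quadratic")
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        dist = dist + rng.normal(0.0, noise_sigma, size=dist.shape)
    return GelLadder(
        marker_mw_kda=mw,
        marker_distance=dist,
        true_coefficients=coeffs,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass(frozen=True)
class PerturbedStructure:
    moving: ChainModel
    target: ChainModel  # rotation @ moving + translation (+ noise)
    rotation: np.ndarray
    translation: np.ndarray
    noise_sigma: float
    seed: int


def random_chain(n: int, seed: int, spread: float = 20.0) -> ChainModel:
    """Random compact chain model with ``n`` residues."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, spread / 3.0, size=(n, 3))
    seq = "".join(rng.choice(list(_AA), size=n))
    return ChainModel(
        chain_id="X",
        residue_numbers=tuple(range(1, n + 1)),
        residue_names=seq,
        coords=coords,
    )


def gen_perturbed_structure(
    chain: ChainModel,
    rotation,
    translation,
    noise_sigma: float,
    seed: int,
) -> PerturbedStructure:
    """Copy of ``chain`` moved by a known rigid transform plus noise.

    The rotation must be proper (orthogonal, determinant +1).
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (reflection) rejected")
    rng = np.random.default_rng(seed)
    moved = chain.coords @ R.T + t
    if noise_sigma > 0:
        moved = moved + rng.normal(0.0, noise_sigma, size=moved.shape)
    target = ChainModel(
        chain_id=chain.chain_id,
        residue_numbers=chain.residue_numbers,
        residue_names=chain.residue_names,
        coords=moved,
    )
    return PerturbedStructure(
        moving=chain,
        target=target,
        rotation=R,
        translation=t,
        noise_sigma=noise_sigma,
        seed=seed,
    )
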
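"""Sequence-guided rigid-body superposition and RMSD reporting.

Compares capsid-protein subunits (e.g. CP against its homolog Ccm, or the
quasi-equivalent hexamer subunits of one shell): a global sequence alignment
pairs up residues, a Kabsch least-squares fit superposes their representative
(alpha-carbon) coordinates, and an iterative trimming step isolates the rigid
core — homologous capsid proteins typically superpose to ~1 A over their
common core while diverging by an order of magnitude when flexible arms and
loops are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ChainModel",
    "SuperpositionResult",
    "align_sequences",
    "AlignmentResult",
    "superpose",
    "core_rmsd",
    "chain_from_structure",
    "kabsch",
]


@dataclass(frozen=True)
class ChainModel:
    """Ordered representative-atom trace of one protein chain."""

    chain_id: str
    residue_numbers: tuple[int, ...]
    residue_names: str  # one-letter codes, aligned with residue_numbers
    coords: np.ndarray  # (n, 3) angstrom

    def __post_init__(self) -> None:
        if len(self.residue_numbers) != len(self.coords) or len(
            self.residue_names
        ) != len(self.coords):
            raise ValueError("residue numbering, names and coordinates disagree")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class AlignmentResult:
    pairs: tuple[tuple[int, int], ...]  # matched (index_a, index_b), 0-based
    identity: float  # matches / aligned (non-gap) columns
    aligned_columns: int


def align_sequences(a: str, b: str) -> AlignmentResult:
    """Global alignment with affine gaps (BLOSUM62, open 11, extend 1).

    Identity is matches over aligned (non-gap) columns; note this value is
    denominator-sensitive, so homolog identities quoted elsewhere may differ
    by a few points depending on convention.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            ia, ib = sa + off, sb + off
            pairs.append((ia, ib))
            if a[ia] == b[ib]:
                matches += 1
    if not pairs:
        raise ValueError("alignment produced no aligned columns")
    return AlignmentResult(
        pairs=tuple(pairs),
        identity=matches / len(pairs),
        aligned_columns=len(pairs),
    )


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3,3) proper rotation applied to A
    translation: np.ndarray  # (3,)
    matched_pairs: tuple[tuple[int, int], ...]  # residue-number pairs
    rmsd_all: float
    rmsd_core: float
    core_pairs: tuple[tuple[int, int], ...]


def kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit mapping point set A onto B.

    Returns (R, t, rmsd) with ``B ~ R @ A + t``, R a proper rotation
    (SVD with determinant correction).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = len(A)
    if n < 3:
        raise ValueError("rigid fit needs at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-9 * max(1.0, np.abs(A0).max())) < 2:
        raise ValueError("degenerate (collinear or coincident) configuration")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def superpose(
    a: ChainModel,
    b: ChainModel,
    pairs: tuple[tuple[int, int], ...] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of chain A onto chain B.

    ``pairs`` are (residue_number_a, residue_number_b) correspondences; by
    default residues are paired through a global sequence alignment of the
    two chains.  The core fields are initialised to the all-pair fit; run
    :func:`core_rmsd` to trim to the rigid core.
    """
    if pairs is None:
        aln = align_sequences(a.residue_names, b.residue_names)
        pairs = tuple(
            (a.residue_numbers[ia], b.residue_numbers[ib]) for ia, ib in aln.pairs
        )
    index_a = {rn: i for i, rn in enumerate(a.residue_numbers)}
    index_b = {rn: i for i, rn in enumerate(b.residue_numbers)}
    try:
        A = np.array([a.coords[index_a[ra]] for ra, _ in pairs])
        B = np.array([b.coords[index_b[rb]] for _, rb in pairs])
    except KeyError as exc:
        raise ValueError(f"pair references unknown residue number {exc}") from None
    R, t, rmsd = kabsch(A, B)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        matched_pairs=tuple(pairs),
        rmsd_all=rmsd,
        rmsd_core=rmsd,
        core_pairs=tuple(pairs),
    )


def core_rmsd(
    a: ChainModel,
    b: ChainModel,
    result: SuperpositionResult,
    cutoff: float = 3.8,
    max_iter: int = 10,
) -> SuperpositionResult:
    """Iteratively trim deviating pairs and refit on the survivors.

    Pairs deviating more than ``cutoff`` (A) under the current transform are
    discarded; to keep a grossly displaced domain from dragging the initial
    fit (where every pair can exceed the cutoff at once), at most the worst
    quartile is dropped per round.  Stops when the core is stable or after
    ``max_iter`` rounds; the final transform comes from the core pairs, and
    both core and all-pair RMSD are reported under that single transform.
    Raises if the core collapses below 3 pairs.
    """
    index_a = {rn: i for i, rn in enumerate(a.residue_numbers)}
    index_b = {rn: i for i, rn in enumerate(b.residue_numbers)}
    all_pairs = result.matched_pairs
    A_all = np.array([a.coords[index_a[ra]] for ra, _ in all_pairs])
    B_all = np.array([b.coords[index_b[rb]] for _, rb in all_pairs])

    core = list(range(len(all_pairs)))
    R, t = result.rotation, result.translation
    # shrink phase: drop at most the worst quartile per round
    for _ in range(max_iter):
        dev = np.linalg.norm((A_all @ R.T + t) - B_all, axis=1)
        threshold = max(cutoff, float(np.percentile(dev[core], 75.0)))
        keep = [i for i in core if dev[i] <= threshold]
        if len(keep) < 3:
            raise ValueError("core collapsed below 3 pairs")
        if keep == core and all(dev[i] <= cutoff for i in core):
            break
        core = keep
        R, t, _ = kabsch(A_all[core], B_all[core])
    # fixed-point phase: under the converged transform the core is exactly
    # the pairs within the cutoff (re-admitting any dropped early)
    for _ in range(max_iter):
        dev = np.linalg.norm((A_all @ R.T + t) - B_all, axis=1)
        keep = [i for i in range(len(all_pairs)) if dev[i] <= cutoff]
        if len(keep) < 3:
            raise ValueError("core collapsed below 3 pairs")
        if keep == core:
            break
        core = keep
        R, t, _ = kabsch(A_all[core], B_all[core])

    diff_all = (A_all @ R.T + t) - B_all
    diff_core = diff_all[core]
    rmsd_all = float(np.sqrt((diff_all**2).sum() / len(all_pairs)))
    rmsd_core = float(np.sqrt((diff_core**2).sum() / len(core)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        matched_pairs=all_pairs,
        rmsd_all=rmsd_all,
        rmsd_core=rmsd_core,
        core_pairs=tuple(all_pairs[i] for i in core),
    )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def chain_from_structure(
    path: str | Path,
    chain_id: str,
    representative_atom: str = "CA",
) -> ChainModel:
    """Extract one chain's representative-atom trace from a PDB/mmCIF file.

    Residues are matched by author numbering; non-standard residues and
    residues lacking the representative atom are skipped.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    for chain in model:
        if chain.name != chain_id:
            continue
        numbers, names, coords = [], [], []
        for res in chain:
            one = _THREE_TO_ONE.get(res.name)
            if one is None:
                continue
            atom = res.find_atom(representative_atom, "*")
            if atom is None:
                continue
            numbers.append(res.seqid.num)
            names.append(one)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not numbers:
            raise ValueError(f"chain {chain_id!r} has no usable residues")
        return ChainModel(
            chain_id=chain_id,
            residue_numbers=tuple(numbers),
            residue_names="".join(names),
            coords=np.array(coords),
        )
    raise ValueError(f"chain {chain_id!r} not found in {path}")
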
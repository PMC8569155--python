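"""Intact-mass arithmetic, cleavage-site mapping and gel MW calibration.

HK97-like capsid proteins carry an N-terminal scaffolding (delta) domain that
is proteolytically removed during maturation.  Given a protein sequence and a
deconvoluted ESI-TOF intact mass, the cleavage site is located by scanning
contiguous fragments whose *average* (not monoisotopic) mass matches the
observation; an N-terminal-truncation match directly delimits the delta
domain.  Apparent molecular weights on SDS-PAGE gels are calibrated with a
second-order polynomial of marker migration distance against log10 of marker
molecular weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "WATER_MASS",
    "AVERAGE_RESIDUE_MASSES",
    "ProteinRecord",
    "CleavageMatch",
    "GelCalibration",
    "average_mass",
    "match_cleavage",
    "delta_domain_report",
    "gel_calibrate",
    "apparent_mw",
    "read_fasta",
]

#: Average mass of one water molecule (Da), pinned from the element table so
#: that peptide-bond additivity mass(AB) = mass(A) + mass(B) - WATER_MASS is
#: exact.
WATER_MASS = float(_pmass.calculate_mass(formula="H2O", average=True))

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue (water-free) masses in Da for the 20 standard amino acids.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    aa: float(_pmass.calculate_mass(sequence=aa, average=True)) - WATER_MASS
    for aa in _STANDARD_AA
}


def average_mass(sequence: str) -> float:
    """Average molecular mass of an unmodified peptide (Da).

    Sum of standard average residue masses plus one water; cysteines are
    taken as reduced, no modifications are applied.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in sequence:
        try:
            total += AVERAGE_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None
    return total


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue numbering."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(_STANDARD_AA)
        if bad:
            raise ValueError(f"non-standard residues in {self.id}: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def full_mass(self) -> float:
        return average_mass(self.sequence)

    def fragment_mass(self, start: int, end: int) -> float:
        """Average mass of residues start..end (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"invalid interval {start}..{end}")
        return average_mass(self.sequence[start - 1 : end])


@dataclass(frozen=True)
class CleavageMatch:
    start: int  # 1-based inclusive
    end: int
    calc_mass: float
    delta: float  # calculated - observed
    site_label: str


def _site_label(protein: ProteinRecord, start: int, end: int) -> str:
    seq = protein.sequence
    parts = []
    if start > 1:
        parts.append(f"between {seq[start - 2]}{start - 1} and {seq[start - 1]}{start}")
    else:
        parts.append("intact N-terminus")
    if end < len(seq):
        parts.append(f"between {seq[end - 1]}{end} and {seq[end]}{end + 1}")
    return "; ".join(parts)


def match_cleavage(
    protein: ProteinRecord,
    observed: float,
    tolerance: float = 2.0,
    mode: str = "n_truncation",
) -> list[CleavageMatch]:
    """Contiguous fragments whose average mass matches an observed intact mass.

    Modes: ``n_truncation`` (fragment retains the C-terminus — the delta
    domain case), ``c_truncation`` (retains the N-terminus), and
    ``any_contiguous``.  Matches are sorted by absolute mass error; an empty
    list means nothing within tolerance.  The default +-2 Da tolerance suits
    deconvoluted ESI-TOF intact masses of ~30 kDa proteins.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in ("n_truncation", "c_truncation", "any_contiguous"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(protein)
    residue = np.array([AVERAGE_RESIDUE_MASSES[aa] for aa in protein.sequence])
    prefix = np.concatenate([[0.0], np.cumsum(residue)])  # prefix[i] = mass of 1..i

    matches: list[CleavageMatch] = []

    def consider(start: int, end: int) -> None:
        calc = prefix[end] - prefix[start - 1] + WATER_MASS
        delta = calc - observed
        if abs(delta) <= tolerance:
            matches.append(
                CleavageMatch(
                    start=start,
                    end=end,
                    calc_mass=float(calc),
                    delta=float(delta),
                    site_label=_site_label(protein, start, end),
                )
            )

    if mode == "n_truncation":
        for start in range(1, n + 1):
            consider(start, n)
    elif mode == "c_truncation":
        for end in range(1, n + 1):
            consider(1, end)
    else:
        # vectorised scan over all O(n^2) contiguous fragments
        for start in range(1, n + 1):
            calc = prefix[start:] - prefix[start - 1] + WATER_MASS
            hits = np.nonzero(np.abs(calc - observed) <= tolerance)[0]
            for off in hits:
                consider(start, start + int(off))

    matches.sort(key=lambda m: (abs(m.delta), m.start, m.end))
    return matches


@dataclass(frozen=True)
class DomainReport:
    delta_domain: tuple[int, int] | None  # (1, start-1) or None when empty
    mature: tuple[int, int]


def delta_domain_report(protein: ProteinRecord, match: CleavageMatch) -> DomainReport:
    """Split a protein into delta domain and mature region from an
    N-terminal-truncation match.

    A match covering 129..402 of a 402-residue capsid protein puts the delta
    domain at residues 1..128.
    """
    if match.end != len(protein):
        raise ValueError(
            "delta-domain mapping requires an N-terminal truncation match "
            f"(fragment must end at residue {len(protein)}, got {match.end})"
        )
    delta = (1, match.start - 1) if match.start > 1 else None
    return DomainReport(delta_domain=delta, mature=(match.start, match.end))


# ---------------------------------------------------------------------------
# SDS-PAGE calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GelCalibration:
    """Quadratic fit of log10(MW / kDa) against marker migration distance."""

    marker_mw_kda: np.ndarray
    marker_distance: np.ndarray
    coefficients: np.ndarray  # highest power first, as numpy.polyval expects
    residuals: np.ndarray  # per-marker residual in log10(MW)


def gel_calibrate(
    marker_mw_kda,
    marker_distance,
) -> GelCalibration:
    """Least-squares second-order polynomial calibration of a marker ladder.

    Markers lying exactly on a quadratic are recovered to numerical
    precision.  Non-monotone ladders are accepted with a warning (a valid gel
    migrates small proteins further).
    """
    mw = np.asarray(marker_mw_kda, dtype=float)
    dist = np.asarray(marker_distance, dtype=float)
    if mw.shape != dist.shape or mw.ndim != 1:
        raise ValueError("marker arrays must be 1-D and the same length")
    if len(mw) < 3:
        raise ValueError("gel calibration needs at least 3 markers")
    if len(np.unique(dist)) != len(dist):
        raise ValueError("marker migration distances must be distinct")
    order = np.argsort(dist)
    if not np.all(np.diff(mw[order]) < 0):
        warnings.warn(
            "marker MW is not strictly decreasing with distance; "
            "calibration may be degenerate",
            stacklevel=2,
        )
    coeffs = np.polyfit(dist, np.log10(mw), 2)
    resid = np.polyval(coeffs, dist) - np.log10(mw)
    return GelCalibration(
        marker_mw_kda=mw,
        marker_distance=dist,
        coefficients=coeffs,
        residuals=resid,
    )


def apparent_mw(cal: GelCalibration, distance) -> np.ndarray | float:
    """Apparent molecular weight (kDa) of a band at a migration distance."""
    d = np.asarray(distance, dtype=float)
    out = 10.0 ** np.polyval(cal.coefficients, d)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
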
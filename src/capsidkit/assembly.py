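"""Stochastic simulator of the pentamer-species capsid assembly decision.

Helper-phage capsid assembly nucleates on the portal with a first shell of
capsid-protein (CP) hexamers.  The pirate element contributes Ccm, a CP
homolog that occupies pentamer positions: when Ccm pentamers join the
nucleus the shell closes as a small isometric T=4 capsid, whereas CP
pentamers allow the cylindrical midsection to grow, yielding the prolate
T_end=4 / T_mid=14 head.  Intermediate sizes are essentially never observed,
so the decision is modelled as a strict either/or choice.

The model draws the species at each pentamer site as an independent
Bernoulli variable with odds ``rho_ccm`` (Ccm incorporation propensity
relative to CP).  Two commitment rules map the draws to a shape:

``first_site``
    the first pentamer to join commits the pathway; all later pentamers
    follow its species (strict either/or, the default);
``unanimous_ring``
    the five pentamer sites of the first ring draw independently; a
    unanimous ring commits to the corresponding shape, a mixed ring stalls
    as an aberrant (incomplete) particle.

The model is deliberately agnostic about whether capsomers pre-form in
solution; it encodes only the decision structure, with no kinetics.
Subunit compositions of completed capsids come from the lattice census:
isometric = (2,0) T=4, prolate = (2,0)/(7,0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeVectors, architecture_counts

__all__ = [
    "AssemblyParams",
    "AssemblyOutcome",
    "simulate_assembly",
    "analytic_fractions",
    "analytic_isometric_fraction",
    "outcome_summary",
]

_SHAPES = ("isometric", "prolate", "aberrant")


@dataclass(frozen=True)
class AssemblyParams:
    """Parameters of one simulation run.

    rho_ccm is the relative propensity of Ccm over CP at a pentamer site
    (0 = CP only, math.inf = Ccm only); there is no measured biological
    value for it.  With a portal the shell offers 11 pentamer sites,
    without (portal-free isometric nucleation) 12.
    """

    rho_ccm: float = 1.0
    portal_nucleation: bool = True
    commitment: str = "first_site"
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rho_ccm >= 0):  # also rejects NaN
            raise ValueError("rho_ccm must be non-negative")
        if self.commitment not in ("first_site", "unanimous_ring"):
            raise ValueError(f"unknown commitment rule {self.commitment!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def p_ccm(self) -> float:
        """Per-site probability of drawing Ccm."""
        if math.isinf(self.rho_ccm):
            return 1.0
        return self.rho_ccm / (1.0 + self.rho_ccm)


@dataclass(frozen=True)
class AssemblyOutcome:
    shape: str  # isometric / prolate / aberrant
    cp_copies: int
    ccm_copies: int
    pentamer_species: tuple[str, ...]
    rings_built: int


def _census(portal: bool) -> dict[str, tuple[int, int, int]]:
    """(pentamer sites, CP copies, Ccm copies per all-Ccm pentamer case)."""
    iso = architecture_counts(LatticeVectors.isometric(2, 0), has_portal=portal)
    pro = architecture_counts(LatticeVectors(2, 0, 7, 0), has_portal=portal)
    return {
        # isometric capsid with Ccm pentamers and CP hexamers
        "isometric": (iso.pentamer_sites, 6 * iso.hexamer_count, 5 * iso.pentamer_sites),
        # prolate capsid made of CP throughout
        "prolate": (pro.pentamer_sites, pro.cp_equivalent_subunits, 0),
    }


def simulate_assembly(p: AssemblyParams) -> list[AssemblyOutcome]:
    """Run ``p.n_trials`` independent assembly trials.

    One seeded generator per run; species draws are consumed in pentamer
    site order, so identical parameters and seed give identical outcomes.
    """
    rng = np.random.default_rng(p.seed)
    census = _census(p.portal_nucleation)
    n_sites = census["isometric"][0]
    q = p.p_ccm
    draws = rng.random((p.n_trials, n_sites)) < q  # True = Ccm

    outcomes: list[AssemblyOutcome] = []
    nucleus_cp = 5 * 6  # five CP hexamers around the nucleation site
    for trial in range(p.n_trials):
        if p.commitment == "first_site":
            committed = "ccm" if draws[trial, 0] else "cp"
            shape = "isometric" if committed == "ccm" else "prolate"
            sites, cp, ccm = census[shape]
            if committed == "cp":
                species = ("cp",) * sites
            else:
                species = ("ccm",) * sites
            outcomes.append(
                AssemblyOutcome(
                    shape=shape,
                    cp_copies=cp,
                    ccm_copies=ccm,
                    pentamer_species=species,
                    rings_built=2,
                )
            )
        else:  # unanimous_ring
            ring = draws[trial, :5]
            if ring.all():
                sites, cp, ccm = census["isometric"]
                outcomes.append(
                    AssemblyOutcome(
                        shape="isometric",
                        cp_copies=cp,
                        ccm_copies=ccm,
                        pentamer_species=("ccm",) * sites,
                        rings_built=2,
                    )
                )
            elif not ring.any():
                sites, cp, ccm = census["prolate"]
                outcomes.append(
                    AssemblyOutcome(
                        shape="prolate",
                        cp_copies=cp,
                        ccm_copies=ccm,
                        pentamer_species=("cp",) * sites,
                        rings_built=2,
                    )
                )
            else:
                species = tuple("ccm" if x else "cp" for x in ring)
                n_ccm = int(ring.sum())
                outcomes.append(
                    AssemblyOutcome(
                        shape="aberrant",
                        cp_copies=nucleus_cp + 5 * (5 - n_ccm),
                        ccm_copies=5 * n_ccm,
                        pentamer_species=species,
                        rings_built=1,
                    )
                )
    return outcomes


def analytic_fractions(p: AssemblyParams) -> dict[str, float]:
    """Closed-form outcome probabilities under the commitment rule.

    first_site: P(isometric) = q where q = rho/(1+rho).
    unanimous_ring: P(isometric) = q^5, P(prolate) = (1-q)^5, the rest
    aberrant (mixed first ring).
    """
    q = p.p_ccm
    if p.commitment == "first_site":
        return {"isometric": q, "prolate": 1.0 - q, "aberrant": 0.0}
    iso = q**5
    pro = (1.0 - q) ** 5
    return {"isometric": iso, "prolate": pro, "aberrant": 1.0 - iso - pro}


def analytic_isometric_fraction(p: AssemblyParams) -> float:
    """Exact probability that one trial yields an isometric capsid."""
    return analytic_fractions(p)["isometric"]


def outcome_summary(outcomes: list[AssemblyOutcome]) -> pd.DataFrame:
    """Shape fractions with Wilson 95% confidence intervals and mean
    compositions, one row per shape class."""
    from statsmodels.stats.proportion import proportion_confint

    if not outcomes:
        raise ValueError("empty outcome list")
    n = len(outcomes)
    rows = []
    for shape in _SHAPES:
        sub = [o for o in outcomes if o.shape == shape]
        count = len(sub)
        lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "shape": shape,
                "count": count,
                "fraction": count / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "mean_cp_copies": float(np.mean([o.cp_copies for o in sub])) if sub else np.nan,
                "mean_ccm_copies": float(np.mean([o.ccm_copies for o in sub])) if sub else np.nan,
            }
        )
    return pd.DataFrame(rows)
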
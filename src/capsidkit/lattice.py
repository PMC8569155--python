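"""Integer lattice accounting for quasi-equivalent icosahedral and prolate capsids.

A Caspar-Klug icosahedral shell is classified by the triangulation number
``T = h^2 + hk + k^2`` of its cap vector ``(h, k)``; it contains ``60*T``
subunits arranged as 12 pentamers and ``10*(T - 1)`` hexamers.  A prolate
(5-fold elongated) shell has icosahedral end caps described by ``(h1, k1)``
and a cylindrical midsection described by a second vector ``(h2, k2)``; its
midsection triangulation number (also called Q) is
``T_mid = h1*h2 + h1*k2 + h2*k1 + k1*k2`` and the full shell holds
``30*(T_end + T_mid)`` subunits.  In tailed phages one 5-fold vertex is
usually occupied by the portal ring instead of a pentamer, removing five
capsid-protein copies from the census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "LatticeVectors",
    "CapsidArchitecture",
    "t_number",
    "q_number",
    "architecture_counts",
    "enumerate_architectures",
]


def t_number(h: int, k: int) -> int:
    """Triangulation number ``T = h^2 + h*k + k^2`` of a lattice vector.

    Parameters
    ----------
    h, k
        Non-negative integers, not both zero.
    """
    _check_vector(h, k)
    return h * h + h * k + k * k


def _check_vector(h: int, k: int) -> None:
    if not (isinstance(h, (int,)) and isinstance(k, (int,))):
        raise TypeError(f"lattice indices must be integers, got ({h!r}, {k!r})")
    if h < 0 or k < 0:
        raise ValueError(f"lattice indices must be non-negative, got ({h}, {k})")
    if h == 0 and k == 0:
        raise ValueError("lattice vector (0, 0) is degenerate")


@dataclass(frozen=True)
class LatticeVectors:
    """Cap vector ``(h1, k1)`` and midsection vector ``(h2, k2)``.

    For an isometric shell the midsection vector equals the cap vector.
    """

    h1: int
    k1: int
    h2: int
    k2: int

    def __post_init__(self) -> None:
        _check_vector(self.h1, self.k1)
        _check_vector(self.h2, self.k2)

    @classmethod
    def isometric(cls, h: int, k: int) -> "LatticeVectors":
        return cls(h, k, h, k)

    @property
    def is_isometric(self) -> bool:
        return (self.h2, self.k2) == (self.h1, self.k1)

    @property
    def t_end(self) -> int:
        return t_number(self.h1, self.k1)

    @property
    def t_mid(self) -> int:
        return q_number(self)


def q_number(v: LatticeVectors) -> int:
    """Midsection triangulation number ``Q = h1*h2 + h1*k2 + h2*k1 + k1*k2``.

    Equals ``t_number(h1, k1)`` when the two vectors coincide, and factorises
    as ``(h1 + k1) * (h2 + k2)`` for the 5-fold prolate geometry.
    """
    return v.h1 * v.h2 + v.h1 * v.k2 + v.h2 * v.k1 + v.k1 * v.k2


@dataclass(frozen=True)
class CapsidArchitecture:
    """Capsomer and subunit census of one capsid architecture."""

    vectors: LatticeVectors
    t_end: int
    t_mid: int
    shape: str  # "isometric" or "prolate"
    has_portal: bool
    pentamer_sites: int
    hexamer_count: int
    cp_equivalent_subunits: int

    @property
    def fivefold_sites(self) -> int:
        """Pentamer sites plus the portal site; always 12 on a closed shell."""
        return self.pentamer_sites + (1 if self.has_portal else 0)


def architecture_counts(v: LatticeVectors, has_portal: bool = False) -> CapsidArchitecture:
    """Fill the capsomer/subunit census for a lattice-vector pair.

    The portal occupies one 5-fold site and contributes no capsid-protein
    copies, so the portal-bearing prolate phi12 shell (cap (2,0), midsection
    (7,0)) counts ``30*(4+14) - 5 = 535`` CP copies in 80 hexamers and 11
    pentamers.

    An isometric shell (midsection vector equal to the cap vector) is a
    plain T shell with ``60*T`` subunits, so its census uses
    ``t_mid = t_end``.  Note the four-term Q formula itself reduces to T
    only for achiral vectors (k = 0): it factorises as
    ``(h1 + k1) * (h2 + k2)``, which for equal chiral vectors gives
    ``(h + k)^2`` rather than ``h^2 + hk + k^2``.
    """
    t_end = v.t_end
    t_mid = t_end if v.is_isometric else q_number(v)
    if t_mid < t_end:
        raise ValueError(
            f"midsection number Q={t_mid} smaller than cap number T={t_end}; "
            "a prolate shell requires t_mid >= t_end"
        )
    shape = "isometric" if v.is_isometric else "prolate"
    pentamer_sites = 12 - (1 if has_portal else 0)
    hexamer_count = 5 * (t_end + t_mid) - 10
    cp_equivalent = 5 * pentamer_sites + 6 * hexamer_count
    return CapsidArchitecture(
        vectors=v,
        t_end=t_end,
        t_mid=t_mid,
        shape=shape,
        has_portal=has_portal,
        pentamer_sites=pentamer_sites,
        hexamer_count=hexamer_count,
        cp_equivalent_subunits=cp_equivalent,
    )


def _canonical_vectors(max_component: int) -> Iterator[LatticeVectors]:
    # Canonical orientation: h1 >= k1.  Because Q = (h1+k1)*(h2+k2) for the
    # 5-fold prolate geometry, every midsection vector with the same index sum
    # describes the same tube; emit the canonical (e, 0) representative.
    for h1 in range(0, max_component + 1):
        for k1 in range(0, min(h1, max_component) + 1):
            if h1 == 0 and k1 == 0:
                continue
            for e in range(1, max_component + 1):
                v = LatticeVectors(h1, k1, e, 0)
                if q_number(v) < v.t_end:
                    continue
                yield v


def enumerate_architectures(
    subunits: int | None = None,
    hexamers: int | None = None,
    portal: bool = False,
    max_component: int = 20,
) -> list[CapsidArchitecture]:
    """Inverse problem: which architectures explain an observed census?

    Exactly one of ``subunits`` (capsid-protein copies, portal excluded from
    the count when ``portal=True``) or ``hexamers`` must be given.  Returns
    matches in canonical orientation (``h1 >= k1``, midsection ``(e, 0)``),
    sorted by ``(t_end, t_mid)``; an empty list means no solution.
    """
    if (subunits is None) == (hexamers is None):
        raise ValueError("give exactly one of subunits= or hexamers=")
    target = subunits if subunits is not None else hexamers
    if target is None or target <= 0:
        raise ValueError("constraint value must be positive")

    out = []
    for v in _canonical_vectors(max_component):
        arch = architecture_counts(v, has_portal=portal)
        if subunits is not None and arch.cp_equivalent_subunits == subunits:
            out.append(arch)
        elif hexamers is not None and arch.hexamer_count == hexamers:
            out.append(arch)
    out.sort(key=lambda a: (a.t_end, a.t_mid, a.vectors.h1, a.vectors.k1))
    return out
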
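"""Explicit 3D capsomer-center models of isometric and prolate capsid shells.

The model places one point per capsomer (pentamer, hexamer or portal).
Isometric shells are built by laying the hexagonal capsomer lattice over the
20 faces of an icosahedron and projecting radially onto the circumscribed
sphere.  Prolate shells combine two icosahedral end caps (cap vector
``(h1, 0)``) with a cylindrical midsection obtained by rolling the hexagonal
lattice into a tube of ``5*h1`` capsomers per ring; consecutive rings are
offset by half a site spacing, so an achiral tube has helical rise
``a*sqrt(3)/2`` and twist ``360/(10*h1)`` degrees for lattice constant ``a``.

Adjacency between capsomers uses a center-distance cutoff at 1.35 times the
lattice constant (midway between the first and second neighbour shells of the
hexagonal lattice), which reproduces pentamer degree 5 and hexamer degree 6
on every closed shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .lattice import LatticeVectors, CapsidArchitecture, architecture_counts

__all__ = [
    "GeometryError",
    "Capsomer",
    "CapsomerLattice3D",
    "HelicalParams",
    "PentamerPath",
    "DihedralReport",
    "DEFAULT_LATTICE_CONSTANT",
    "build_icosahedral_lattice",
    "build_prolate_lattice",
    "ring_partition",
    "helical_params",
    "shortest_pentamer_path",
    "dihedral_angles",
    "export_lattice",
    "read_lattice_csv",
]

#: Hexamer center-to-center spacing, in angstrom, chosen so that the helical
#: rise a*sqrt(3)/2 of the phi12 midsection evaluates to 96 A.
DEFAULT_LATTICE_CONSTANT = 110.85

#: Adjacency cutoff as a multiple of the lattice constant (midpoint between
#: the first (1.0 a) and second (sqrt(3) a) neighbour shells).
NEIGHBOR_CUTOFF_FACTOR = 1.35

_GOLDEN_CIRCUMRADIUS = math.sin(2 * math.pi / 5)  # circumradius / edge length


class GeometryError(ValueError):
    """Raised for lattice constructions the builder cannot realise."""


@dataclass(frozen=True)
class Capsomer:
    id: int
    kind: str  # "pentamer", "hexamer" or "portal"
    center: np.ndarray  # (3,) angstrom
    normal: np.ndarray  # outward unit vector
    region: str  # "cap_bottom", "cap_top" or "midsection"
    ring_index: int | None = None  # midsection hexamers only


@dataclass
class CapsomerLattice3D:
    architecture: CapsidArchitecture
    capsomers: list[Capsomer]
    edges: set[tuple[int, int]]  # unordered id pairs stored as sorted tuples
    lattice_constant: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for c in self.capsomers:
            g.add_node(c.id, kind=c.kind, region=c.region)
        g.add_edges_from(self.edges)
        return g

    def counts(self) -> dict[str, int]:
        out = {"pentamer": 0, "hexamer": 0, "portal": 0}
        for c in self.capsomers:
            out[c.kind] += 1
        return out

    def by_id(self, cid: int) -> Capsomer:
        return self._index()[cid]

    def _index(self) -> dict[int, Capsomer]:
        return {c.id: c for c in self.capsomers}

    def positions(self) -> np.ndarray:
        return np.array([c.center for c in self.capsomers])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "CapsomerLattice3D":
        """Apply a rigid motion; normals rotate, adjacency is preserved."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("transform requires a proper rotation matrix")
        caps = [
            replace(c, center=R @ c.center + t, normal=R @ c.normal)
            for c in self.capsomers
        ]
        return CapsomerLattice3D(
            architecture=self.architecture,
            capsomers=caps,
            edges=set(self.edges),
            lattice_constant=self.lattice_constant,
            axis=R @ self.axis,
        )


@dataclass(frozen=True)
class HelicalParams:
    rise: float  # angstrom per ring
    twist: float  # degrees per ring, reported in [0, 360/hexamers_per_ring)
    ring_count: int
    hexamers_per_ring: int
    tube_radius: float


@dataclass(frozen=True)
class PentamerPath:
    """Shortest lattice walk between a bottom-cap and a top-cap pentamer.

    ``n_steps`` counts graph edges on the path; ``n_hexamers_between`` counts
    the hexamer nodes strictly between the two pentamer endpoints (always
    ``n_steps - 1`` on a valid shell).
    """

    capsomer_ids: tuple[int, ...]
    n_steps: int
    n_hexamers_between: int


@dataclass(frozen=True)
class DihedralReport:
    per_pentamer: dict[int, tuple[float, ...]]  # pentamer id -> angles (deg)
    mean: float
    std: float

    def pentamer_means(self) -> dict[int, float]:
        return {pid: float(np.mean(a)) for pid, a in self.per_pentamer.items()}


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _hex_cart(i: float, j: float) -> np.ndarray:
    """Hexagonal lattice basis a1=(1,0), a2=(1/2, sqrt(3)/2)."""
    return np.array([i + 0.5 * j, j * math.sqrt(3) / 2.0])


def _face_points(h: int, k: int):
    """Lattice points of the Caspar-Klug face triangle, as barycentric weights.

    The face corners are c1 = (0,0), c2 = h*a1 + k*a2 and c3 = c2 rotated by
    +60 degrees; every hexagonal lattice point whose barycentric coordinates
    lie in [0, 1] belongs to the face.
    """
    c1 = _hex_cart(0, 0)
    c2 = _hex_cart(h, k)
    c3 = _hex_cart(-k, h + k)  # rotation by +60 deg: (h,k) -> (-k, h+k)
    M = np.column_stack([c2 - c1, c3 - c1])
    Minv = np.linalg.inv(M)
    lo = min(0, h, -k) - 1
    hi = max(0, h, -k) + 1
    lo_j = -1
    hi_j = max(0, k, h + k) + 1
    eps = 1e-9
    out = []
    for i in range(lo, hi + 1):
        for j in range(lo_j, hi_j + 1):
            uv = Minv @ (_hex_cart(i, j) - c1)
            w = np.array([1.0 - uv[0] - uv[1], uv[0], uv[1]])
            if np.all(w >= -eps):
                out.append(np.clip(w, 0.0, 1.0))
    return out


def _icosahedron_vertices(radius: float) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Vertices (axis = +z through two opposite vertices) and the 20 faces."""
    verts = [np.array([0.0, 0.0, radius])]
    zr = radius / math.sqrt(5.0)
    rr = 2.0 * radius / math.sqrt(5.0)
    for m in range(5):
        phi = math.radians(72.0 * m)
        verts.append(np.array([rr * math.cos(phi), rr * math.sin(phi), zr]))
    for m in range(5):
        phi = math.radians(36.0 + 72.0 * m)
        verts.append(np.array([rr * math.cos(phi), rr * math.sin(phi), -zr]))
    verts.append(np.array([0.0, 0.0, -radius]))
    faces: list[tuple[int, int, int]] = []
    for m in range(5):
        faces.append((0, 1 + m, 1 + (m + 1) % 5))  # top cap
    for m in range(5):
        faces.append((1 + m, 6 + m, 1 + (m + 1) % 5))  # upper equator
        faces.append((1 + (m + 1) % 5, 6 + m, 6 + (m + 1) % 5))  # lower equator
    for m in range(5):
        faces.append((11, 6 + (m + 1) % 5, 6 + m))  # bottom cap
    return np.array(verts), faces


def _dedupe(points: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge points closer than ``tol``; returns (unique points, labels)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    pairs = tree.query_pairs(tol)
    parent = list(range(len(points)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    labels = np.array([find(i) for i in range(len(points))])
    roots, inverse = np.unique(labels, return_inverse=True)
    uniq = np.array([points[labels == r].mean(axis=0) for r in roots])
    return uniq, inverse


def _sorted_ids(points: np.ndarray, a: float) -> np.ndarray:
    """Deterministic capsomer ordering: ascending z, then azimuth, then radius."""
    z = np.round(points[:, 2] / a, 6)
    az = np.degrees(np.arctan2(points[:, 1], points[:, 0]))
    az = np.round(np.mod(az, 360.0), 4)
    r = np.round(np.hypot(points[:, 0], points[:, 1]) / a, 6)
    az[r < 1e-6] = 0.0
    order = np.lexsort((r, az, z))
    ranks = np.empty(len(points), dtype=int)
    ranks[order] = np.arange(len(points))
    return ranks


def _distance_edges(points: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    return {tuple(sorted(p)) for p in tree.query_pairs(cutoff)}


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_icosahedral_lattice(
    h: int,
    k: int,
    lattice_constant: float = DEFAULT_LATTICE_CONSTANT,
    portal: bool = False,
    neighbor_cutoff_factor: float = NEIGHBOR_CUTOFF_FACTOR,
) -> CapsomerLattice3D:
    """Capsomer-center model of an isometric (h, k) shell.

    Pentamers sit on the 12 icosahedral vertices, hexamers on the remaining
    lattice points, all projected radially onto the circumscribed sphere.
    ``portal=True`` replaces the bottom-vertex (-z) pentamer with the portal.
    """
    v = LatticeVectors.isometric(h, k)
    arch = architecture_counts(v, has_portal=portal)
    a = float(lattice_constant)
    if a <= 0:
        raise ValueError("lattice_constant must be positive")
    edge = a * math.sqrt(arch.t_end)
    radius = _GOLDEN_CIRCUMRADIUS * edge
    verts, faces = _icosahedron_vertices(radius)
    weights = _face_points(h, k)

    raw = []
    for f in faces:
        tri = verts[list(f)]
        for w in weights:
            p = w @ tri
            raw.append(radius * p / np.linalg.norm(p))
    points, _ = _dedupe(np.array(raw), tol=0.25 * a)

    is_vertex = np.zeros(len(points), dtype=bool)
    for vtx in verts:
        d = np.linalg.norm(points - vtx, axis=1)
        is_vertex[np.argmin(d)] = True
    if is_vertex.sum() != 12:
        raise GeometryError("failed to locate the 12 five-fold vertices")

    ids = _sorted_ids(points, a)
    bottom_apex = int(np.argmin(points[:, 2]))
    capsomers = []
    for idx in range(len(points)):
        kind = "hexamer"
        if is_vertex[idx]:
            kind = "portal" if (portal and idx == bottom_apex) else "pentamer"
        c = points[idx]
        capsomers.append(
            Capsomer(
                id=int(ids[idx]),
                kind=kind,
                center=c,
                normal=c / np.linalg.norm(c),
                region="cap_top" if c[2] >= 0 else "cap_bottom",
            )
        )
    capsomers.sort(key=lambda cc: cc.id)
    edges = {
        (int(ids[i]), int(ids[j])) if ids[i] < ids[j] else (int(ids[j]), int(ids[i]))
        for i, j in _distance_edges(points, neighbor_cutoff_factor * a)
    }
    lat = CapsomerLattice3D(arch, capsomers, edges, a)
    _validate_census(lat)
    return lat


def _cap_net(
    h1: int,
    apex_z_sign: int,
    center_z: float,
    radius: float,
    phase_deg: float,
    a: float,
):
    """Points of one end cap: the five apex faces of an (h1, 0) icosahedral
    net, projected onto a sphere of ``radius`` centred on the axis at
    ``center_z``.  Returns (points, is_vertex_flags)."""
    verts, _ = _icosahedron_vertices(radius)
    if apex_z_sign > 0:
        apex = verts[0]
        ring = verts[1:6]
    else:
        apex = verts[11]
        ring = verts[6:11]
    rot = math.radians(phase_deg)
    cz, sz = math.cos(rot), math.sin(rot)
    R = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    apex = R @ apex
    ring = ring @ R.T
    # bottom ring vertices sit at azimuth 36 + 72k in the template; shift so
    # that ring pentamers land on azimuth phase_deg + 72k for either cap
    if apex_z_sign < 0:
        extra = math.radians(-36.0)
        ce, se = math.cos(extra), math.sin(extra)
        Re = np.array([[ce, -se, 0.0], [se, ce, 0.0], [0.0, 0.0, 1.0]])
        apex = Re @ apex
        ring = ring @ Re.T

    weights = _face_points(h1, 0)
    raw = []
    for m in range(5):
        tri = np.array([apex, ring[m], ring[(m + 1) % 5]])
        for w in weights:
            p = w @ tri
            raw.append(radius * p / np.linalg.norm(p))
    points, _ = _dedupe(np.array(raw), tol=0.25 * a)
    vertices = np.vstack([apex, ring])
    is_vertex = np.zeros(len(points), dtype=bool)
    for vtx in vertices:
        d = np.linalg.norm(points - vtx, axis=1)
        is_vertex[np.argmin(d)] = True
    points = points + np.array([0.0, 0.0, center_z])
    return points, is_vertex, np.array([0.0, 0.0, center_z])


def build_prolate_lattice(
    v: LatticeVectors,
    lattice_constant: float = DEFAULT_LATTICE_CONSTANT,
    portal: bool = False,
    neighbor_cutoff_factor: float = NEIGHBOR_CUTOFF_FACTOR,
) -> CapsomerLattice3D:
    """Capsomer-center model of a 5-fold prolate shell.

    Supports achiral end caps (``k1 = 0``).  The midsection depends on the
    two lattice vectors only through ``e = h2 + k2`` (the elongation in
    lattice rows), because ``Q = (h1+k1)*(h2+k2)``; it is realised as
    ``e - 1`` stacked rings of ``5*h1`` hexamers between the two junction
    pentamer rings.  The portal, if requested, replaces the bottom apex.
    """
    if v.k1 != 0:
        raise GeometryError(
            f"cap vector ({v.h1},{v.k1}) not supported: the cap/tube seam is "
            "only constructed for achiral caps (k1 = 0)"
        )
    arch = architecture_counts(v, has_portal=portal)
    a = float(lattice_constant)
    if a <= 0:
        raise ValueError("lattice_constant must be positive")
    h1 = v.h1
    e = v.h2 + v.k2  # junction-to-junction distance in lattice rows
    n_per_row = 5 * h1
    rise = a * math.sqrt(3.0) / 2.0
    site_step = 360.0 / n_per_row  # degrees between sites within a row
    half_step = site_step / 2.0  # azimuthal offset between consecutive rows
    tube_radius = n_per_row * a / (2.0 * math.pi)

    edge = a * math.sqrt(arch.t_end)
    cap_R = _GOLDEN_CIRCUMRADIUS * edge
    ring_z_rel = cap_R / math.sqrt(5.0)
    z_top = e * rise

    def row_phase(j: int) -> float:
        return j * half_step

    # (point, kind, region, ring_index, cap sphere center or None)
    parts: list[tuple[np.ndarray, str, str, int | None, np.ndarray | None]] = []

    bot_pts, bot_isv, bot_center = _cap_net(
        h1, apex_z_sign=-1, center_z=ring_z_rel, radius=cap_R,
        phase_deg=row_phase(0), a=a,
    )
    top_pts, top_isv, top_center = _cap_net(
        h1, apex_z_sign=+1, center_z=z_top - ring_z_rel, radius=cap_R,
        phase_deg=row_phase(e), a=a,
    )

    bottom_apex_idx = int(np.argmin(bot_pts[:, 2]))
    for idx in range(len(bot_pts)):
        if bot_isv[idx]:
            kind = "portal" if (portal and idx == bottom_apex_idx) else "pentamer"
        else:
            kind = "hexamer"
        parts.append((bot_pts[idx], kind, "cap_bottom", None, bot_center))
    for j in range(1, e):
        for m in range(n_per_row):
            phi = math.radians(row_phase(j) + m * site_step)
            p = np.array(
                [tube_radius * math.cos(phi), tube_radius * math.sin(phi), j * rise]
            )
            parts.append((p, "hexamer", "midsection", j - 1, None))
    for idx in range(len(top_pts)):
        kind = "pentamer" if top_isv[idx] else "hexamer"
        parts.append((top_pts[idx], kind, "cap_top", None, top_center))

    points = np.array([p[0] for p in parts])
    ids = _sorted_ids(points, a)
    capsomers = []
    for idx, (p, kind, region, ring, cap_center) in enumerate(parts):
        if region == "midsection":
            n = np.array([p[0], p[1], 0.0])
        else:
            n = p - cap_center
        capsomers.append(
            Capsomer(
                id=int(ids[idx]),
                kind=kind,
                center=p,
                normal=n / np.linalg.norm(n),
                region=region,
                ring_index=ring,
            )
        )
    capsomers.sort(key=lambda cc: cc.id)
    edges = {
        (int(ids[i]), int(ids[j])) if ids[i] < ids[j] else (int(ids[j]), int(ids[i]))
        for i, j in _distance_edges(points, neighbor_cutoff_factor * a)
    }
    lat = CapsomerLattice3D(arch, capsomers, edges, a)
    _validate_census(lat)
    return lat


def _validate_census(lat: CapsomerLattice3D) -> None:
    counts = lat.counts()
    arch = lat.architecture
    if counts["pentamer"] != arch.pentamer_sites:
        raise GeometryError(
            f"pentamer count {counts['pentamer']} != census {arch.pentamer_sites}"
        )
    if counts["hexamer"] != arch.hexamer_count:
        raise GeometryError(
            f"hexamer count {counts['hexamer']} != census {arch.hexamer_count}"
        )
    if counts["portal"] != (1 if arch.has_portal else 0):
        raise GeometryError("portal count does not match architecture")
    if not nx.is_connected(lat.graph()):
        raise GeometryError("capsomer adjacency graph is disconnected")


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def ring_partition(
    lat: CapsomerLattice3D, axial_tolerance_factor: float = 0.25
) -> list[list[int]]:
    """Cluster midsection hexamers into rings by axial coordinate.

    Clusters are split wherever the axial gap exceeds
    ``axial_tolerance_factor`` of the ideal rise; every ring must contain
    exactly ``5*h1`` hexamers or the lattice is considered malformed.
    Works on noisy capsomer clouds as long as the noise is small compared to
    the ring spacing.
    """
    axis = lat.axis / np.linalg.norm(lat.axis)
    mids = [c for c in lat.capsomers if c.region == "midsection" and c.kind == "hexamer"]
    if not mids:
        return []
    rise = lat.lattice_constant * math.sqrt(3.0) / 2.0
    zs = np.array([float(c.center @ axis) for c in mids])
    order = np.argsort(zs, kind="stable")
    rings: list[list[int]] = [[mids[order[0]].id]]
    cluster_z: list[float] = [float(zs[order[0]])]
    for o in order[1:]:
        if zs[o] - np.mean(cluster_z) > axial_tolerance_factor * rise:
            rings.append([])
            cluster_z = []
        rings[-1].append(mids[o].id)
        cluster_z.append(float(zs[o]))
    expected = 5 * lat.architecture.vectors.h1
    for ring in rings:
        if len(ring) != expected:
            raise GeometryError(
                f"ring of size {len(ring)} (expected {expected}); malformed lattice"
            )
    return rings


def helical_params(lat: CapsomerLattice3D) -> HelicalParams:
    """Rise and twist of the midsection helix from the ring structure.

    The twist is the mean azimuthal phase offset between consecutive rings,
    computed from the n-fold circular mean of each ring and reported in
    ``[0, 360/n)`` degrees (an achiral tube gives exactly half the site
    spacing).
    """
    rings = ring_partition(lat)
    if len(rings) < 2:
        raise GeometryError("helical parameters require at least two rings")
    axis = lat.axis / np.linalg.norm(lat.axis)
    idx = lat._index()
    n = len(rings[0])
    period = 360.0 / n
    ring_z = []
    ring_phase = []
    radii = []
    for ring in rings:
        pts = np.array([idx[i].center for i in ring])
        ring_z.append(float(np.mean(pts @ axis)))
        az = np.arctan2(pts[:, 1], pts[:, 0])
        phase = math.degrees(np.angle(np.exp(1j * n * az).mean())) / n
        ring_phase.append(phase)
        radii.append(float(np.mean(np.hypot(pts[:, 0], pts[:, 1]))))
    rises = np.diff(ring_z)
    twists = [
        (ring_phase[i + 1] - ring_phase[i]) % period for i in range(len(rings) - 1)
    ]
    return HelicalParams(
        rise=float(np.mean(rises)),
        twist=float(np.mean(twists)),
        ring_count=len(rings),
        hexamers_per_ring=n,
        tube_radius=float(np.mean(radii)),
    )


def _junction_pentamers(lat: CapsomerLattice3D, region: str) -> list[Capsomer]:
    pents = [c for c in lat.capsomers if c.kind == "pentamer" and c.region == region]
    if not pents:
        return []
    # the apex pentamer sits on the axis; junction pentamers are off-axis
    r = [float(np.hypot(c.center[0], c.center[1])) for c in pents]
    rmax = max(r)
    return [c for c, ri in zip(pents, r) if ri > 0.5 * rmax]


def shortest_pentamer_path(lat: CapsomerLattice3D) -> PentamerPath:
    """BFS shortest path between the closest bottom-cap and top-cap junction
    pentamer pair.

    Ties are broken by the lowest capsomer-id pair.  On the (2,0)/(7,0)
    lattice the walk spans 7 lattice steps and passes 6 hexamers strictly
    between the two pentamers; on the isometric (2,0) shell the equivalent
    walk is 2 steps with a single hexamer between.
    """
    bottoms = _junction_pentamers(lat, "cap_bottom")
    tops = _junction_pentamers(lat, "cap_top")
    if not bottoms or not tops:
        raise GeometryError("lattice lacks junction pentamers at one cap")
    g = lat.graph()
    best: tuple[int, int, int, tuple[int, ...]] | None = None
    for b in sorted(bottoms, key=lambda c: c.id):
        dist = nx.single_source_shortest_path(g, b.id)
        for t in sorted(tops, key=lambda c: c.id):
            path = dist[t.id]
            key = (len(path) - 1, b.id, t.id)
            if best is None or key < best[:3]:
                best = (*key, tuple(path))
    n_steps = best[0]
    path = best[3]
    idx = lat._index()
    between = [idx[i] for i in path[1:-1]]
    if any(c.kind == "pentamer" for c in between):
        raise GeometryError("shortest pentamer path crosses another pentamer")
    return PentamerPath(
        capsomer_ids=path,
        n_steps=n_steps,
        n_hexamers_between=len(between),
    )


def dihedral_angles(lat: CapsomerLattice3D) -> DihedralReport:
    """Interior angle between each pentamer plane and its neighbouring
    hexamer planes, from the stored outward normals.

    Coplanar capsomers report 180 degrees; a sharper fold reports a smaller
    angle.  For the T=1 shell (pentamer planes = faces of the dual
    dodecahedron) every angle equals arccos(-1/sqrt(5)) ~ 116.57 degrees.
    """
    idx = lat._index()
    adj: dict[int, list[int]] = {c.id: [] for c in lat.capsomers}
    for i, j in lat.edges:
        adj[i].append(j)
        adj[j].append(i)
    per: dict[int, tuple[float, ...]] = {}
    allangles = []
    for c in lat.capsomers:
        if c.kind != "pentamer":
            continue
        angles = []
        for nb in sorted(adj[c.id]):
            other = idx[nb]
            if other.kind == "pentamer":
                continue
            n1, n2 = c.normal, other.normal
            if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
                raise GeometryError("degenerate capsomer normal")
            cosang = float(np.clip(n1 @ n2, -1.0, 1.0))
            angles.append(180.0 - math.degrees(math.acos(cosang)))
        per[c.id] = tuple(angles)
        allangles.extend(angles)
    arr = np.array(allangles)
    return DihedralReport(per_pentamer=per, mean=float(arr.mean()), std=float(arr.std()))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "id", "kind", "region", "ring_index",
    "x", "y", "z", "nx", "ny", "nz",
]


def export_lattice(lat: CapsomerLattice3D, path: str | Path, format: str = "csv") -> Path:
    """Write the lattice as CSV (full record) or PDB pseudo-atoms.

    The PDB output holds one HETATM per capsomer with the kind encoded in the
    residue name (PEN/HEX/POR).  Output is bit-stable for fixed input.
    """
    path = Path(path)
    if format == "csv":
        arch = lat.architecture
        header = (
            f"# capsidkit lattice h1={arch.vectors.h1} k1={arch.vectors.k1} "
            f"h2={arch.vectors.h2} k2={arch.vectors.k2} "
            f"portal={int(arch.has_portal)} a={lat.lattice_constant!r}\n"
        )
        rows = []
        for c in sorted(lat.capsomers, key=lambda cc: cc.id):
            rows.append(
                {
                    "id": c.id,
                    "kind": c.kind,
                    "region": c.region,
                    "ring_index": "" if c.ring_index is None else c.ring_index,
                    "x": repr(float(c.center[0])),
                    "y": repr(float(c.center[1])),
                    "z": repr(float(c.center[2])),
                    "nx": repr(float(c.normal[0])),
                    "ny": repr(float(c.normal[1])),
                    "nz": repr(float(c.normal[2])),
                }
            )
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        return path
    if format == "pdb":
        import gemmi

        st = gemmi.Structure()
        st.name = "capsomer lattice"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        resnames = {"pentamer": "PEN", "hexamer": "HEX", "portal": "POR"}
        for c in sorted(lat.capsomers, key=lambda cc: cc.id):
            res = gemmi.Residue()
            res.name = resnames[c.kind]
            res.seqid = gemmi.SeqId(c.id + 1, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "C"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*[float(x) for x in c.center])
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))
        return path
    raise ValueError(f"unknown export format {format!r}")


def read_lattice_csv(path: str | Path) -> CapsomerLattice3D:
    """Read a lattice written by :func:`export_lattice` (CSV round-trip)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# capsidkit lattice"):
        raise ValueError(f"{path} is not a capsidkit lattice CSV")
    meta = dict(tok.split("=", 1) for tok in header.split()[3:])
    v = LatticeVectors(int(meta["h1"]), int(meta["k1"]), int(meta["h2"]), int(meta["k2"]))
    arch = architecture_counts(v, has_portal=bool(int(meta["portal"])))
    a = float(meta["a"])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    capsomers = []
    for _, row in df.iterrows():
        ring = row["ring_index"]
        capsomers.append(
            Capsomer(
                id=int(row["id"]),
                kind=str(row["kind"]),
                center=np.array([row["x"], row["y"], row["z"]], dtype=float),
                normal=np.array([row["nx"], row["ny"], row["nz"]], dtype=float),
                region=str(row["region"]),
                ring_index=None if pd.isna(ring) else int(ring),
            )
        )
    capsomers.sort(key=lambda c: c.id)
    points = np.array([c.center for c in capsomers])
    ids = np.array([c.id for c in capsomers])
    edges = {
        (int(ids[i]), int(ids[j])) if ids[i] < ids[j] else (int(ids[j]), int(ids[i]))
        for i, j in _distance_edges(points, NEIGHBOR_CUTOFF_FACTOR * a)
    }
    lat = CapsomerLattice3D(arch, capsomers, edges, a)
    _validate_census(lat)
    return lat
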
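"""3D capsomer lattice construction, adjacency, rings, paths and dihedrals."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capsidkit.geometry import (
    GeometryError,
    build_icosahedral_lattice,
    build_prolate_lattice,
    dihedral_angles,
    export_lattice,
    helical_params,
    read_lattice_csv,
    ring_partition,
    shortest_pentamer_path,
)
from capsidkit.lattice import LatticeVectors, architecture_counts


def hexamer_only_hexamers(lat):
    idx = {c.id: c for c in lat.capsomers}
    adj = {c.id: set() for c in lat.capsomers}
    for i, j in lat.edges:
        adj[i].add(j)
        adj[j].add(i)
    return [
        c
        for c in lat.capsomers
        if c.kind == "hexamer"
        and all(idx[n].kind == "hexamer" for n in adj[c.id])
    ]


class TestIcosahedral:
    def test_t4_census_and_pentamer_spacing(self, t4_lattice):
        """T=4: 12 pentamers, 30 hexamers; one hexamer between each pentamer pair."""
        assert t4_lattice.counts() == {"pentamer": 12, "hexamer": 30, "portal": 0}
        g = t4_lattice.graph()
        pents = [c.id for c in t4_lattice.capsomers if c.kind == "pentamer"]
        # nearest pentamer pairs (graph distance 2) share exactly one hexamer
        for a in pents:
            near = [
                b for b in pents if b != a
                and nx.shortest_path_length(g, a, b) == 2
            ]
            assert len(near) == 5  # icosahedron edges
            for b in near:
                common = set(g[a]) & set(g[b])
                assert len(common) == 1

    def test_t1_is_dodecahedral(self):
        """The (1,0) shell is 12 pentamers on icosahedron vertices; adjacent
        capsomer planes meet at the dodecahedral dihedral arccos(-1/sqrt(5))."""
        lat = build_icosahedral_lattice(1, 0)
        assert lat.counts() == {"pentamer": 12, "hexamer": 0, "portal": 0}
        g = lat.graph()
        assert all(d == 5 for _, d in g.degree())
        expected = math.degrees(math.acos(-1.0 / math.sqrt(5.0)))
        idx = {c.id: c for c in lat.capsomers}
        for i, j in lat.edges:
            ang = 180.0 - math.degrees(
                math.acos(np.clip(idx[i].normal @ idx[j].normal, -1, 1))
            )
            assert ang == pytest.approx(expected, abs=1e-6)

    def test_portal_occupies_bottom_vertex(self):
        lat = build_icosahedral_lattice(2, 0, portal=True)
        counts = lat.counts()
        assert counts == {"pentamer": 11, "hexamer": 30, "portal": 1}
        portal = [c for c in lat.capsomers if c.kind == "portal"]
        assert len(portal) == 1
        assert portal[0].center[2] == min(c.center[2] for c in lat.capsomers)


class TestProlate:
    def test_phi12_midsection_organisation(self, phi12_lattice):
        """60 midsection hexamers in six rings of ten; 40 with only hexamer
        neighbours; 10 cap hexamers per cap."""
        mids = [
            c for c in phi12_lattice.capsomers
            if c.region == "midsection" and c.kind == "hexamer"
        ]
        assert len(mids) == 60
        rings = ring_partition(phi12_lattice)
        assert len(rings) == 6
        assert all(len(r) == 10 for r in rings)
        assert len(hexamer_only_hexamers(phi12_lattice)) == 40
        for region in ("cap_bottom", "cap_top"):
            caphex = [
                c for c in phi12_lattice.capsomers
                if c.region == region and c.kind == "hexamer"
            ]
            assert len(caphex) == 10

    def test_phi12_helix(self, phi12_lattice):
        """Stacked rings twisted by half a site spacing: twist 18 deg, rise
        a*sqrt(3)/2 (= 96 A for the default lattice constant)."""
        hp = helical_params(phi12_lattice)
        a = phi12_lattice.lattice_constant
        assert hp.hexamers_per_ring == 10
        assert hp.ring_count == 6
        assert hp.twist == pytest.approx(18.0, abs=1e-9)
        assert hp.rise == pytest.approx(a * math.sqrt(3) / 2, rel=1e-9)
        assert hp.rise == pytest.approx(96.0, abs=0.1)
        assert hp.tube_radius == pytest.approx(10 * a / (2 * math.pi), rel=1e-6)

    def test_phi12_shortest_pentamer_path(self, phi12_lattice):
        """The bottom-to-top pentamer walk spans 7 lattice steps (the
        elongation h2+k2), passing 6 hexamers strictly between."""
        path = shortest_pentamer_path(phi12_lattice)
        assert path.n_steps == 7
        assert path.n_hexamers_between == 6
        ids = {c.id: c for c in phi12_lattice.capsomers}
        assert ids[path.capsomer_ids[0]].kind == "pentamer"
        assert ids[path.capsomer_ids[-1]].kind == "pentamer"
        assert all(ids[i].kind == "hexamer" for i in path.capsomer_ids[1:-1])

    def test_isometric_degeneracy(self, t4_lattice, t4_prolate_degenerate):
        """(2,0) isometric and (2,0,2,0) prolate inputs give the same shell."""
        assert t4_lattice.counts() == t4_prolate_degenerate.counts()
        assert nx.is_isomorphic(t4_lattice.graph(), t4_prolate_degenerate.graph())
        path = shortest_pentamer_path(t4_prolate_degenerate)
        assert path.n_steps == 2
        assert path.n_hexamers_between == 1
        assert ring_partition(t4_prolate_degenerate) == [] or len(
            ring_partition(t4_prolate_degenerate)[0]
        ) == 10  # single equatorial row, no complete midsection rings beyond it

    def test_doubled_tube(self):
        """(2,0,14,0): the census forces 130 midsection hexamers = 13 rings;
        the pentamer walk doubles to 14 steps."""
        lat = build_prolate_lattice(LatticeVectors(2, 0, 14, 0))
        rings = ring_partition(lat)
        assert len(rings) == 13
        assert shortest_pentamer_path(lat).n_steps == 14

    def test_chiral_caps_rejected(self):
        with pytest.raises(GeometryError):
            build_prolate_lattice(LatticeVectors(2, 1, 7, 0))

    def test_midsection_depends_on_vector_sum_only(self):
        """(7,0), (6,1) and (5,2) midsection vectors describe the same tube."""
        base = build_prolate_lattice(LatticeVectors(2, 0, 7, 0))
        for h2, k2 in [(6, 1), (5, 2)]:
            alt = build_prolate_lattice(LatticeVectors(2, 0, h2, k2))
            assert alt.counts() == base.counts()
            assert nx.is_isomorphic(alt.graph(), base.graph())


def test_census_equality_with_lattice_core():
    """Geometry census equals the integer accounting for every supported
    vector with components <= 5."""
    for h in range(1, 6):
        for k in range(0, h + 1):
            lat = build_icosahedral_lattice(h, k)
            arch = architecture_counts(LatticeVectors.isometric(h, k))
            counts = lat.counts()
            assert counts["pentamer"] == arch.pentamer_sites
            assert counts["hexamer"] == arch.hexamer_count
    for h1 in range(1, 6):
        for e in range(h1, 11):
            lat = build_prolate_lattice(LatticeVectors(h1, 0, e, 0))
            arch = architecture_counts(LatticeVectors(h1, 0, e, 0))
            counts = lat.counts()
            assert counts["pentamer"] == arch.pentamer_sites
            assert counts["hexamer"] == arch.hexamer_count


def test_graph_regularity():
    """Pentamer degree 5, hexamer degree 6, no self loops, on closed shells."""
    for lat in [
        build_icosahedral_lattice(3, 1),
        build_prolate_lattice(LatticeVectors(3, 0, 8, 0), portal=True),
    ]:
        g = lat.graph()
        assert nx.number_of_selfloops(g) == 0
        for c in lat.capsomers:
            expected = 6 if c.kind == "hexamer" else 5
            assert g.degree(c.id) == expected, (c.kind, c.id)


def test_cap_subgraph_matches_isometric_shell(phi12_lattice, t4_lattice):
    """The prolate end cap is graph-isomorphic to a 6-pentamer cap cut from
    the isometric T=4 shell."""
    cap_nodes = [
        c.id for c in phi12_lattice.capsomers if c.region == "cap_top"
    ]
    cap = phi12_lattice.graph().subgraph(cap_nodes)
    # cut the isometric shell at its upper junction-pentamer plane
    pents = sorted(
        (c for c in t4_lattice.capsomers if c.kind == "pentamer"),
        key=lambda c: -c.center[2],
    )
    ring_z = pents[1].center[2]  # second-highest pentamer level
    iso_nodes = [
        c.id for c in t4_lattice.capsomers if c.center[2] >= ring_z - 1e-6
    ]
    iso_cap = t4_lattice.graph().subgraph(iso_nodes)
    assert len(cap_nodes) == len(iso_nodes) == 16
    assert nx.is_isomorphic(cap, iso_cap)


def test_helical_rise_ratio_for_achiral_tubes():
    """rise / lattice_constant = sqrt(3)/2 for every achiral tube."""
    for h1, e in [(2, 5), (2, 9), (3, 7)]:
        lat = build_prolate_lattice(LatticeVectors(h1, 0, e, 0), lattice_constant=50.0)
        hp = helical_params(lat)
        assert hp.rise / 50.0 == pytest.approx(math.sqrt(3) / 2, rel=1e-9)
        assert hp.twist == pytest.approx(180.0 / (5 * h1), abs=1e-9)


def test_dihedral_angles(phi12_lattice, t4_lattice):
    rep_pro = dihedral_angles(phi12_lattice)
    rep_iso = dihedral_angles(t4_lattice)
    for rep in (rep_pro, rep_iso):
        for angles in rep.per_pentamer.values():
            assert all(0 < a <= 180 for a in angles)
    # pentamer environments agree between the isometric shell and the
    # prolate end caps to within a few degrees
    pro_means = sorted(rep_pro.pentamer_means().values())
    iso_means = sorted(rep_iso.pentamer_means().values())
    assert abs(np.mean(pro_means) - np.mean(iso_means)) < 5.0


def test_rigid_motion_invariance(phi12_lattice):
    """Rotating and translating the lattice changes no derived quantity."""
    R = Rotation.from_euler("zyx", [17.0, -42.0, 63.0], degrees=True).as_matrix()
    t = np.array([100.0, -250.0, 40.0])
    moved = phi12_lattice.transform(R, t)
    assert moved.counts() == phi12_lattice.counts()
    assert moved.edges == phi12_lattice.edges
    assert [len(r) for r in ring_partition(moved)] == [
        len(r) for r in ring_partition(phi12_lattice)
    ]
    p0 = shortest_pentamer_path(phi12_lattice)
    p1 = shortest_pentamer_path(moved)
    assert p0.n_steps == p1.n_steps
    d0 = dihedral_angles(phi12_lattice)
    d1 = dihedral_angles(moved)
    assert d1.mean == pytest.approx(d0.mean, abs=1e-9)
    assert helical_params(moved).rise == pytest.approx(
        helical_params(phi12_lattice).rise, abs=1e-9
    )


class TestExport:
    def test_pdb_record_count(self, phi12_lattice, tmp_path):
        """One HETATM per capsomer: 80 hexamers + 11 pentamers + portal = 92."""
        out = export_lattice(phi12_lattice, tmp_path / "m.pdb", format="pdb")
        records = [
            line for line in out.read_text().splitlines()
            if line.startswith(("ATOM", "HETATM"))
        ]
        assert len(records) == 92

    def test_csv_round_trip(self, phi12_lattice, tmp_path):
        out = export_lattice(phi12_lattice, tmp_path / "m.csv", format="csv")
        back = read_lattice_csv(out)
        assert back.counts() == phi12_lattice.counts()
        assert back.edges == phi12_lattice.edges
        orig = {c.id: c for c in phi12_lattice.capsomers}
        for c in back.capsomers:
            o = orig[c.id]
            assert c.kind == o.kind and c.region == o.region
            assert c.ring_index == o.ring_index
            assert np.array_equal(c.center, o.center)
            assert np.array_equal(c.normal, o.normal)

    def test_unknown_format_rejected(self, phi12_lattice, tmp_path):
        with pytest.raises(ValueError):
            export_lattice(phi12_lattice, tmp_path / "m.xyz", format="")
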
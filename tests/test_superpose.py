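"""Kabsch superposition, core trimming and sequence-guided pairing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capsidkit.superpose import (
    ChainModel,
    align_sequences,
    chain_from_structure,
    core_rmsd,
    kabsch,
    superpose,
)
from capsidkit.synthetic import gen_perturbed_structure, random_chain


def rot(zyx):
    return Rotation.from_euler("zyx", zyx, degrees=True).as_matrix()


class TestKabsch:
    def test_identical_sets_give_identity(self):
        ch = random_chain(40, seed=1)
        res = superpose(ch, ch)
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.translation, 0.0, atol=1e-9)

    def test_known_transform_recovered(self):
        ch = random_chain(60, seed=2)
        R, t = rot([25.0, -70.0, 110.0]), np.array([12.0, -4.0, 33.0])
        ps = gen_perturbed_structure(ch, R, t, noise_sigma=0.0, seed=3)
        res = superpose(ps.moving, ps.target)
        assert res.rmsd_all < 1e-9
        assert np.abs(res.rotation - R).max() < 1e-9
        assert np.abs(res.translation - t).max() < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper(self):
        # near-planar configuration that tempts a reflection solution
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.01]], dtype=float)
        B = A[:, [1, 0, 2]].copy()  # mirrored counterpart
        R, t, rmsd = kabsch(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_noise_gives_expected_rmsd(self):
        """Isotropic sigma per coordinate on one copy gives RMSD ~ sigma*sqrt(3)
        (slightly reduced by fitting); checked against a Monte-Carlo oracle."""
        sigma = 0.8
        ch = random_chain(300, seed=4)
        rmsds = []
        for seed in range(20):
            ps = gen_perturbed_structure(
                ch, rot([10.0, 20.0, 30.0]), [1.0, 2.0, 3.0], sigma, seed=seed
            )
            rmsds.append(superpose(ps.moving, ps.target).rmsd_all)
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)

    def test_degenerate_configurations_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch(line, line)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_optimal_on_small_instances_vs_rotation_grid(self):
        """Brute-force search over a fine rotation grid cannot beat the
        Kabsch RMSD on <= 6 points (up to grid resolution)."""
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 3)) * 5.0
        B = rng.normal(size=(6, 3)) * 5.0
        _, _, best = kabsch(A, B)
        ca, cb = A.mean(axis=0), B.mean(axis=0)
        A0, B0 = A - ca, B - cb
        step = 9.0
        angles = np.arange(0.0, 360.0, step)
        tilt = np.arange(-90.0, 90.1, step)
        grid_best = np.inf
        for az in angles:
            for el in tilt:
                for tw in angles:
                    Rg = Rotation.from_euler("zyz", [az, el, tw], degrees=True)
                    d = Rg.apply(A0) - B0
                    grid_best = min(grid_best, float(np.sqrt((d**2).sum() / 6)))
        assert best <= grid_best + 1e-9
        # the grid comes within its resolution of the optimum
        assert grid_best - best < np.radians(step) * np.abs(A0).max() * 2

    def test_rmsd_invariant_under_prerotation(self):
        ch = random_chain(50, seed=5)
        ps = gen_perturbed_structure(ch, rot([40.0, 10.0, 5.0]), [0, 0, 0], 0.5, seed=6)
        base = superpose(ps.moving, ps.target).rmsd_all
        pre = gen_perturbed_structure(
            ps.moving, rot([123.0, 45.0, 67.0]), [9.0, 9.0, 9.0], 0.0, seed=7
        ).target
        assert superpose(pre, ps.target).rmsd_all == pytest.approx(base, abs=1e-9)


class TestCoreRmsd:
    def test_clean_pair_keeps_all_pairs(self):
        ch = random_chain(30, seed=8)
        ps = gen_perturbed_structure(ch, rot([15.0, 25.0, 35.0]), [1, 1, 1], 0.0, seed=9)
        res = superpose(ps.moving, ps.target)
        trimmed = core_rmsd(ps.moving, ps.target, res)
        assert trimmed.core_pairs == trimmed.matched_pairs
        assert trimmed.rmsd_core == pytest.approx(0.0, abs=1e-9)

    def test_planted_mobile_domain_excluded(self):
        """Two-domain model: the rigidly displaced domain is trimmed away and
        the still domain superposes exactly."""
        ch = random_chain(80, seed=10)
        moved = ch.coords.copy()
        moved[50:] += np.array([25.0, 0.0, 0.0])  # displace the second domain
        target = ChainModel(
            chain_id="Y",
            residue_numbers=ch.residue_numbers,
            residue_names=ch.residue_names,
            coords=moved,
        )
        res = superpose(ch, target)
        trimmed = core_rmsd(ch, target, res, cutoff=3.8)
        core_residues = {ra for ra, _ in trimmed.core_pairs}
        assert core_residues == set(range(1, 51))
        assert trimmed.rmsd_core == pytest.approx(0.0, abs=1e-9)
        assert trimmed.rmsd_core <= trimmed.rmsd_all

    def test_core_collapse_raises(self):
        ch = random_chain(10, seed=11)
        scattered = ChainModel(
            chain_id="Z",
            residue_numbers=ch.residue_numbers,
            residue_names=ch.residue_names,
            coords=ch.coords + np.random.default_rng(1).normal(0, 50.0, ch.coords.shape),
        )
        res = superpose(ch, scattered)
        with pytest.raises(ValueError):
            core_rmsd(ch, scattered, res, cutoff=0.01)


class TestAlignment:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        aln = align_sequences(seq, seq)
        assert aln.identity == 1.0
        assert aln.aligned_columns == len(seq)
        assert aln.pairs[0] == (0, 0) and aln.pairs[-1] == (len(seq) - 1, len(seq) - 1)

    def test_shuffled_sequence_identity_near_background(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        shuffled = "".join(rng.permutation(list(seq)))
        aln = align_sequences(seq, shuffled)
        assert aln.identity < 0.35  # ~1/20 expected, alignment inflates a little

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD")

    def test_alignment_guided_superposition(self):
        """Chains differing by numbering offset and a gap still pair up via
        the sequence alignment."""
        ch = random_chain(60, seed=13)
        ps = gen_perturbed_structure(ch, rot([5.0, 15.0, 25.0]), [3, 2, 1], 0.0, seed=14)
        # delete residues 20-24 from the target and renumber from 101
        keep = [i for i in range(60) if not 19 <= i <= 23]
        target = ChainModel(
            chain_id="B",
            residue_numbers=tuple(101 + i for i in range(len(keep))),
            residue_names="".join(ps.target.residue_names[i] for i in keep),
            coords=ps.target.coords[keep],
        )
        res = superpose(ps.moving, target)
        assert len(res.matched_pairs) >= 50
        assert res.rmsd_all < 1e-6


def test_chain_from_structure_pdb(tmp_path):
    """Round trip through a minimal PDB file, residues matched by author
    numbering."""
    import gemmi

    ch = random_chain(15, seed=15)
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    three = {v: k for k, v in {
        "ALA": "A", "GLY": "G", "LEU": "L", "SER": "S",
    }.items()}
    seq = ("AGLS" * 4)[:15]
    for i, (aa, xyz) in enumerate(zip(seq, ch.coords), start=1):
        res = gemmi.Residue()
        res.name = three[aa]
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = tmp_path / "toy.pdb"
    st.setup_entities()
    st.write_pdb(str(path))

    out = chain_from_structure(path, "A")
    assert out.residue_names == seq
    assert out.residue_numbers == tuple(range(1, 16))
    assert np.allclose(out.coords, ch.coords, atol=1e-3)  # PDB precision
    with pytest.raises(ValueError):
        chain_from_structure(path, "B")
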
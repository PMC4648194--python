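"""Heme-pocket geometry: parsing, planted closure, invariance, Kabsch."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rhizoglob.heme_geometry import (
    atom_distance,
    dihedral,
    kabsch_superpose,
    parse_structure,
    pocket_geometry,
    write_pdb,
)
from rhizoglob.synthetic_data import generate_heme_pocket_pdb

ROLE_RESSEQ = {"proximal": 93, "distal": 64, "B10": 33, "CD1": 43}


class TestParsing:
    def test_round_trip_preserves_coordinates(self):
        pdb = generate_heme_pocket_pdb({"proximal": 2.1, "distal": 6.71})
        model = parse_structure(pdb)
        again = parse_structure(write_pdb(model))
        for a, b in zip(model.atoms, again.atoms):
            assert np.allclose(a.xyz, b.xyz, atol=1e-3)
            assert (a.name, a.resname, a.resseq) == (b.name, b.resname, b.resseq)

    def test_missing_heme_rejected(self):
        pdb = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        with pytest.raises(ValueError, match="no Fe"):
            parse_structure(pdb)

    def test_malformed_record_reports_line_number(self):
        good = generate_heme_pocket_pdb({"proximal": 2.1}).splitlines()
        bad = good[:2] + ["ATOM      3  CB  HIS A  93      bad coords"] + good[3:]
        with pytest.raises(ValueError, match="line 3"):
            parse_structure("\n".join(bad))

    def test_gemmi_agrees_with_fixed_column_parser(self):
        gemmi = pytest.importorskip("gemmi")
        pdb = generate_heme_pocket_pdb({"proximal": 2.1, "B10": 5.0})
        mine = parse_structure(pdb)
        theirs = gemmi.read_pdb_string(pdb)
        their_atoms = [
            (atom.name, round(atom.pos.x, 3), round(atom.pos.y, 3), round(atom.pos.z, 3))
            for model in theirs
            for chain in model
            for residue in chain
            for atom in residue
        ]
        my_atoms = [(a.name, a.x, a.y, a.z) for a in mine.atoms]
        assert my_atoms == their_atoms


class TestPrimitives:
    def test_distance_examples(self):
        assert atom_distance((0, 0, 0), (0, 0, 2.10)) == pytest.approx(2.10)
        assert atom_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_distance_formula_cross_check(self):
        """Norm-of-difference agrees with the expanded dot-product form."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.normal(size=3), rng.normal(size=3)
            expanded = np.sqrt(a @ a - 2 * a @ b + b @ b)
            assert atom_distance(a, b) == pytest.approx(expanded, abs=1e-12)

    def test_dihedral_sign_convention(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == pytest.approx(-90.0)
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_degenerate_dihedral_returns_none(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)) is None


class TestPocketClosure:
    def test_planted_distances_recovered_to_milliangstrom(self):
        requested = {"proximal": 2.10, "distal": 6.71, "B10": 5.44, "CD1": 9.83}
        model = parse_structure(generate_heme_pocket_pdb(requested))
        geom = pocket_geometry(model, {r: ROLE_RESSEQ[r] for r in requested})
        for role, d in requested.items():
            assert geom.roles[role].distance == pytest.approx(d, abs=1e-3)

    def test_planted_dihedrals_recovered_to_tenth_degree(self):
        chis = {"proximal": -90.0, "distal": 37.5, "B10": 179.0, "CD1": -12.25}
        pdb = generate_heme_pocket_pdb(
            {r: 3.0 + i for i, r in enumerate(chis)}, dihedrals=chis
        )
        geom = pocket_geometry(
            parse_structure(pdb), {r: ROLE_RESSEQ[r] for r in chis}
        )
        for role, chi in chis.items():
            assert geom.roles[role].chi1 == pytest.approx(chi, abs=0.1)

    def test_coordination_calls(self):
        cases = [
            ({"proximal": 2.10, "distal": 6.71}, "penta"),
            ({"proximal": 2.0, "distal": 2.4}, "hexa"),
            ({"proximal": 7.5, "distal": 8.2}, "indeterminate"),
        ]
        for distances, expected in cases:
            model = parse_structure(generate_heme_pocket_pdb(distances))
            geom = pocket_geometry(model, {r: ROLE_RESSEQ[r] for r in distances})
            assert geom.coordination == expected

    def test_unrealizable_distance_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            generate_heme_pocket_pdb({"proximal": -2.0})

    def test_rigid_motion_invariance(self):
        """Distances, dihedrals and the coordination call are unchanged to
        1e-9 under random rotations + translations."""
        model = parse_structure(
            generate_heme_pocket_pdb({"proximal": 2.10, "distal": 6.71}, {"proximal": -90.0})
        )
        roles = {"proximal": 93, "distal": 64}
        base = pocket_geometry(model, roles)
        rng = np.random.default_rng(5)
        for k in range(5):
            R = Rotation.random(random_state=int(rng.integers(1e6))).as_matrix()
            t = rng.normal(scale=20, size=3)
            moved = pocket_geometry(model.transformed(R, t), roles)
            for role in roles:
                assert moved.roles[role].distance == pytest.approx(
                    base.roles[role].distance, abs=1e-9
                )
                assert moved.roles[role].chi1 == pytest.approx(
                    base.roles[role].chi1, abs=1e-9
                )
            assert moved.coordination == base.coordination


class TestKabsch:
    def test_self_superposition_is_exact(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 3)) * 5
        R, t, rmsd = kabsch_superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(50, 3)) * 10
        R0 = Rotation.random(random_state=3).as_matrix()
        t0 = np.array([4.0, -2.0, 7.0])
        B = A @ R0.T + t0
        R, t, rmsd = kabsch_superpose(A, B)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R, R0, atol=1e-6)

    def test_scipy_align_vectors_cross_check(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(40, 3)) * 8
        B = A @ Rotation.random(random_state=9).as_matrix().T + 1.5
        B += rng.normal(scale=0.2, size=B.shape)
        R, t, rmsd = kabsch_superpose(A, B)
        rot, scipy_rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(scipy_rssd / np.sqrt(len(A)), rel=1e-6)

    def test_noisy_copy_rmsd_calibration(self):
        """With iid N(0, sigma^2) noise per coordinate the expected RMSD is
        sigma * sqrt(3 * (1 - 6/(3n))/...) ~ sigma*sqrt(3)*sqrt(1 - 2/n);
        check within 3 SE over replicates."""
        rng = np.random.default_rng(6)
        sigma, n = 0.1, 50
        rmsds = []
        for _ in range(40):
            A = rng.normal(size=(n, 3)) * 10
            B = A + rng.normal(scale=sigma, size=A.shape)
            rmsds.append(kabsch_superpose(A, B)[2])
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3.0 * n))
        se = np.std(rmsds, ddof=1) / np.sqrt(len(rmsds))
        assert abs(np.mean(rmsds) - expected) < 3 * se

    def test_optimality_against_random_motions(self):
        """The closed-form solution beats 200 random rigid motions."""
        rng = np.random.default_rng(8)
        A = rng.normal(size=(25, 3)) * 6
        B = A @ Rotation.random(random_state=11).as_matrix().T + 2.0
        B += rng.normal(scale=0.3, size=B.shape)
        _R, _t, best = kabsch_superpose(A, B)
        for k in range(200):
            R = Rotation.random(random_state=k).as_matrix()
            t = rng.normal(scale=5, size=3)
            moved = A @ R.T + t
            rmsd = np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
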
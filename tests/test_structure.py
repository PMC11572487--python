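"""PDB parsing, residue distances, FP reclassification, plane fitting."""

import numpy as np
import pytest

from ibspred.metrics import precision_score
from ibspred.structure import (
    StructureModel,
    estimate_membrane_plane,
    min_residue_distance,
    read_structure,
    reclassify_fp,
    write_pdb,
)
from oracles import brute_force_min_distance


def _structure(coords_by_pos, length=None, names=None):
    """Build a StructureModel from {position: (n,3) array}."""
    coords = {p: np.atleast_2d(np.asarray(c, dtype=float)) for p, c in coords_by_pos.items()}
    n = length if length is not None else max(coords) + 1
    return StructureModel(
        protein_id="test",
        atoms_by_position=coords,
        atom_names={p: (names or ["CA"] * len(c)) for p, c in coords.items()},
        residue_names={p: "GLY" for p in coords},
        length=n,
    )


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  HB1 ALA A   1       2.000   1.000   0.000  1.00  0.00           H
ATOM      4  CA  GLY A   2       3.000   2.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C
END
"""

GAP_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   3       3.800   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_parse_drops_hydrogens(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(MINIMAL_PDB)
        s = read_structure(path, "A")
        assert sorted(s.atoms_by_position) == [0, 1]
        assert len(s.atoms_by_position[0]) == 2  # N + CA, hydrogen dropped
        assert len(s.atoms_by_position[1]) == 1

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        s = read_structure(path, "A")
        assert len(s.atoms_by_position[0]) == 1
        assert s.atoms_by_position[0][0, 0] == pytest.approx(5.0)

    def test_numbering_gap_leaves_mask_zero(self, tmp_path):
        path = tmp_path / "gap.pdb"
        path.write_text(GAP_PDB)
        s = read_structure(path, "A", length=3)
        assert s.resolved_mask.tolist() == [1, 0, 1]

    def test_missing_chain_lists_available(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(KeyError, match="A"):
            read_structure(path, "Z")

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = {i: rng.uniform(-20, 20, (2, 3)).round(3) for i in range(5)}
        s = _structure(coords, names=["CA", "CB"])
        path = tmp_path / "rt.pdb"
        write_pdb(path, s)
        back = read_structure(path, "A", length=5)
        assert sorted(back.atoms_by_position) == sorted(coords)
        for pos in coords:
            assert np.allclose(back.atoms_by_position[pos], coords[pos], atol=1e-3)


class TestMinDistance:
    def test_three_four_five_triangle(self):
        s = _structure({0: [[0, 0, 0]], 1: [[3, 4, 0]]})
        assert min_residue_distance(s, 0, 1) == pytest.approx(5.0)

    def test_identity_is_zero(self):
        s = _structure({0: [[1, 2, 3]]})
        assert min_residue_distance(s, 0, 0) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        coords = {i: rng.uniform(-10, 10, (3, 3)) for i in range(10)}
        s = _structure(coords)
        for i in range(10):
            for j in range(i, 10):
                expected = brute_force_min_distance(coords[i], coords[j])
                assert min_residue_distance(s, i, j) == pytest.approx(expected)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        coords = {i: rng.uniform(-5, 5, (2, 3)) for i in range(4)}
        s = _structure(coords)
        for i in range(4):
            for j in range(4):
                d = min_residue_distance(s, i, j)
                assert d >= 0
                assert d == pytest.approx(min_residue_distance(s, j, i))

    def test_unresolved_residue_rejected(self):
        s = _structure({0: [[0, 0, 0]]}, length=2)
        with pytest.raises(ValueError, match="unresolved"):
            min_residue_distance(s, 0, 1)


class TestReclassifyFP:
    def _case(self):
        # residue 0: annotated IBS; residues 1-3: false positives at
        # planned distances 2.0, 3.0, 3.1 from residue 0's atom
        coords = {
            0: [[0.0, 0.0, 0.0]],
            1: [[2.0, 0.0, 0.0]],
            2: [[3.0, 0.0, 0.0]],
            3: [[3.1, 0.0, 0.0]],
        }
        truth = np.array([1, 0, 0, 0])
        pred = np.array([1, 1, 1, 1])
        return _structure(coords), truth, pred

    def test_boundary_inclusive_at_three_angstrom(self):
        s, truth, pred = self._case()
        cm, flags, dmin = reclassify_fp(truth, pred, s, radius=3.0)
        # distances {2.0, 3.0, 3.1}: exactly two inside the inclusive cutoff
        assert flags.tolist() == [0, 1, 1, 0]
        assert (cm.tp, cm.fp) == (3, 1)
        assert dmin[1] == pytest.approx(2.0)
        assert dmin[3] == pytest.approx(3.1)

    def test_radius_zero_without_touching_atoms_is_identity(self):
        s, truth, pred = self._case()
        cm, flags, _ = reclassify_fp(truth, pred, s, radius=0.0)
        assert flags.sum() == 0
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 3, 0, 0)

    def test_constructed_geometry_within_cutoff(self):
        coords = {0: [[0, 0, 0]], 1: [[2.9, 0, 0]], 2: [[9, 9, 9]]}
        truth = np.array([1, 0, 0])
        pred = np.array([1, 1, 0])
        cm, flags, _ = reclassify_fp(truth, pred, _structure(coords))
        assert flags.tolist() == [0, 1, 0]
        assert (cm.tp, cm.fp) == (2, 0)

    def test_totals_preserved_and_precision_monotone(self):
        rng = np.random.default_rng(3)
        coords = {i: rng.uniform(-8, 8, (2, 3)) for i in range(30)}
        s = _structure(coords)
        truth = rng.integers(0, 2, 30)
        pred = rng.integers(0, 2, 30)
        from ibspred.metrics import confusion

        before = confusion(truth, pred)
        after, _, _ = reclassify_fp(truth, pred, s, radius=3.0)
        assert after.tp + after.fp == before.tp + before.fp
        assert after.fn + after.tn == before.fn + before.tn
        assert precision_score(after) >= precision_score(before)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(4)
        coords = {i: rng.uniform(-6, 6, (1, 3)) for i in range(20)}
        s = _structure(coords)
        truth = (rng.random(20) < 0.3).astype(int)
        pred = (rng.random(20) < 0.5).astype(int)
        previous: set[int] = set()
        for radius in (0.0, 1.0, 2.0, 4.0, 8.0):
            _, flags, _ = reclassify_fp(truth, pred, s, radius=radius)
            current = set(np.flatnonzero(flags))
            assert previous <= current
            previous = current

    def test_flags_agree_with_brute_force_distances(self):
        rng = np.random.default_rng(5)
        coords = {i: rng.uniform(-6, 6, (2, 3)) for i in range(12)}
        s = _structure(coords)
        truth = np.zeros(12, dtype=int)
        truth[[0, 5]] = 1
        pred = np.ones(12, dtype=int)
        _, flags, _ = reclassify_fp(truth, pred, s, radius=3.0)
        for pos in range(12):
            if truth[pos] == 1:
                assert flags[pos] == 0
                continue
            dmin = min(
                brute_force_min_distance(coords[pos], coords[k]) for k in (0, 5)
            )
            assert flags[pos] == (1 if dmin <= 3.0 else 0)

    def test_unresolved_fp_left_unadjusted(self, caplog):
        coords = {0: [[0, 0, 0]], 2: [[1, 0, 0]]}
        s = _structure(coords, length=3)
        truth = np.array([1, 0, 0])
        pred = np.array([1, 1, 1])
        cm, flags, _ = reclassify_fp(truth, pred, s, radius=3.0)
        assert flags[1] == 0  # position 1 has no coordinates
        assert flags[2] == 1


class TestMembranePlane:
    def test_exact_plane_through_coplanar_points(self):
        coords = {i: [[x, y, 2.0]] for i, (x, y) in enumerate(
            [(0, 0), (4, 0), (0, 4), (4, 4)]
        )}
        s = _structure(coords)
        plane = estimate_membrane_plane(s, np.ones(4, dtype=int))
        assert np.allclose(np.abs(plane.normal), [0, 0, 1])
        assert plane.point[2] == pytest.approx(2.0)
        assert plane.inlier_rms == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance_of_normal_and_rms(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((10, 3)) * [5, 5, 0.3]
        s1 = _structure({i: pts[i : i + 1] for i in range(10)})
        shift = np.array([10.0, -3.0, 7.0])
        s2 = _structure({i: pts[i : i + 1] + shift for i in range(10)})
        labels = np.ones(10, dtype=int)
        p1 = estimate_membrane_plane(s1, labels)
        p2 = estimate_membrane_plane(s2, labels)
        assert np.allclose(p1.normal, p2.normal)
        assert p1.inlier_rms == pytest.approx(p2.inlier_rms)
        assert np.allclose(p2.point, p1.point + shift)

    def test_noisy_plane_recovered_against_svd_oracle(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(-10, 10, (20, 2))
        z = 0.2 * rng.standard_normal(20)
        pts = np.column_stack([xy, z])
        s = _structure({i: pts[i : i + 1] for i in range(20)})
        plane = estimate_membrane_plane(s, np.ones(20, dtype=int))
        # independent decomposition oracle: eigenvector of the smallest
        # eigenvalue of the covariance matrix
        cov = np.cov((pts - pts.mean(axis=0)).T)
        w, v = np.linalg.eigh(cov)
        oracle_normal = v[:, 0]
        cosang = abs(np.dot(plane.normal, oracle_normal))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1e-6
        assert np.degrees(np.arccos(abs(plane.normal[2]))) < 5.0

    def test_rotation_invariance_up_to_rotated_normal(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack(
            [rng.uniform(-8, 8, (15, 2)), 0.1 * rng.standard_normal(15)]
        )
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=3).as_matrix()
        s1 = _structure({i: pts[i : i + 1] for i in range(15)})
        s2 = _structure({i: (pts[i : i + 1] @ R.T) for i in range(15)})
        labels = np.ones(15, dtype=int)
        p1 = estimate_membrane_plane(s1, labels)
        p2 = estimate_membrane_plane(s2, labels)
        assert abs(np.dot(p2.normal, R @ p1.normal)) == pytest.approx(1.0, abs=1e-9)
        assert p1.inlier_rms == pytest.approx(p2.inlier_rms, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        s = _structure({0: [[0, 0, 0]], 1: [[1, 0, 0]]}, length=3)
        with pytest.raises(ValueError, match=">= 3"):
            estimate_membrane_plane(s, np.array([1, 1, 0]))
        line = _structure({i: [[float(i), 0, 0]] for i in range(5)})
        with pytest.raises(ValueError, match="collinear"):
            estimate_membrane_plane(line, np.ones(5, dtype=int))

    def test_principal_axis_mode_is_orthogonal_to_default(self):
        rng = np.random.default_rng(9)
        pts = np.column_stack(
            [rng.uniform(-10, 10, 12), rng.uniform(-2, 2, 12), 0.1 * rng.standard_normal(12)]
        )
        s = _structure({i: pts[i : i + 1] for i in range(12)})
        labels = np.ones(12, dtype=int)
        default = estimate_membrane_plane(s, labels)
        axis = estimate_membrane_plane(s, labels, normal_mode="principal-axis")
        assert abs(np.dot(default.normal, axis.normal)) < 1e-6
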
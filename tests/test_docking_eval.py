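"""Pose RMSD, the best-pose acceptance gate, interaction profiling and
grid-box containment."""

import itertools

import numpy as np
import pytest

from glucotriage import docking_eval as de
from glucotriage.docking_eval import (
    DEFAULT_GRID_BOXES, GridBox, Pose, classify_hbond, gridbox_contains,
    pose_rmsd, profile_interactions, read_pdbqt_poses, select_best_pose,
)


def make_pose(coords, elements=None, energy=-7.0, **kw):
    coords = np.asarray(coords, dtype=float)
    elements = tuple(elements or ["C"] * len(coords))
    return Pose(coords=coords, elements=elements, energy=energy, **kw)


HEXAGON = 1.4 * np.array([
    [np.cos(a), np.sin(a), 0.0] for a in np.arange(6) * np.pi / 3
])


class TestPoseRmsd:
    def test_identical_poses(self):
        p = make_pose(np.arange(12).reshape(4, 3))
        assert pose_rmsd(p, p) == 0.0

    def test_uniform_translation(self):
        p = make_pose(np.arange(12).reshape(4, 3))
        q = make_pose(p.coords + [2.0, 0.0, 0.0])
        assert pose_rmsd(p, q) == pytest.approx(2.0)

    def test_symmetry_aware_matches_exhaustive_minimum(self):
        """A rotated hexagonal ring: the symmetry-aware RMSD equals the
        brute-force minimum over all element-preserving permutations."""
        a = make_pose(HEXAGON)
        theta = np.pi / 3          # one ring step: atoms relabeled
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        b = make_pose(HEXAGON @ rot.T)
        brute = min(
            np.sqrt(((a.coords - b.coords[list(perm)]) ** 2)
                    .sum(axis=1).mean())
            for perm in itertools.permutations(range(6))
        )
        assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(brute)
        assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(0.0, abs=1e-9)
        assert pose_rmsd(a, b, symmetry_aware=False) > 1.0

    def test_pseudometric_properties(self, rng):
        # fixed atom mapping: symmetry, identity, triangle inequality
        d = lambda x, y: pose_rmsd(x, y, symmetry_aware=False)
        poses = [make_pose(rng.normal(size=(5, 3))) for _ in range(3)]
        for p, q in itertools.combinations(poses, 2):
            assert d(p, q) == pytest.approx(d(q, p))
            assert d(p, p) == 0.0
        a, b, c = poses
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-9

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError):
            pose_rmsd(make_pose(np.zeros((3, 3))), make_pose(np.zeros((4, 3))))

    def test_element_mismatch(self):
        with pytest.raises(ValueError):
            pose_rmsd(make_pose(np.zeros((2, 3)), ["C", "N"]),
                      make_pose(np.zeros((2, 3)), ["C", "O"]))


class TestSelectBestPose:
    def test_none_below_energy_cut_rejected(self):
        poses = [make_pose(np.zeros((2, 3)), energy=e) for e in (-5.0, -5.5)]
        result = select_best_pose(poses)
        assert not result.accepted
        assert result.best is None

    def test_rmsd_gate_excludes_distant_pose(self):
        ref = make_pose(np.zeros((2, 3)))
        near = make_pose(np.zeros((2, 3)) + 0.5, energy=-7.0)
        far = make_pose(np.zeros((2, 3)) + 3.0, energy=-9.0)
        result = select_best_pose([near, far], reference=ref)
        assert result.accepted
        assert result.best.energy == -7.0
        assert result.best_rmsd == pytest.approx(np.sqrt(3 * 0.25))

    def test_matches_brute_force_filter_argmin(self, rng):
        ref = make_pose(rng.normal(size=(4, 3)), ["C", "N", "O", "C"])
        poses = [
            make_pose(ref.coords + rng.normal(scale=s, size=(4, 3)),
                      ["C", "N", "O", "C"], energy=float(rng.uniform(-10, -4)),
                      pose_index=i)
            for i, s in enumerate(rng.uniform(0.1, 3.0, size=100))
        ]
        result = select_best_pose(poses, reference=ref, symmetry_aware=False)
        passing = [p for p in poses
                   if p.energy < -6.0
                   and pose_rmsd(p, ref, symmetry_aware=False) < 2.0]
        if passing:
            expected = min(passing, key=lambda p: p.energy)
            assert result.best.energy == expected.energy
        else:
            assert not result.accepted

    def test_invariant_to_pose_order(self, rng):
        poses = [make_pose(rng.normal(size=(3, 3)),
                           energy=float(rng.uniform(-9, -6.1)), pose_index=i)
                 for i in range(10)]
        a = select_best_pose(poses)
        b = select_best_pose(list(reversed(poses)))
        assert a.best.pose_index == b.best.pose_index

    def test_empty_pose_set(self):
        with pytest.raises(ValueError):
            select_best_pose([])


class TestHbondClasses:
    @pytest.mark.parametrize("distance,expected", [
        (2.3, "strong"),
        (2.73, "moderate"),   # aspartate-contact distance of the lead
        (2.97, "moderate"),   # cysteine-contact distance
        (3.99, "weak"),       # isoleucine-contact distance
        (4.5, "none"),
        (2.5, "moderate"),    # bin edges are left-closed
        (3.2, "weak"),
    ])
    def test_bins(self, distance, expected):
        assert classify_hbond(distance) == expected

    def test_nonpositive_distance(self):
        with pytest.raises(ValueError):
            classify_hbond(0.0)


class TestProfileInteractions:
    def test_planted_contacts_recovered(self, toy_complex):
        receptor, pose, truth = toy_complex
        records = profile_interactions(receptor, pose)
        found = {(r.residue, r.kind): r for r in records}
        for planted in truth["contacts"]:
            key = (planted["residue"], planted["kind"])
            assert key in found, f"missing planted contact {key}"
            assert found[key].distance == pytest.approx(
                planted["distance"], abs=1e-3)
        assert len(records) == len(truth["contacts"])

    def test_hbond_strength_class(self, toy_complex):
        receptor, pose, _ = toy_complex
        (rec,) = [r for r in profile_interactions(receptor, pose)
                  if r.kind == "hbond"]
        assert rec.strength == "moderate"   # 2.73 A

    def test_contact_beyond_cutoff_not_reported(self):
        from glucotriage.synthetic_data import Contact, SimSpec, gen_toy_complex
        receptor, pose, _ = gen_toy_complex(
            SimSpec(seed=0), contacts=[Contact("hydrophobic", "PHE", 6.0)])
        records = profile_interactions(receptor, pose)
        assert records == []

    def test_empty_receptor_rejected(self, toy_complex):
        import biotite.structure as bst
        _, pose, _ = toy_complex
        with pytest.raises(ValueError):
            profile_interactions(bst.AtomArray(0), pose)


class TestGridBox:
    def test_contained_pose(self):
        box = GridBox((0, 0, 0), (10, 10, 10))
        pose = make_pose(np.random.default_rng(0).uniform(-4, 4, (20, 3)))
        assert gridbox_contains(box, pose) == 1.0

    def test_fully_outside(self):
        box = GridBox((0, 0, 0), (10, 10, 10))
        assert gridbox_contains(box, make_pose(np.full((5, 3), 50.0))) == 0.0

    def test_max_face_is_outside_half_open(self):
        box = GridBox((0, 0, 0), (10, 10, 10))
        assert gridbox_contains(box, make_pose([[5.0, 0.0, 0.0]])) == 0.0
        assert gridbox_contains(box, make_pose([[-5.0, 0.0, 0.0]])) == 1.0

    def test_published_boxes(self):
        assert DEFAULT_GRID_BOXES["2IKH"].center == (14.17, -0.095, 23.464)
        assert DEFAULT_GRID_BOXES["2IKH"].dimensions == (60.0, 40.0, 56.0)
        assert DEFAULT_GRID_BOXES["4IXC"].dimensions == (66.0, 72.0, 66.0)

    def test_bad_dimensions(self):
        with pytest.raises(ValueError):
            GridBox((0, 0, 0), (10, -1, 10))


class TestPdbqtReader:
    def test_reads_models_energies_elements(self, tmp_path):
        text = "\n".join([
            "MODEL 1",
            "REMARK VINA RESULT:      -7.2      0.000      0.000",
            "ATOM      1  C   LIG A   1       1.000   2.000   3.000  0.00  0.00    +0.000 C ",
            "ATOM      2  OA  LIG A   1       2.000   2.000   3.000  0.00  0.00    -0.250 OA",
            "ENDMDL",
            "MODEL 2",
            "REMARK VINA RESULT:      -6.1      1.200      2.100",
            "ATOM      1  C   LIG A   1       1.500   2.000   3.000  0.00  0.00    +0.000 C ",
            "ATOM      2  OA  LIG A   1       2.500   2.000   3.000  0.00  0.00    -0.250 OA",
            "ENDMDL",
        ])
        path = tmp_path / "poses.pdbqt"
        path.write_text(text)
        poses = read_pdbqt_poses(path)
        assert [p.energy for p in poses] == [-7.2, -6.1]
        assert poses[0].elements == ("C", "O")
        np.testing.assert_allclose(poses[0].coords[0], [1.0, 2.0, 3.0])

    def test_missing_energy_is_an_error(self, tmp_path):
        path = tmp_path / "bad.pdbqt"
        path.write_text(
            "MODEL 1\n"
            "ATOM      1  C   LIG A   1       1.000   2.000   3.000  0.00  0.00    +0.000 C \n"
            "ENDMDL\n")
        with pytest.raises(ValueError, match="VINA RESULT"):
            read_pdbqt_poses(path)
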
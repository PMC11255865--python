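import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crystbio import (
    AngleDefinition,
    StateBounds,
    TrajectoryFeatures,
    assign_states,
    com_distance_matrix,
    compare_conformations,
    default_state_bounds,
    featurize,
    kde_landscape,
    orientation_angle,
    pick_representative_frames,
    superpose,
)
from crystbio.fileio import Trajectory
from crystbio.synth import gen_two_domain_trajectory

from conftest import make_frame, quaternion_rmsd


def backbone_frame(ca_positions, start_res=1):
    atoms = []
    offsets = {"N": (-0.5, 0.3, 0.1), "CA": (0, 0, 0), "C": (0.5, -0.3, 0.1), "O": (1.0, 0.4, -0.2)}
    for i, ca in enumerate(np.atleast_2d(ca_positions)):
        for name, off in offsets.items():
            atoms.append((start_res + i, "GLY", name, tuple(np.asarray(ca) + off)))
    return make_frame(atoms)


def random_backbone(rng, n_res=10):
    return backbone_frame(rng.normal(scale=5.0, size=(n_res, 3)))


class TestSuperpose:
    def test_identical_frames_zero_rmsd(self, rng):
        fr = random_backbone(rng)
        _, rmsd = superpose(fr, fr)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        fr = random_backbone(rng)
        rot = Rotation.from_rotvec(np.deg2rad(37.0) * np.array([1, 2, 2]) / 3.0)
        moved = fr.with_coords(rot.apply(fr.coords) + np.array([5.0, -3.0, 11.0]))
        fitted, rmsd = superpose(moved, fr)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(fitted.coords, fr.coords, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            a = random_backbone(rng, n_res=3)  # 12 atoms
            b = a.with_coords(a.coords + rng.normal(scale=1.0, size=a.coords.shape))
            _, rmsd = superpose(b, a)
            sel = np.isin(a.atom_names, ("N", "CA", "C", "O"))
            oracle = quaternion_rmsd(b.coords[sel], a.coords[sel])
            assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_superposed_rmsd_never_worse_than_raw(self, rng):
        for _ in range(20):
            a = random_backbone(rng, n_res=6)
            b = a.with_coords(a.coords + rng.normal(scale=2.0, size=a.coords.shape))
            _, rmsd = superpose(b, a)
            raw = np.sqrt(np.mean(np.sum((b.coords - a.coords) ** 2, axis=1)))
            assert rmsd <= raw + 1e-12

    def test_too_few_atoms_error(self):
        fr = make_frame([(1, "GLY", "CA", (0, 0, 0)), (1, "GLY", "N", (1, 0, 0))])
        with pytest.raises(ValueError, match="3 matched atoms"):
            superpose(fr, fr)

    def test_collinear_selection_error(self):
        atoms = [(r, "GLY", "CA", (float(r), 0.0, 0.0)) for r in range(1, 5)]
        fr = make_frame(atoms)
        with pytest.raises(ValueError, match="collinear"):
            superpose(fr, fr)


class TestOrientationAngle:
    def _frame_with_coms(self, vertex, arm_a, arm_b):
        return make_frame(
            [
                (1, "GLY", "CA", tuple(vertex)),
                (2, "GLY", "CA", tuple(arm_a)),
                (3, "GLY", "CA", tuple(arm_b)),
            ]
        )

    def test_orthogonal_arms(self):
        fr = self._frame_with_coms((0, 0, 0), (1, 0, 0), (0, 1, 0))
        defn = AngleDefinition(vertex_residues=(1,), arm_a_residues=(2,), arm_b_residues=(3,))
        assert orientation_angle(fr, defn) == pytest.approx(90.0, abs=1e-10)

    def test_collinear_arms_zero(self):
        fr = self._frame_with_coms((0, 0, 0), (1, 0, 0), (2, 0, 0))
        defn = AngleDefinition(vertex_residues=(1,), arm_a_residues=(2,), arm_b_residues=(3,))
        assert orientation_angle(fr, defn) == pytest.approx(0.0, abs=1e-6)

    def test_hand_trigonometry_45_degrees(self):
        fr = self._frame_with_coms((0, 0, 0), (1, 0, 0), (1, 1, 0))
        defn = AngleDefinition(vertex_residues=(1,), arm_a_residues=(2,), arm_b_residues=(3,))
        assert orientation_angle(fr, defn) == pytest.approx(45.0, abs=1e-10)

    def test_degenerate_geometry_error(self):
        fr = self._frame_with_coms((0, 0, 0), (0, 0, 0), (1, 1, 0))
        defn = AngleDefinition(vertex_residues=(1,), arm_a_residues=(2,), arm_b_residues=(3,))
        with pytest.raises(ValueError, match="degenerate"):
            orientation_angle(fr, defn)

    def test_rigid_motion_invariance(self, rng):
        gen = gen_two_domain_trajectory(n_res_per_domain=8, n_frames=1, jitter_sigma=0.0, seed=3)
        fr = gen.reference
        base = orientation_angle(fr, gen.angle_definition)
        for _ in range(100):
            rot = Rotation.random(rng=rng)
            moved = fr.with_coords(rot.apply(fr.coords) + rng.normal(scale=20, size=3))
            _, rmsd = superpose(moved, fr)
            assert rmsd <= 1e-8
            assert orientation_angle(moved, gen.angle_definition) == pytest.approx(
                base, abs=1e-9
            )

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            AngleDefinition(vertex_residues=(1, 2), arm_a_residues=(2,), arm_b_residues=(3,))


class TestFeaturize:
    def test_copies_of_reference(self):
        gen = gen_two_domain_trajectory(n_res_per_domain=8, n_frames=1, jitter_sigma=0.0, seed=1)
        traj = Trajectory(frames=[gen.reference.with_coords(gen.reference.coords, i) for i in range(5)])
        feats = featurize(traj, gen.reference, gen.angle_definition)
        np.testing.assert_allclose(feats.rmsd, 0.0, atol=1e-10)
        np.testing.assert_allclose(feats.angle, feats.angle[0], atol=1e-10)

    def test_scripted_hinge_angles_recovered(self):
        gen = gen_two_domain_trajectory(
            n_res_per_domain=10, n_frames=40, jitter_sigma=0.05, seed=8, occupancy_minor=0.5
        )
        feats = featurize(gen.trajectory, gen.reference, gen.angle_definition)
        for label, scripted in (("major", gen.info["angle_major"]), ("minor", gen.info["angle_minor"])):
            sel = gen.labels == label
            assert np.all(np.abs(feats.angle[sel] - scripted) < 1.5)


class TestKDELandscape:
    def test_point_mass_single_mode(self):
        feats = TrajectoryFeatures(rmsd=np.full(50, 2.0), angle=np.full(50, 20.0))
        grid = kde_landscape(feats, bandwidths=(0.1, 0.5))
        modes = grid.modes()
        assert len(modes) == 1
        assert modes[0][0] == pytest.approx(2.0, abs=0.05)
        assert modes[0][1] == pytest.approx(20.0, abs=0.25)

    def test_two_separated_clusters(self, rng):
        n = 400
        rmsd = np.concatenate([rng.normal(1.0, 0.1, n), rng.normal(4.0, 0.1, n)])
        angle = np.concatenate([rng.normal(20.0, 0.5, n), rng.normal(8.0, 0.5, n)])
        grid = kde_landscape(TrajectoryFeatures(rmsd=rmsd, angle=angle))
        modes = grid.modes()[:2]
        centers = sorted((m[0], m[1]) for m in modes)
        assert centers[0][0] == pytest.approx(1.0, abs=0.15)
        assert centers[0][1] == pytest.approx(20.0, abs=1.0)
        assert centers[1][0] == pytest.approx(4.0, abs=0.15)
        assert centers[1][1] == pytest.approx(8.0, abs=1.0)

    def test_density_normalized_over_grid(self, rng):
        feats = TrajectoryFeatures(rmsd=rng.normal(2, 0.3, 300), angle=rng.normal(15, 2, 300))
        grid = kde_landscape(feats)
        assert grid.density.sum() * grid.cell_area == pytest.approx(1.0, abs=1e-6)
        assert (grid.density >= 0).all()

    def test_zero_variance_errors_with_hint(self):
        feats = TrajectoryFeatures(rmsd=np.full(20, 2.0), angle=np.linspace(0, 30, 20))
        with pytest.raises(ValueError, match="bandwidth"):
            kde_landscape(feats)

    def test_too_few_frames_error(self):
        feats = TrajectoryFeatures(rmsd=np.arange(5.0), angle=np.arange(5.0))
        with pytest.raises(ValueError, match="10 frames"):
            kde_landscape(feats)


class TestStates:
    def test_all_frames_in_major_box(self):
        feats = TrajectoryFeatures(rmsd=np.full(30, 1.0), angle=np.full(30, 20.0))
        labels, occ = assign_states(feats, default_state_bounds())
        assert occ["major"] == 1.0
        assert occ["other"] == 0.0

    def test_empty_bounds_all_other(self):
        feats = TrajectoryFeatures(rmsd=np.full(10, 1.0), angle=np.full(10, 20.0))
        labels, occ = assign_states(feats, StateBounds(regions={}))
        assert occ == {"other": 1.0}

    def test_occupancies_sum_to_one(self, rng):
        feats = TrajectoryFeatures(rmsd=rng.uniform(0, 6, 500), angle=rng.uniform(0, 40, 500))
        _, occ = assign_states(feats, default_state_bounds())
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StateBounds(regions={"a": (0, 2, 0, 20), "b": (1, 3, 10, 30)})

    def test_scripted_occupancy_recovered(self):
        gen = gen_two_domain_trajectory(
            n_res_per_domain=10, n_frames=500, jitter_sigma=0.0, occupancy_minor=0.2, seed=17
        )
        feats = featurize(gen.trajectory, gen.reference, gen.angle_definition)
        labels, occ = assign_states(feats, gen.bounds)
        assert occ["minor"] == pytest.approx(gen.info["occupancy_minor_drawn"], abs=1e-12)
        assert (labels == gen.labels).all()

    def test_representative_frames_lie_in_their_box(self):
        gen = gen_two_domain_trajectory(n_res_per_domain=10, n_frames=200, seed=4)
        feats = featurize(gen.trajectory, gen.reference, gen.angle_definition)
        reps = pick_representative_frames(feats, gen.bounds)
        for name, idx in reps.items():
            assert gen.bounds.contains(name, feats.rmsd[idx], feats.angle[idx])


class TestDistances:
    def test_three_four_five(self):
        fr = make_frame([(1, "GLY", "CA", (0, 0, 0)), (2, "GLY", "CA", (3, 4, 0))])
        d = com_distance_matrix(fr, [1], [2])
        assert d[0, 0] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        fr = backbone_frame(rng.normal(scale=8, size=(5, 3)))
        res = [1, 2, 3, 4, 5]
        d = com_distance_matrix(fr, res, res)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)

    def test_triangle_inequality(self, rng):
        fr = backbone_frame(rng.normal(scale=8, size=(6, 3)))
        res = list(range(1, 7))
        d = com_distance_matrix(fr, res, res)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_hand_computed_pairwise(self):
        fr = make_frame(
            [
                (1, "GLY", "CA", (0, 0, 0)),
                (2, "GLY", "CA", (1, 0, 0)),
                (3, "GLY", "CA", (1, 2, 2)),
            ]
        )
        d = com_distance_matrix(fr, [1, 2, 3], [1, 2, 3])
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(3.0)
        assert d[1, 2] == pytest.approx(np.sqrt(8))


class TestCompareConformations:
    def _acidic_chain(self, rng, n=8):
        atoms = []
        for r in range(1, n + 1):
            name = "ASP" if r % 2 == 0 else "GLY"
            ca = rng.normal(scale=6, size=3)
            for aname, off in (("N", (-0.5, 0.3, 0)), ("CA", (0, 0, 0)), ("C", (0.5, -0.3, 0)), ("O", (1, 0.4, 0))):
                atoms.append((r, name, aname, tuple(ca + np.array(off, dtype=float))))
        return make_frame(atoms)

    def test_identical_frames_zero_differences(self, rng):
        fr = self._acidic_chain(rng)
        table = compare_conformations(fr, fr, sites=(2, 4))
        np.testing.assert_allclose(table["difference_A"], 0.0, atol=1e-12)

    def test_single_residue_translation(self, rng):
        fr = self._acidic_chain(rng)
        moved_coords = fr.coords.copy()
        mask = fr.residue_indices == 2
        moved_coords[mask] += np.array([50.0, 0.0, 0.0])
        moved = fr.with_coords(moved_coords)
        table = compare_conformations(fr, moved, sites=(2, 4), cutoffs=(15.0, 20.0))
        changed = table[table["difference_A"].abs() > 1e-9]
        assert set(changed[["res_i", "res_j"]].to_numpy().ravel()) >= {2}
        untouched = table[(table["res_i"] != 2) & (table["res_j"] != 2)]
        np.testing.assert_allclose(untouched["difference_A"], 0.0, atol=1e-12)

    def test_hinge_moves_interdomain_pairs_most(self):
        gen = gen_two_domain_trajectory(
            n_res_per_domain=10, n_frames=2, jitter_sigma=0.0, occupancy_minor=1.0, seed=2
        )
        minor = gen.trajectory[0]
        major = gen.reference
        n = 10  # domain A is residues 1..10, domain B 16..25
        table = compare_conformations(major, minor, sites=(5, 10, 20, 25))
        intra = table[(table["res_i"] <= n) & (table["res_j"] <= n)]
        inter = table[(table["res_i"] <= n) & (table["res_j"] > n + 5)]
        assert intra["difference_A"].abs().max() < inter["difference_A"].abs().max()

    def test_sorted_by_absolute_difference(self, rng):
        fr = self._acidic_chain(rng)
        other = fr.with_coords(fr.coords + rng.normal(scale=1.0, size=fr.coords.shape))
        table = compare_conformations(fr, other, sites=(2, 4))
        diffs = table["difference_A"].abs().to_numpy()
        assert np.all(np.diff(diffs) <= 1e-12)

    def test_empty_partner_list_error(self):
        fr = backbone_frame(np.arange(12).reshape(4, 3) * 2.0)  # all GLY
        with pytest.raises(ValueError, match="partner"):
            compare_conformations(fr, fr, sites=(1, 2))

    def test_cutoff_flags(self, rng):
        fr = make_frame(
            [
                (1, "ASP", "CA", (0, 0, 0)),
                (2, "ASP", "CA", (10, 0, 0)),
                (3, "ASP", "CA", (100, 0, 0)),
            ]
        )
        table = compare_conformations(fr, fr, sites=(1,), cutoffs=(15.0, 20.0))
        row_near = table[(table["res_i"] == 1) & (table["res_j"] == 2)].iloc[0]
        row_far = table[(table["res_i"] == 1) & (table["res_j"] == 3)].iloc[0]
        assert row_near["within_15A"] and row_near["within_20A"]
        assert not row_far["within_15A"] and not row_far["within_20A"]
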
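"""Trajectory geometry: rescaling, concatenated R^2, Hausdorff, separation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import cdist

from trajscale.subspace import NeuralTrajectory
from trajscale.trajgeo import (
    distance_contrasts,
    distance_vs_angle,
    hausdorff,
    lower_limit_r2,
    pairwise_scaled_r2,
    rescale_trajectory,
    scaled_r2,
    separation_profile,
    trim_trajectory,
    within_bin_ceiling,
)


def brute_hausdorff(x, y):
    D = cdist(x, y)
    return max(D.min(axis=1).max(), D.min(axis=0).max())


def traj(points, dt=10.0, cond="c", t0=0.0):
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    axis = t0 + np.arange(points.shape[0]) * dt
    return NeuralTrajectory(points=points, dt_ms=dt, condition=cond,
                            time_axis_ms=axis)


class TestRescale:
    def test_identity_on_600_bins(self):
        pts = np.random.default_rng(0).normal(size=(600, 3))
        out = rescale_trajectory(traj(pts)).points
        np.testing.assert_array_equal(out, pts)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(-1.0, 3.0, 41)
        out = rescale_trajectory(traj(ramp)).points[:, 0]
        np.testing.assert_allclose(out, np.linspace(-1.0, 3.0, 600),
                                   atol=1e-12)

    def test_quadratic_within_interpolation_bound(self):
        s = np.linspace(0, 1, 60)
        out = rescale_trajectory(traj(s**2)).points[:, 0]
        dense = np.linspace(0, 1, 600) ** 2
        # local error of linear interpolation <= h^2/8 * max|f''|
        assert np.abs(out - dense).max() <= (1 / 59) ** 2 / 8 * 2 + 1e-12

    def test_endpoints_preserved(self):
        pts = np.random.default_rng(1).normal(size=(17, 2))
        out = rescale_trajectory(traj(pts)).points
        np.testing.assert_allclose(out[0], pts[0])
        np.testing.assert_allclose(out[-1], pts[-1])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            rescale_trajectory(traj([[1.0, 2.0]]))


class TestScaledR2:
    @pytest.mark.parametrize("x,y,expected", [
        ([0, 1, 2], [0, 1, 2], 1.0),
        ([0, 1, 2], [1, 1, 1], 0.0),       # baseline: the mean of X
        ([0, 1, 2], [2, 1, 0], -3.0),
    ])
    def test_hand_computed_values(self, x, y, expected):
        assert scaled_r2(np.array(x, float), np.array(y, float)) == expected

    def test_asymmetry_convention(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert scaled_r2(x, y) != scaled_r2(y, x)

    def test_constant_baseline_rejected(self):
        with pytest.raises(ValueError):
            scaled_r2(np.ones(5), np.arange(5.0))

    def test_common_rotation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 3))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        assert scaled_r2(X @ R, Y @ R) == pytest.approx(scaled_r2(X, Y),
                                                        rel=1e-10)

    @given(hnp.arrays(np.float64, (20, 3),
                      elements=st.floats(-50, 50)).filter(
                          lambda a: np.ptp(a) > 1e-6))
    def test_self_similarity_is_one(self, pts):
        assert scaled_r2(pts, pts) == pytest.approx(1.0)


class TestHausdorff:
    def test_single_points_euclidean(self):
        assert hausdorff(np.array([[0.0, 0.0]]),
                         np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.empty((0, 2)), np.array([[1.0, 1.0]]))

    @given(st.integers(0, 1000))
    def test_metric_properties_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = (rng.normal(size=(rng.integers(2, 12), 3))
                   for _ in range(3))
        dxy, dyx = hausdorff(x, y), hausdorff(y, x)
        assert dxy == dyx                                   # symmetry
        assert hausdorff(x, x) == 0.0                       # identity
        assert dxy <= hausdorff(x, z) + hausdorff(z, y) + 1e-12  # triangle

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(rng.integers(2, 30), 4))
        y = rng.normal(size=(rng.integers(2, 30), 4))
        assert hausdorff(x, y) == brute_hausdorff(x, y)


class TestSeparationProfile:
    def _diverging_trajs(self, t_div_ms=-100.0):
        axis = np.arange(-500.0, 700.0, 10.0)
        trajs = []
        for k in range(8):
            offset = np.zeros((axis.size, 2))
            after = axis >= t_div_ms
            amp = np.sin(np.pi * np.arange(after.sum()) / after.sum())
            offset[after, 0] = amp * np.cos(2 * np.pi * k / 8)
            offset[after, 1] = amp * np.sin(2 * np.pi * k / 8)
            trajs.append(NeuralTrajectory(offset, 10.0, (k, 0), axis))
        return trajs

    def test_divergence_time_recovered(self):
        trajs = self._diverging_trajs(-100.0)
        prof = separation_profile(trajs)
        assert abs(prof.t_min_pre_ms - (-100.0)) <= 10.0
        assert not prof.degenerate
        assert prof.mean_distance.max() <= 1.0

    def test_identical_trajectories_degenerate(self):
        axis = np.arange(-200.0, 200.0, 10.0)
        pts = np.random.default_rng(0).normal(size=(axis.size, 2))
        trajs = [NeuralTrajectory(pts.copy(), 10.0, (k, 0), axis)
                 for k in range(4)]
        prof = separation_profile(trajs)
        assert prof.degenerate
        np.testing.assert_allclose(prof.mean_distance, 0.0)

    def test_unequal_lengths_rejected(self):
        a = traj(np.zeros((10, 2)))
        b = traj(np.zeros((12, 2)))
        with pytest.raises(ValueError):
            separation_profile([a, b])

    def test_distance_monotone_in_angle_on_cosine_tuned_data(
            self, ideal_trajectories):
        df = distance_vs_angle(ideal_trajectories, duration_bin=1)
        d = df.sort_values("angle_deg")["distance"].to_numpy()
        assert np.all(np.diff(d) >= -1e-9)


class TestDistanceContrasts:
    def test_duration_contrast_bookkeeping_and_significance(
            self, ideal_trajectories):
        df, summ = distance_contrasts(ideal_trajectories, "duration")
        assert summ["n_a"] == 96       # 8 dirs x 4 durs x 3 other durs
        assert summ["n_b"] == 64       # 8 dirs x 4 durs x 2 adjacent dirs
        assert summ["n_composition"] == 3 * 2 * 4 * 8 == 192
        assert summ["mean_a"] < summ["mean_b"]
        assert summ["p"] < 0.01

    def test_missing_condition_raises(self, ideal_trajectories):
        partial = dict(ideal_trajectories)
        partial.pop((3, 2))
        with pytest.raises(ValueError, match="missing"):
            distance_contrasts(partial, "duration")

    def test_within_bin_contrast_needs_split_distances(
            self, ideal_trajectories):
        with pytest.raises(ValueError, match="split"):
            distance_contrasts(ideal_trajectories, "within_bin")
        df, summ = distance_contrasts(ideal_trajectories, "within_bin",
                                      split_distances=np.full(20, 0.05))
        assert summ["alternative"] == "greater"


class TestCeilingAndLimits:
    def test_identical_movements_ceiling_one(self, ideal_space, ideal_tensor):
        per_movement = {
            lab: [ideal_tensor.values[i]] * 4
            for i, lab in enumerate(ideal_tensor.condition_labels[:3])
        }
        ceiling, df = within_bin_ceiling(per_movement, ideal_space, seed=0)
        assert ceiling == pytest.approx(1.0)

    def test_seeded_ceiling_deterministic(self, noisy_pipeline):
        t, s = noisy_pipeline["tensor"], noisy_pipeline["space"]
        c1, _ = within_bin_ceiling(t.per_movement, s, seed=42)
        c2, _ = within_bin_ceiling(t.per_movement, s, seed=42)
        assert c1 == c2

    def test_no_splittable_bin_raises(self, ideal_space, ideal_tensor):
        per_movement = {(0, 0): [ideal_tensor.values[0]] * 3}
        with pytest.raises(ValueError):
            within_bin_ceiling(per_movement, ideal_space, seed=0)

    def test_scaled_r2_between_durations_reaches_ceiling(
            self, noisy_pipeline):
        """Temporal-scaling structure: cross-duration similarity is close to
        the within-bin ceiling, and far above the cross-direction floor."""
        t, s = noisy_pipeline["tensor"], noisy_pipeline["space"]
        trajs = noisy_pipeline["trajectories"]
        mean_r2 = pairwise_scaled_r2(trajs)["r2"].mean()
        ceiling, _ = within_bin_ceiling(t.per_movement, s, seed=0)
        floor = lower_limit_r2(trajs)["r2"].mean()
        assert mean_r2 >= ceiling - 0.05
        assert floor < mean_r2 - 0.3


class TestTrim:
    def test_region_epochs(self):
        axis = np.arange(-500.0, 1000.0 + 300.0 + 1, 10.0)  # 1000 ms movement
        t = NeuralTrajectory(np.zeros((axis.size, 2)), 10.0, (0, 0), axis)
        m1 = trim_trajectory(t, "M1", movement_end_ms=1000.0)
        assert m1.time_axis_ms[0] == -250.0
        assert m1.time_axis_ms[-1] == 1200.0
        pmd = trim_trajectory(t, "PMd", movement_end_ms=1000.0)
        assert pmd.time_axis_ms[0] == -450.0
        assert pmd.time_axis_ms[-1] == 1050.0
        full = trim_trajectory(t, "full")
        assert full.points.shape == t.points.shape
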
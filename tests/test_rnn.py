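"""E/I rate network: nonlinearity, stabilization, simulation, experiments."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trajscale.rnn import (
    RampInput,
    RNNModel,
    build_stabilized_network,
    estimate_duration,
    nonlinearity,
    rotate_projection,
    simulate,
    _spectral_abscissa,
    _smoothed_abscissa_and_gradient,
)


class TestNonlinearity:
    def test_fixed_point_at_zero(self):
        assert nonlinearity(np.array([0.0]))[0] == 0.0

    def test_asymptotes(self):
        assert nonlinearity(np.array([-1e6]))[0] == pytest.approx(-5.0)
        assert nonlinearity(np.array([1e6]))[0] == pytest.approx(65.0)

    def test_unit_slope_at_zero(self):
        eps = 1e-6
        d = (nonlinearity(np.array([eps])) - nonlinearity(np.array([-eps])))
        assert d[0] / (2 * eps) == pytest.approx(1.0, rel=1e-5)

    def test_bounded_and_monotone(self):
        x = np.linspace(-100, 100, 2001)
        y = nonlinearity(x)
        assert np.all(y >= -5.0) and np.all(y <= 65.0)
        inner = nonlinearity(np.linspace(-10, 10, 201))
        assert np.all(inner > -5.0) and np.all(inner < 65.0)
        assert np.all(np.diff(y) >= 0)


class TestStabilization:
    def test_seeded_build_deterministic(self):
        a = build_stabilized_network(n=60, seed=3)
        b = build_stabilized_network(n=60, seed=3)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.p, b.p)

    def test_dale_signs_and_stability(self):
        m = build_stabilized_network(n=80, seed=1)
        assert m.validate_dale()
        assert _spectral_abscissa(m.W - np.eye(m.n)) < 0

    def test_ablating_inhibition_destabilizes(self):
        m = build_stabilized_network(n=80, seed=2)
        W_noinh = m.W.copy()
        W_noinh[:, m.n // 2:] = 0.0
        before = _spectral_abscissa(m.W - np.eye(m.n))
        after = _spectral_abscissa(W_noinh - np.eye(m.n))
        assert after > before

    def test_smoothed_abscissa_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        A = rng.normal(0, 1 / np.sqrt(20), (20, 20)) + 0.3 * np.eye(20)
        s, G = _smoothed_abscissa_and_gradient(A)
        eps = 1e-5
        for (i, j) in [(0, 1), (3, 4)]:
            Ap = A.copy()
            Ap[i, j] += eps
            sp, _ = _smoothed_abscissa_and_gradient(Ap)
            assert (sp - s) / eps == pytest.approx(G[i, j], rel=1e-2)

    def test_scale_fallback_reaches_target(self):
        m = build_stabilized_network(n=80, seed=4, method="scale")
        assert _spectral_abscissa(m.W - np.eye(m.n)) <= -0.2 + 1e-6
        assert m.validate_dale()

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            build_stabilized_network(n=33, seed=0)


class TestSimulate:
    @pytest.fixture(scope="class")
    def model(self):
        return build_stabilized_network(n=80, seed=5)

    def test_zero_input_stays_at_fixed_point(self, model):
        out = simulate(model, RampInput(amplitude=0.0))
        assert np.abs(out["x"]).max() == 0.0

    def test_rates_bounded(self, model):
        out = simulate(model)
        assert out["rates"].min() > 0.0
        assert out["rates"].max() < 70.0

    def test_returns_toward_baseline_after_input(self, model):
        out = simulate(model)
        t = out["t"]
        late = np.linalg.norm(out["x"][t > 3.8], axis=1).mean()
        peak = np.linalg.norm(out["x"], axis=1).max()
        assert late < 0.1 * peak

    def test_linear_regime_matches_closed_form(self, model):
        from scipy.integrate import solve_ivp
        inp = RampInput(amplitude=0.02)
        out = simulate(model, inp)
        tau = model.tau_ms / 1000.0
        sol = solve_ivp(
            lambda t, x: (-x + model.p * inp(np.array([t]))[0]
                          + model.W @ x) / tau,
            (0.0, inp.total_sim_time_s), np.zeros(model.n),
            t_eval=out["t"], rtol=1e-8, atol=1e-11, max_step=0.01)
        rel = (np.sqrt(np.mean((out["x"] - sol.y.T) ** 2))
               / np.sqrt(np.mean(sol.y ** 2)))
        assert rel < 0.01

    def test_dt_convergence(self, model):
        out = simulate(model, store_every=2)
        fine = RNNModel(W=model.W, p=model.p, tau_ms=model.tau_ms, dt_ms=0.25)
        out2 = simulate(fine, store_every=4)
        n = min(out["x"].shape[0], out2["x"].shape[0])
        rel = (np.sqrt(np.mean((out["x"][:n] - out2["x"][:n]) ** 2))
               / np.sqrt(np.mean(out2["x"][:n] ** 2)))
        assert rel < 1e-3


class TestRotateProjection:
    def test_zero_and_full_turn_identity(self):
        p = np.random.default_rng(0).uniform(-1, 1, 40)
        np.testing.assert_array_equal(rotate_projection(p, 0.0), p)
        np.testing.assert_allclose(rotate_projection(p, 360.0), p, atol=1e-12)

    @given(st.integers(0, 500), st.floats(-720, 720))
    def test_isometry(self, seed, angle):
        p = np.random.default_rng(seed).uniform(-1, 1, 30)
        assert np.linalg.norm(rotate_projection(p, angle)) == pytest.approx(
            np.linalg.norm(p))

    def test_rotations_compose_additively(self):
        p = np.random.default_rng(1).uniform(-1, 1, 24)
        ab = rotate_projection(rotate_projection(p, 33.0), 45.0)
        np.testing.assert_allclose(ab, rotate_projection(p, 78.0), atol=1e-12)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            rotate_projection(np.ones(7), 10.0)


class TestEstimateDuration:
    def _excursion(self, t_leave=1.2, t_return=2.4):
        t = np.arange(0.0, 4.0, 0.002)
        r = np.zeros_like(t)
        mid = (t >= t_leave) & (t <= t_return)
        r[mid] = np.sin(np.pi * (t[mid] - t_leave) / (t_return - t_leave))
        pts = np.stack([r * 3.0, np.zeros_like(t)], axis=1)
        return pts, t

    def test_known_geometry_exact(self):
        pts, t = self._excursion(1.2, 2.4)
        est = estimate_duration(pts, t, onset_s=1.0, radius=0.3)
        # re-entry when 3 sin(...) falls back below 0.3
        s = 1 - np.arcsin(0.1) / np.pi
        expected = (1.2 + s * 1.2 - 1.0) * 1000.0
        assert est["duration_ms"] == pytest.approx(expected, abs=5.0)

    def test_never_leaving_flagged(self):
        t = np.arange(0.0, 4.0, 0.01)
        pts = np.zeros((t.size, 2))
        est = estimate_duration(pts, t, onset_s=1.0, radius=0.5)
        assert est["flagged"]

    def test_smaller_radius_never_shortens_duration(self):
        pts, t = self._excursion()
        d20 = estimate_duration(pts, t, onset_s=1.0, radius_percentile=20)
        d10 = estimate_duration(pts, t, onset_s=1.0, radius_percentile=10)
        assert d10["duration_ms"] >= d20["duration_ms"]


class TestExperiments:
    def test_direction_distance_zero_at_zero_angle(self):
        from trajscale.rnn import direction_experiment
        m = build_stabilized_network(n=60, seed=6)
        res = direction_experiment(m, n_rotations=4)
        d_same = [d for (a, d) in res["pair_distances"] if a == 0]
        assert not d_same          # no zero-angle pairs among distinct rotations
        assert all(d > 0 for _, d in res["distance_curve"])

    def test_tau_repeat_identical(self):
        from trajscale.rnn import timeconstant_experiment
        m = build_stabilized_network(n=60, seed=7)
        r1 = timeconstant_experiment(m, taus_ms=(200.0, 200.0))
        np.testing.assert_array_equal(r1["trajectories"][0],
                                      r1["trajectories"][1])
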
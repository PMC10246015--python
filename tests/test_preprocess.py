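"""Smoothing, segmentation, condition binning, soft-normalization."""

import numpy as np
import pytest

from trajscale.preprocess import (
    ConditionTensor,
    SmoothingSpec,
    condition_average,
    filter_and_normalize,
    median_isi_sigma,
    segment_movements,
    smooth_spikes,
    preprocess_session,
)


class TestSmoothing:
    def test_single_spike_gaussian_bump(self):
        spec = SmoothingSpec(sigma_ms=50.0, rate_sample_interval_ms=10.0)
        times, rates = smooth_spikes([np.array([1.0])], spec, 0.0, 2.0)
        peak = rates[0].max()
        expected = 1.0 / (0.05 * np.sqrt(2 * np.pi))   # ~7.98 spikes/s
        assert abs(peak - expected) / expected < 0.02
        assert abs(times[np.argmax(rates[0])] - 1.0) < 0.011

    def test_empty_train_gives_zero_series(self):
        _, rates = smooth_spikes([np.array([])], SmoothingSpec(50.0), 0.0, 1.0)
        assert np.all(rates == 0)

    def test_mass_conservation_interior(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0.5, 9.5, 100))   # >= 3 sigma from edges
        spec = SmoothingSpec(sigma_ms=50.0, rate_sample_interval_ms=10.0)
        times, rates = smooth_spikes([spikes], spec, 0.0, 10.0)
        integral = np.trapezoid(rates[0], times)
        assert abs(integral - 100) <= 1.0

    def test_rates_nonnegative(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 5, 40))
        _, rates = smooth_spikes([spikes], SmoothingSpec(30.0), 0.0, 5.0)
        assert np.all(rates >= 0)


class TestMedianIsiSigma:
    def test_hand_computed_median(self):
        spec = median_isi_sigma([np.array([0.0, 0.1, 0.2, 0.4])])
        assert spec.sigma_ms == pytest.approx(100.0)

    def test_two_spikes_boundary_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            spec = median_isi_sigma([np.array([0.0, 1.0])])
        assert spec.sigma_ms == pytest.approx(1000.0)

    def test_too_few_spikes_raises(self):
        with pytest.raises(ValueError):
            median_isi_sigma([np.array([0.5]), np.array([])])

    def test_default_synthetic_sigma_in_reported_range(self, noisy_pipeline):
        # the recorded populations had median-ISI sigmas of 36-86 ms
        assert 36.0 <= noisy_pipeline["spec"].sigma_ms <= 86.0

    def test_pooling_modes_differ_consistently(self):
        trains = [np.array([0, 0.01, 0.02, 0.03]), np.array([0, 1.0, 2.0])]
        pooled = median_isi_sigma(trains, pooling="pooled")
        per_unit = median_isi_sigma(trains, pooling="per_unit")
        assert pooled.sigma_ms == pytest.approx(10.0)
        assert per_unit.sigma_ms == pytest.approx(505.0)


class TestSegmentation:
    def test_onset_recovered_within_one_sample(self, balanced_session):
        s = balanced_session
        events = segment_movements(s.hand_times, s.hand_position,
                                   s.target_events)
        gt = s.ground_truth
        kin_dt = 1.0 / s.config.kinematics_rate
        onsets = np.array([e.onset_time for e in events])
        assert len(events) == len(gt)
        err = np.abs(onsets - gt.onset.to_numpy())
        assert np.quantile(err, 0.95) <= kin_dt

    def test_direction_bins_match_ground_truth(self, balanced_session):
        s = balanced_session
        events = segment_movements(s.hand_times, s.hand_position,
                                   s.target_events)
        gt_bins = (np.round(s.ground_truth.direction_deg / 45).astype(int)) % 8
        ev_bins = np.array([e.direction_bin for e in events])
        assert np.mean(gt_bins.to_numpy() == ev_bins) >= 0.99

    def test_duration_rounding_rule(self, balanced_session):
        # a 240 ms movement belongs to bin 0 and rounds to a 300 ms end
        s = balanced_session
        events = [e for e in segment_movements(
            s.hand_times, s.hand_position, s.target_events) if not e.excluded]
        for e in events:
            lo = 200 + 100 * e.duration_bin
            assert lo <= e.duration_ms <= lo + 100
            assert e.rounded_duration_ms == lo + 100
        any_bin0 = [e for e in events if e.duration_bin == 0]
        assert any_bin0 and all(e.rounded_duration_ms == 300.0
                                for e in any_bin0)

    def test_due_east_reach_is_direction_zero(self):
        import pandas as pd
        t = np.arange(0.0, 3.0, 0.01)
        pos = np.zeros((t.size, 2)) + 5.0
        sl = (t >= 1.0) & (t < 1.5)
        pos[sl, 0] = 5.0 + 10.0 * (t[sl] - 1.0) / 0.5   # 20 cm/s due +x
        pos[t >= 1.5, 0] = 10.0
        ev = pd.DataFrame([dict(trial=0, reach=1, t_appear=0.9,
                                target_x=10.0, target_y=5.0, success=True)])
        # previous target = start position for reach>0 is supplied via an
        # initial event at the start location
        ev0 = pd.DataFrame([dict(trial=0, reach=0, t_appear=0.01,
                                 target_x=5.0, target_y=5.0, success=True),
                            ]).assign()
        events = segment_movements(t, pos, pd.concat([ev0, ev]))
        east = events[-1]
        assert east.direction_deg == pytest.approx(0.0, abs=1e-6)
        assert east.direction_bin == 0

    def test_never_crossing_threshold_flagged(self):
        import pandas as pd
        t = np.arange(0.0, 2.0, 0.01)
        pos = np.tile([5.0, 5.0], (t.size, 1))          # hand never moves
        ev = pd.DataFrame([dict(trial=0, reach=0, t_appear=0.5,
                                target_x=10.0, target_y=5.0, success=True)])
        events = segment_movements(t, pos, ev)
        assert events[0].excluded
        assert events[0].exclusion_reason == "no_threshold_crossing"


class TestConditionAverage:
    def test_partition_and_count_conservation(self, noisy_pipeline):
        tensor = noisy_pipeline["tensor"]
        events = [e for e in noisy_pipeline["events"] if not e.excluded]
        assert sum(tensor.n_movements) == len(events)
        assert len(tensor.condition_labels) == 32

    def test_two_identical_movements_average_to_either(self):
        rate_times = np.arange(0.0, 20.0, 0.01)
        rates = np.vstack([np.sin(rate_times), np.cos(rate_times)]) + 2.0
        from trajscale.preprocess import MovementEvent
        mk = lambda onset: MovementEvent(
            onset_time=onset, end_time=onset + 0.25, duration_ms=250.0,
            direction_deg=10.0, direction_bin=0, duration_bin=0,
            max_speed=20.0, distance=5.0, rounded_duration_ms=300.0)
        # identical rates around both onsets: use a periodic signal with
        # onsets one period apart
        period = 2 * np.pi
        tensor = condition_average(rate_times, rates,
                                   [mk(3.0), mk(3.0 + period)])
        single = condition_average(rate_times, rates, [mk(3.0)])
        np.testing.assert_allclose(tensor.values[0], single.values[0],
                                   atol=1e-4)

    def test_epoch_spans_minus500_to_rounded_plus300(self, noisy_pipeline):
        tensor = noisy_pipeline["tensor"]
        for (d, u), axis in zip(tensor.condition_labels, tensor.time_axes):
            assert axis[0] == -500.0
            rounded = 200.0 + 100.0 * (u + 1)
            assert axis[-1] == pytest.approx(rounded + 300.0)

    def test_speed_scheme_common_base_and_median_split(self, balanced_session):
        tensor, _, _ = preprocess_session(balanced_session, scheme="speed")
        lens = {a.size for a in tensor.time_axes}
        assert len(lens) == 1
        assert set(u for _, u in tensor.condition_labels) <= {0, 1}


class TestFilterAndNormalize:
    def _tensor(self, values):
        axes = [np.arange(-500.0, 610.0, 10.0)] * len(values)
        n_t = axes[0].size
        vals = [np.tile(np.asarray(v, float)[:, None], (1, n_t))
                for v in values]
        return ConditionTensor([(i, 0) for i in range(len(values))], vals,
                               axes, [1] * len(values), "duration", 10.0)

    def test_low_count_unit_dropped(self):
        # unit 0: ~0.04 spikes total over epochs; unit 1: plenty
        t = self._tensor([[0.003, 20.0]])
        out = filter_and_normalize(t)
        assert out.n_units == 1
        assert list(out.normalization["kept_units"]) == [1]

    def test_constant_rate_divided_by_five(self):
        t = self._tensor([[10.0, 10.0]])
        out = filter_and_normalize(t)
        np.testing.assert_allclose(out.values[0], 10.0 / 5.0)

    def test_range_45_gives_divisor_50(self):
        axes = [np.arange(-500.0, 610.0, 10.0)] * 2
        n_t = axes[0].size
        v1 = np.full((1, n_t), 5.0)
        v2 = np.full((1, n_t), 50.0)
        t = ConditionTensor([(0, 0), (1, 0)], [v1, v2], axes, [1, 1],
                            "duration", 10.0)
        out = filter_and_normalize(t)
        assert out.normalization["divisor"][0] == pytest.approx(50.0)

    def test_normalized_range_below_one(self, noisy_pipeline):
        tensor = noisy_pipeline["tensor"]
        stacked = np.hstack(tensor.values)
        rng_ = stacked.max(axis=1) - stacked.min(axis=1)
        assert np.all(rng_ < 1.0)

    def test_all_units_filtered_raises(self):
        t = self._tensor([[0.001, 0.001]])
        with pytest.raises(ValueError):
            filter_and_normalize(t)
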
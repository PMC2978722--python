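import numpy as np
import pytest

from nirspeed import (DriftParams, EventSchedule, PipelineConfig,
                      SimulationSpec, accuracy, cohort_report,
                      generate_recording, label_timepoints,
                      onset_offset_delays, sweep_channels,
                      sweep_history, sweep_signals)


class TestAccuracy:
    def test_perfect_and_inverted(self):
        truth = np.array([1, -1, 1, -1])
        assert accuracy(truth, truth) == 1.0
        assert accuracy(-truth, truth) == 0.0

    def test_hand_count(self):
        truth = np.ones(10, dtype=int)
        pred = truth.copy()
        pred[[1, 4, 7]] = -1
        assert accuracy(pred, truth) == pytest.approx(0.7)

    def test_mask_restricts_scoring(self):
        truth = np.array([1, 1, -1, -1])
        pred = np.array([1, -1, -1, 1])
        mask = np.array([True, False, True, False])
        assert accuracy(pred, truth, mask) == 1.0

    def test_no_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([1]), np.array([1]), np.array([False]))

    def test_always_rest_scores_rest_fraction(self):
        ev = EventSchedule([(20 + 30 * i, 10) for i in range(4)], 140)
        truth = label_timepoints(ev, 1400, 10.0)
        pred = np.full(1400, -1)
        assert accuracy(pred, truth) == pytest.approx((truth == -1).mean())


class TestOnsetOffsetDelays:
    def test_perfect_predictor_zero_delays(self):
        ev = EventSchedule([(10, 5), (25, 5)], 40)
        pred = label_timepoints(ev, 400, 10.0)
        res = onset_offset_delays(pred, ev, 10.0)
        np.testing.assert_array_equal(res.onset_delays_s, [0.0, 0.0])
        np.testing.assert_array_equal(res.offset_delays_s, [0.0, 0.0])
        assert res.censor_count == 0

    def test_index_arithmetic_toy(self):
        """Block onset at sample 100; first active prediction at 140."""
        ev = EventSchedule([(10, 5)], 30)
        pred = np.full(300, -1)
        pred[140:160] = 1
        res = onset_offset_delays(pred, ev, 10.0)
        assert res.onset_delays_s[0] == pytest.approx(4.0)
        assert res.offset_delays_s[0] == pytest.approx(1.0)

    def test_always_rest_censors_all_onsets(self):
        ev = EventSchedule([(10, 5), (25, 5)], 40)
        res = onset_offset_delays(np.full(400, -1), ev, 10.0)
        assert res.onset_censored.all()
        assert res.censor_count == 2  # offsets detect immediately
        assert np.isnan(res.mean_onset_s)

    def test_delays_bounded_by_trial_interval(self, quick_sim, cfg):
        from nirspeed import FeatureSpec, evaluate_feature_space
        rec, events, _ = quick_sim
        res = evaluate_feature_space(
            rec, events, cfg, FeatureSpec(channels=("ch1",), history_s=1.0))
        interval = events.blocks[1][0] - events.blocks[0][0]
        for d in np.concatenate([res.delays.onset_delays_s, res.delays.offset_delays_s]):
            assert np.isnan(d) or 0 <= d < interval
        # censoring is exhaustive: one entry per test block
        assert len(res.delays.onset_delays_s) == 3

    def test_standard_error_uses_sample_variance(self):
        res = onset_offset_delays(
            np.full(400, -1), EventSchedule([(10, 5), (25, 5)], 40), 10.0)
        # offsets are [0, 0]: SE = 0; onsets censored: SE undefined
        assert res.se_offset_s == 0.0
        assert np.isnan(res.se_onset_s)


@pytest.fixture(scope="module")
def sim_pair():
    spec = SimulationSpec(n_channels=4, n_trials=6, seed=21)
    rec, events, amps = generate_recording(spec)
    return rec, events


class TestSweeps:
    def test_history_improves_accuracy(self, sim_pair, cfg):
        rec, events = sim_pair
        sweep = sweep_history(rec, events, cfg, [0.0, 1.0])
        assert sweep.accuracies[1] >= sweep.accuracies[0]

    def test_single_value_sweep(self, sim_pair, cfg):
        rec, events = sim_pair
        sweep = sweep_history(rec, events, cfg, [0.5])
        assert len(sweep.values) == 1 and sweep.optimum == 0.5

    def test_sweep_determinism(self, sim_pair, cfg):
        rec, events = sim_pair
        s1 = sweep_history(rec, events, cfg, [0.0, 1.0])
        s2 = sweep_history(rec, events, cfg, [0.0, 1.0])
        assert s1.accuracies == s2.accuracies
        np.testing.assert_array_equal(s1.mean_onset_s, s2.mean_onset_s)

    def test_signal_sweep_structure_and_total_worst(self, sim_pair, cfg):
        rec, events = sim_pair
        sweep = sweep_signals(rec, events, cfg)
        assert sweep.values == ["oxy", "deoxy", "both", "total", "cbsi"]
        acc = dict(zip(sweep.values, sweep.accuracies))
        assert acc["total"] <= acc["both"]

    def test_oxy_deoxy_symmetric_when_noiseless(self, cfg):
        spec = SimulationSpec(n_channels=2, n_trials=6, noise_sd=0.0,
                              drift=DriftParams(amplitude=0.0), seed=5)
        rec, events, _ = generate_recording(spec)
        sweep = sweep_signals(rec, events, cfg)
        acc = dict(zip(sweep.values, sweep.accuracies))
        assert abs(acc["oxy"] - acc["deoxy"]) <= 0.02 + 1e-9

    def test_low_accuracy_delays_undefined(self, sim_pair):
        rec, events = sim_pair
        strict = PipelineConfig(delay_accuracy_floor=1.0)  # nothing qualifies
        sweep = sweep_signals(rec, events, strict)
        assert all(np.isnan(v) for v in sweep.mean_onset_s)

    def test_channel_sweep_consistency(self, sim_pair, cfg):
        rec, events = sim_pair
        sweep = sweep_channels(rec, events, cfg, max_channels=3)
        assert sweep.values == [1, 2, 3]
        assert sweep.optimum == sweep.values[int(np.argmax(sweep.accuracies))]
        single = sweep_channels(rec, events, cfg, max_channels=1)
        assert single.accuracies[0] == sweep.accuracies[0]

    def test_channel_inclusion_helps_on_average(self, cfg):
        """With 3 truly active channels among 12 and a noise-limited
        single-channel decoder, accuracy at 3 channels beats 1 channel on
        average over seeds (spatial averaging pays off only when one
        channel alone is not already ceiling-limited by the hemodynamic
        delay)."""
        amps = (1.0, 0.8, 0.6) + (0.0,) * 9
        deltas = []
        for seed in range(10):
            spec = SimulationSpec(n_channels=12, noise_sd=0.5,
                                  channel_amplitudes=amps, seed=seed)
            rec, events, _ = generate_recording(spec)
            sweep = sweep_channels(rec, events, cfg, max_channels=3)
            deltas.append(sweep.accuracies[2] - sweep.accuracies[0])
        assert np.mean(deltas) >= 0

    def test_max_channels_validated(self, sim_pair, cfg):
        rec, events = sim_pair
        with pytest.raises(ValueError):
            sweep_channels(rec, events, cfg, max_channels=99)


@pytest.fixture(scope="module")
def small_cohort_report():
    cohort = []
    for seed in (0, 1):
        spec = SimulationSpec(n_channels=4, n_trials=6, seed=seed)
        rec, events, _ = generate_recording(spec)
        cohort.append((rec, events))
    cfg = PipelineConfig(max_channels=3)
    return cohort_report(cohort, cfg)


class TestFullPipeline:
    def test_schema_has_four_conditions(self, small_cohort_report):
        for rec_report in small_cohort_report["per_recording"]:
            assert list(rec_report["conditions"]) == [
                "baseline", "history", "oxy_deoxy", "multichannel"]

    def test_full_features_reduce_onset_delay(self, small_cohort_report):
        agg = small_cohort_report["aggregate"]
        assert (agg["multichannel"]["mean_onset_delay_s"]
                < agg["baseline"]["mean_onset_delay_s"])

    def test_aggregate_is_mean_of_per_recording(self, small_cohort_report):
        rep = small_cohort_report
        vals = [r["conditions"]["history"]["accuracy"] for r in rep["per_recording"]]
        assert rep["aggregate"]["history"]["accuracy"] == pytest.approx(np.mean(vals))

    def test_selected_channel_count_is_argmax(self, small_cohort_report):
        for rec_report in small_cohort_report["per_recording"]:
            assert 1 <= rec_report["n_channels_selected"] <= 3
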
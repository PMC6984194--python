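"""Time-frequency analysis, ERD statistics and the CSP quality rubric."""

import numpy as np
import pytest

from mibci import decode, erdlab
from mibci.erdlab import (
    band_power_traces,
    csp_component_segments,
    erd_latency,
    mean_smr_change,
    morlet_tf,
    percent_power_change,
    summarize_quality,
)

FS = 500.0


def _segment(signal_fn, seconds=5.0, t0=-2.0):
    t = t0 + np.arange(int(seconds * FS)) / FS
    return signal_fn(t), t


class TestMorlet:
    def test_frequency_selectivity(self):
        seg, t = _segment(lambda t: np.sin(2 * np.pi * 20 * t))
        power, times, freqs = morlet_tf(seg, FS, times=t)
        mid = (times > -0.3) & (times < 1.8)
        p20 = power[0, freqs == 20][0, mid].mean()
        p35 = power[0, freqs == 35][0, mid].mean()
        assert p20 >= 10 * p35

    def test_zero_signal_zero_power(self):
        seg, t = _segment(lambda t: np.zeros_like(t))
        power, _, _ = morlet_tf(seg, FS, times=t)
        assert np.allclose(power, 0.0)

    def test_am_tone_power_tracks_squared_envelope(self):
        env = lambda t: 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        seg, t = _segment(lambda t: env(t) * np.sin(2 * np.pi * 15 * t))
        power, times, freqs = morlet_tf(seg, FS, times=t)
        trace = power[0, freqs == 15][0]
        inner = (times > -0.5) & (times < 2.0)
        r = np.corrcoef(trace[inner], env(times[inner]) ** 2)[0, 1]
        assert r >= 0.95

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            morlet_tf(np.zeros(300), FS)


class TestPercentPowerChange:
    def _map(self, scale_after_zero):
        """Raw power map: baseline power 1, then scaled after t = 0."""
        times = np.arange(-0.5, 2.0, 0.02)
        power = np.ones((1, 3, len(times)))
        power[:, :, times >= 0] = scale_after_zero
        return power, times, np.array([10.0, 15.0, 20.0])

    def test_power_equal_to_baseline_gives_zero(self):
        tf = percent_power_change(*self._map(1.0))
        assert np.allclose(tf.values, 0.0, atol=1e-12)

    def test_amplitude_halved_gives_minus_75(self):
        tf = percent_power_change(*self._map(0.25))  # amplitude / 2 => power / 4
        after = tf.values[:, tf.times >= 0]
        assert np.allclose(after, -75.0, atol=1e-9)

    def test_baseline_db_change_is_exactly_zero_mean(self):
        rng = np.random.default_rng(0)
        times = np.arange(-0.8, 2.3, 0.01)
        power = rng.gamma(2.0, 1.0, size=(20, 5, len(times)))
        tf = percent_power_change(power, times, np.arange(5))
        base = (tf.times >= -0.5) & (tf.times <= 0)
        assert np.allclose(tf.db_change[:, :, base].mean(axis=-1), 0.0, atol=1e-9)

    def test_percent_change_bounded_below(self):
        rng = np.random.default_rng(1)
        times = np.arange(-0.5, 2.0, 0.01)
        power = rng.gamma(1.0, 1.0, size=(5, 4, len(times)))
        tf = percent_power_change(power, times, np.arange(4))
        assert tf.values.min() >= -100.0

    def test_injected_depth_recovered(self, training50):
        cfg, rec, events = training50  # depth 0.4, latency 0.4
        c3 = np.zeros(rec.n_channels)
        c3[rec.ch_names.index("C3")] = 1.0
        segs, labels, times = csp_component_segments(rec, events, c3)
        power, t_crop, freqs = morlet_tf(segs[labels == "flexion"], cfg.fs, times=times)
        tf = percent_power_change(power, t_crop, freqs)
        assert mean_smr_change(tf) == pytest.approx(-40.0, abs=5.0)


class TestMeanSMRChange:
    def test_empty_submatrix_rejected(self):
        times = np.arange(-0.5, 2.0, 0.02)
        tf = percent_power_change(np.ones((1, 3, len(times))), times, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            mean_smr_change(tf, band=(10, 25))

    def test_monotone_in_depth(self):
        times = np.arange(-0.5, 2.0, 0.02)
        freqs = np.arange(10.0, 26.0)
        vals = []
        for depth in (0.2, 0.35, 0.5):
            power = np.ones((1, len(freqs), len(times)))
            power[:, :, times >= 0.3] = 1.0 - depth
            tf = percent_power_change(power, times, freqs)
            vals.append(mean_smr_change(tf))
        assert vals[0] > vals[1] > vals[2]


class TestERDLatency:
    def _step_traces(self, depth, onset, n=40, jitter=0.0, rng=None):
        times = np.arange(-0.5, 2.0, 0.01)
        traces = np.zeros((n, len(times)))
        for i in range(n):
            o = onset + (rng.normal(0, jitter) if jitter else 0.0)
            traces[i, times >= o] = -depth
        return traces, times

    def test_step_erd_recovers_onset(self):
        traces, times = self._step_traces(50.0, 0.6)
        assert erd_latency(traces, times) == pytest.approx(0.6, abs=0.011)

    def test_depth_below_threshold_undefined(self):
        traces, times = self._step_traces(20.0, 0.6)
        assert np.isnan(erd_latency(traces, times))

    def test_20th_percentile_robust_to_late_outliers(self):
        rng = np.random.default_rng(2)
        traces, times = self._step_traces(50.0, 0.5, n=40, jitter=0.02, rng=rng)
        out_traces, _ = self._step_traces(50.0, 1.8, n=10)
        with_outliers = np.vstack([traces, out_traces])
        base = erd_latency(traces, times)
        contaminated = erd_latency(with_outliers, times)
        mean_shift = 10 / 50 * (1.8 - 0.5)
        assert abs(contaminated - base) < mean_shift / 3

    def test_latency_scale_invariant(self, training50):
        cfg, rec, events = training50
        c3 = np.zeros(rec.n_channels)
        c3[rec.ch_names.index("C3")] = 1.0
        segs, labels, times = csp_component_segments(rec, events, c3)
        power, t_crop, freqs = morlet_tf(segs[labels == "flexion"][:20], cfg.fs, times=times)
        t1 = band_power_traces(power, t_crop, freqs)
        t2 = band_power_traces(power * 7.3, t_crop, freqs)
        assert erd_latency(t1, t_crop) == erd_latency(t2, t_crop)
        np.testing.assert_allclose(t1, t2, atol=1e-8)


class TestComponentSegments:
    def test_full_block_yields_100_segments(self, training50):
        _, rec, events = training50
        w = np.zeros(rec.n_channels)
        w[rec.ch_names.index("C3")] = 1.0
        segs, labels, times = csp_component_segments(rec, events, w)
        assert len(segs) == 100
        assert int((labels == "flexion").sum()) == 50
        assert times[0] == pytest.approx(-2.0)

    def test_unit_filter_reproduces_channel(self, training50):
        _, rec, events = training50
        idx = rec.ch_names.index("CZ")
        w = np.zeros(rec.n_channels)
        w[idx] = 1.0
        segs, labels, _ = csp_component_segments(rec, events, w, z_thresh=np.inf)
        first = sorted(e for e in events if e.label.endswith(("flexion_onset", "extension_onset")))[0]
        s0 = int((first.time - 2.0) * rec.fs)
        np.testing.assert_array_equal(segs[0], rec.data[idx, s0:s0 + len(segs[0])])

    def test_wrong_filter_length_rejected(self, training50):
        _, rec, events = training50
        with pytest.raises(ValueError):
            csp_component_segments(rec, events, np.ones(3))


class TestQualityRubric:
    def test_strong_planted_data_scores_twelve(self, strong_bank, strong_epochs):
        report = erdlab.csp_quality_score(
            strong_bank.csp_models["Y_OF"], strong_bank.csp_models["Y_CE"], strong_epochs)
        assert report.total == 12
        assert report.plausible

    def test_pure_noise_fails_discriminability_criteria(self, rng):
        from mibci.sigproc import EpochSet, fit_csp

        ch = [f"ch{i}" for i in range(8)]
        labels = np.array((["flexion", "rest_open", "extension", "rest_closed"] * 25),
                          dtype=object)
        epochs = EpochSet(data=rng.standard_normal((100, 8, 400)), labels=labels,
                          fs=FS, ch_names=ch, onsets=np.arange(100, dtype=float))
        of = fit_csp(epochs.for_classes("flexion"), epochs.for_classes("rest_open"))
        ce = fit_csp(epochs.for_classes("extension"), epochs.for_classes("rest_closed"))
        report = erdlab.csp_quality_score(of, ce, epochs)
        for flags in report.criteria.values():
            assert not flags[2] and not flags[3] and not flags[4]  # criteria 3-5
        assert report.total <= 6
        assert not report.plausible

    def test_plausibility_cutoff_inclusive_at_ten(self):
        ten = summarize_quality({"flexion": [True] * 6, "extension": [True] * 4 + [False] * 2})
        nine = summarize_quality({"flexion": [True] * 5 + [False], "extension": [True] * 4 + [False] * 2})
        assert ten.total == 10 and ten.plausible
        assert nine.total == 9 and not nine.plausible

    def test_too_few_trials_scores_criteria_false(self, strong_bank, strong_epochs):
        small = strong_epochs.subset(np.arange(6))
        with pytest.warns(UserWarning, match="too few trials"):
            flags = erdlab.score_filter(
                strong_bank.csp_models["Y_OF"],
                strong_bank.csp_models["Y_OF"].selected_[0],
                small, ("flexion", "rest_open"))
        assert flags[2] is False and flags[3] is False and flags[5] is False


class TestChooseComponent:
    def test_prefers_desynchronizing_component(self, strong_bank, strong_epochs, strong_training):
        cfg, _, _ = strong_training
        model = strong_bank.csp_models["Y_OF"]
        comp = erdlab.choose_component(model, strong_epochs, decode.CLASS_PAIRS["Y_OF"])
        pair = strong_epochs.for_classes("flexion", "rest_open")
        from mibci.sigproc import logvar_features

        feats = logvar_features(pair, model)
        col = model.selected_.index(comp)
        assert (feats[pair.labels == "flexion", col].mean()
                < feats[pair.labels == "rest_open", col].mean())
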
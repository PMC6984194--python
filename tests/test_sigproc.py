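"""Filtering, epoching, artifact rejection and CSP algebra."""

import numpy as np
import pytest
from scipy import signal

from mibci.io import Recording
from mibci.sigproc import (
    CSP,
    EpochSet,
    bandpass,
    epoch_training,
    fit_csp,
    logvar_features,
    reject_artifacts,
    select_plausible_components,
)


def _sine_recording(freq, fs=500.0, seconds=4.0, n_channels=2):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording(data=data, fs=fs)


class TestBandpass:
    def test_stopband_sine_attenuated(self):
        out = bandpass(_sine_recording(4.0), 8, 28)
        mid = out.data[0, 500:-500]
        assert np.abs(mid).max() <= 0.1

    def test_passband_sine_preserved(self):
        out = bandpass(_sine_recording(15.0), 8, 28)
        mid = out.data[0, 500:-500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_white_noise_band_ratio(self, rng):
        rec = Recording(data=rng.standard_normal((1, 50_000)), fs=500.0)
        out = bandpass(rec, 8, 28)
        f, p = signal.welch(out.data[0], fs=500.0, nperseg=1024)
        in_band = p[(f >= 8) & (f <= 28)].sum()
        assert in_band / p.sum() >= 0.9

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            bandpass(_sine_recording(10.0), 8, 300)
        with pytest.raises(ValueError):
            bandpass(_sine_recording(10.0), 0, 28)

    def test_causal_mode_delays_but_preserves_band(self):
        rec = _sine_recording(15.0, seconds=6.0)
        causal = bandpass(rec, 8, 28, mode="causal").data[0]
        zero_phase = bandpass(rec, 8, 28, mode="zero_phase").data[0]
        assert not np.allclose(causal, zero_phase)
        assert np.abs(causal[1000:-1000]).max() == pytest.approx(1.0, rel=0.05)


class TestEpoching:
    def test_training_epoch_counts(self, training50):
        _, rec, events = training50
        epochs = epoch_training(rec, events)
        counts = {c: int((epochs.labels == c).sum()) for c in set(epochs.labels)}
        assert counts == {"flexion": 50, "extension": 50, "rest_open": 50, "rest_closed": 50}
        assert epochs.data.shape[2] == int(1.5 * rec.fs)

    def test_empty_event_list(self, training50):
        _, rec, _ = training50
        epochs = epoch_training(rec, [])
        assert epochs.n_trials == 0

    def test_truncated_run_drops_epoch(self, training50):
        _, rec, events = training50
        last_ext = max(e.time for e in events if e.label == "extension_onset")
        cut = rec.copy_with(rec.data[:, : int((last_ext + 0.5) * rec.fs)])
        epochs = epoch_training(cut, events)
        assert int((epochs.labels == "extension").sum()) == 49
        assert int((epochs.labels == "flexion").sum()) == 50


class TestArtifactRejection:
    def _epochs(self, rng, n=40):
        data = rng.standard_normal((n, 4, 200))
        return EpochSet(data=data, labels=np.array(["flexion"] * n, dtype=object), fs=500.0)

    def test_clean_epochs_not_rejected(self, rng):
        cleaned, report = reject_artifacts(self._epochs(rng))
        assert report["n_rejected"] == 0
        assert cleaned.n_trials == 40

    def test_spike_epoch_rejected_exactly(self, rng):
        epochs = self._epochs(rng)
        epochs.data[7] *= 10.0
        cleaned, report = reject_artifacts(epochs)
        assert report["rejected_indices"] == [7]
        assert cleaned.n_trials == 39

    def test_infinite_threshold_is_identity(self, rng):
        epochs = self._epochs(rng)
        epochs.data[3] *= 50.0
        cleaned, report = reject_artifacts(epochs, z_thresh=np.inf)
        assert report["n_rejected"] == 0
        assert cleaned.n_trials == 40

    def test_empty_input_raises(self):
        empty = EpochSet(data=np.empty((0, 4, 200)), labels=np.array([]), fs=500.0)
        with pytest.raises(ValueError):
            reject_artifacts(empty)


def _two_class_epochs(rng, var_a, var_b, n=30, n_channels=2, n_samples=400):
    a = rng.standard_normal((n, n_channels, n_samples)) * np.sqrt(var_a)[:, None]
    b = rng.standard_normal((n, n_channels, n_samples)) * np.sqrt(var_b)[:, None]
    X = np.concatenate([a, b])
    y = np.array(["A"] * n + ["B"] * n, dtype=object)
    return X, y


class TestCSP:
    def test_identical_classes_give_half_eigenvalues(self, rng):
        X, y = _two_class_epochs(rng, np.ones(2), np.ones(2), n=100)
        model = CSP().fit(X, y)
        assert np.allclose(model.eigenvalues_, 0.5, atol=0.05)

    def test_two_channel_toy_top_filter_on_loud_channel(self, rng):
        # class A has 10x variance on channel 0 only: the top filter must
        # align with channel 0 (closed-form 2x2 generalized eigenproblem)
        X, y = _two_class_epochs(rng, np.array([10.0, 1.0]), np.ones(2), n=200)
        model = CSP(class_order=("A", "B")).fit(X, y)
        w = model.filters_[:, 0]
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine >= 0.99
        # trace-normalized eigenvalue: (10/11) / (10/11 + 1/2) ~ 0.645
        assert model.eigenvalues_[0] == pytest.approx(0.645, abs=0.03)

    def test_simultaneous_diagonalization(self, rng):
        X, y = _two_class_epochs(rng, np.array([5.0, 1.0, 2.0]), np.ones(3),
                                 n=50, n_channels=3)
        model = CSP(class_order=("A", "B")).fit(X, y)

        def class_cov(data):
            covs = [t @ t.T / np.trace(t @ t.T) for t in data]
            return np.mean(covs, axis=0)

        W = model.filters_
        for cov in (class_cov(X[y == "A"]), class_cov(X[y == "B"])):
            proj = W.T @ cov @ W
            off = proj - np.diag(np.diag(proj))
            assert np.linalg.norm(off) < 1e-8

    def test_class_swap_symmetry(self, rng):
        X, y = _two_class_epochs(rng, np.array([4.0, 1.0, 1.5]), np.ones(3),
                                 n=40, n_channels=3)
        ab = CSP(class_order=("A", "B")).fit(X, y)
        ba = CSP(class_order=("B", "A")).fit(X, y)
        assert np.allclose(np.sort(ba.eigenvalues_), np.sort(1.0 - ab.eigenvalues_), atol=1e-10)
        assert np.allclose(np.abs(ab.filters_), np.abs(ba.filters_[:, ::-1]), atol=1e-8)

    def test_channel_permutation_invariance(self, rng):
        X, y = _two_class_epochs(rng, np.array([6.0, 1.0, 2.0, 1.0]), np.ones(4),
                                 n=40, n_channels=4)
        perm = np.array([2, 0, 3, 1])
        model = CSP(class_order=("A", "B")).fit(X, y)
        model_p = CSP(class_order=("A", "B")).fit(X[:, perm, :], y)
        feats = model.transform(X)
        feats_p = model_p.transform(X[:, perm, :])
        assert np.allclose(feats, feats_p, atol=1e-8)

    def test_planted_topography_recovered(self, strong_bank, strong_training):
        cfg, _, _ = strong_training
        model = strong_bank.csp_models["Y_OF"]
        topo = cfg.topographies["flexion"]
        best = max(model.selected_,
                   key=lambda j: abs(np.corrcoef(model.patterns_[:, j], topo)[0, 1]))
        r = np.corrcoef(model.patterns_[:, best], topo)[0, 1]
        assert abs(r) >= 0.9

    def test_candidates_are_first_and_last_four(self, strong_bank):
        model = strong_bank.csp_models["Y_OF"]
        n = model.filters_.shape[1]
        assert n == 24
        assert model.candidates_ == [0, 1, 2, 3, 20, 21, 22, 23]

    def test_too_few_epochs_raises(self, rng):
        X, y = _two_class_epochs(rng, np.ones(2), np.ones(2), n=1)
        with pytest.raises(ValueError):
            CSP().fit(X, y)

    def test_rank_deficient_needs_shrinkage(self, rng):
        # duplicated channel makes the pooled covariance singular
        base = rng.standard_normal((20, 1, 300))
        X = np.concatenate([base, base], axis=1)
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            CSP().fit(X, y)
        model = CSP(shrinkage=0.1).fit(X, y)  # remediation works
        assert np.all(np.isfinite(model.filters_))


class TestLogVarFeatures:
    def test_unit_variance_gives_zero_feature(self, rng):
        n, c, s = 20, 2, 20_000
        X = rng.standard_normal((n, c, s))
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        model = CSP(class_order=("A", "B")).fit(X, y)
        model.selected_ = [0]
        model.filters_ = np.eye(c)[:, :1]  # identity projection, channel 0
        feats = model.transform(X)
        assert np.allclose(feats, 0.0, atol=0.05)

    def test_doubling_amplitude_adds_log4(self, strong_epochs, strong_bank):
        model = strong_bank.csp_models["Y_EF"]
        feats = logvar_features(strong_epochs, model)
        doubled = strong_epochs.subset(np.arange(strong_epochs.n_trials))
        doubled.data = doubled.data * 2.0
        feats2 = logvar_features(doubled, model)
        assert np.allclose(feats2 - feats, np.log(4.0), atol=1e-9)

    def test_planted_classes_separate_by_one_nat(self, strong_epochs, strong_bank):
        model = strong_bank.csp_models["Y_OF"]
        pair = strong_epochs.for_classes("flexion", "rest_open")
        feats = logvar_features(pair, model)
        gaps = [abs(feats[pair.labels == "flexion", j].mean()
                    - feats[pair.labels == "rest_open", j].mean())
                for j in range(feats.shape[1])]
        assert max(gaps) >= 1.0


class TestComponentSelection:
    def _model_with_patterns(self, strong_epochs, pattern):
        pair = strong_epochs.for_classes("flexion", "rest_open")
        model = fit_csp(pair.for_classes("flexion"), pair.for_classes("rest_open"))
        model.patterns_ = np.tile(pattern[:, None], (1, model.patterns_.shape[1]))
        return model

    def test_pattern_on_c3_retained(self, strong_epochs):
        idx = strong_epochs.ch_names.index("C3")
        pattern = np.zeros(len(strong_epochs.ch_names))
        pattern[idx] = 1.0
        model = self._model_with_patterns(strong_epochs, pattern)
        out = select_plausible_components(model)
        assert out.selected_ == model.candidates_

    def test_occipital_pattern_falls_back_to_best(self, strong_epochs):
        pattern = np.zeros(len(strong_epochs.ch_names))
        pattern[strong_epochs.ch_names.index("O1")] = 1.0
        pattern[strong_epochs.ch_names.index("O2")] = 1.0
        model = self._model_with_patterns(strong_epochs, pattern)
        out = select_plausible_components(model)
        assert len(out.selected_) == 1  # fallback keeps exactly one

    def test_planted_component_survives_selection(self, strong_bank, strong_training):
        cfg, _, _ = strong_training
        model = strong_bank.csp_models["Y_OF"]
        topo = cfg.topographies["flexion"]
        corrs = [abs(np.corrcoef(model.patterns_[:, j], topo)[0, 1]) for j in model.selected_]
        assert max(corrs) >= 0.9
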
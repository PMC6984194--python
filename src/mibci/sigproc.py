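"""Signal processing for classifier training: band-pass filtering, epoching,
artifact rejection, CSP spatial filtering and log-variance features.

The CSP implementation solves the generalized eigenproblem
``Sigma_A w = lambda (Sigma_A + Sigma_B) w`` on trace-normalized, per-trial
averaged class covariances, orders components by eigenvalue descending, and
marks the first four and last four filters (the most discriminative ends of
the spectrum) as candidates.  It is exposed as a scikit-learn transformer
whose ``transform`` yields log-variance features.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import Recording
from .montage import SENSORIMOTOR_CHANNELS, channel_indices

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "CSP",
    "bandpass",
    "epoch_training",
    "reject_artifacts",
    "fit_csp",
    "logvar_features",
    "select_plausible_components",
    "EPOCH_DURATION",
    "REST_EPOCH_OFFSET",
]

#: Epoch length used for classifier calibration (seconds).
EPOCH_DURATION = 1.5
#: Rest epochs start this far into each 5 s rest period (centered placement,
#: clear of movement-offset transients).
REST_EPOCH_OFFSET = 1.75


@dataclass
class EpochSet:
    """Segmented trials: ``data`` has shape (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    t0: float = 0.0
    ch_names: list[str] = field(default_factory=list)
    onsets: np.ndarray = None  # epoch start times within the recording

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.onsets is None:
            self.onsets = np.full(self.data.shape[0], np.nan)
        self.onsets = np.asarray(self.onsets, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self, data=self.data[mask], labels=self.labels[mask],
            onsets=self.onsets[mask], ch_names=list(self.ch_names),
        )

    def for_classes(self, *classes) -> "EpochSet":
        return self.subset(np.isin(self.labels, classes))


def bandpass(recording: Recording, low: float = 8.0, high: float = 28.0,
             mode: str = "zero_phase", order: int = 4) -> Recording:
    """Butterworth band-pass.

    ``causal`` mode (single forward pass) is required on the online
    controller path, ``zero_phase`` (forward-backward) for offline analysis.
    """
    if not 0 < low < high < recording.fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={recording.fs / 2}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    if mode == "causal":
        out = signal.sosfilt(sos, recording.data, axis=-1)
    elif mode == "zero_phase":
        out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return recording.copy_with(out)


def _extract(recording, t_start, n_samp):
    s0 = int(round(t_start * recording.fs))
    if s0 < 0 or s0 + n_samp > recording.n_samples:
        return None
    return recording.data[:, s0:s0 + n_samp]


def epoch_training(recording: Recording, events) -> EpochSet:
    """Cut 1.5 s training epochs.

    One epoch per flexion/extension onset plus two rest epochs per run —
    one from the 5 s rest period preceding each imagery trial, labelled by
    the hand state at rest (``rest_open`` before flexion, ``rest_closed``
    before extension).  Epochs extending past the recording are dropped
    with a logged warning.
    """
    n_samp = int(round(EPOCH_DURATION * recording.fs))
    mi_events = sorted(e for e in events if e.label in ("flexion_onset", "extension_onset"))
    rest_events = sorted(e for e in events if e.label == "rest_onset")

    entries = []  # (onset_time, label)
    for e in mi_events:
        entries.append((e.time, e.label.replace("_onset", "")))
    for r in rest_events:
        nxt = next((e for e in mi_events if e.time > r.time), None)
        if nxt is None:
            logger.warning("rest period at %.2f s has no following imagery trial; dropped", r.time)
            continue
        label = "rest_open" if nxt.label == "flexion_onset" else "rest_closed"
        entries.append((r.time + REST_EPOCH_OFFSET, label))

    entries.sort()
    data, labels, onsets, dropped = [], [], [], 0
    for t, label in entries:
        seg = _extract(recording, t, n_samp)
        if seg is None:
            dropped += 1
            logger.warning("epoch %r at %.2f s extends past recording bounds; dropped", label, t)
            continue
        data.append(seg)
        labels.append(label)
        onsets.append(t)
    if dropped:
        logger.warning("dropped %d out-of-bounds epochs, kept %d", dropped, len(data))
    shape = (0, recording.n_channels, n_samp)
    return EpochSet(
        data=np.array(data) if data else np.empty(shape),
        labels=np.array(labels, dtype=object),
        fs=recording.fs,
        t0=0.0,
        ch_names=list(recording.ch_names),
        onsets=np.array(onsets) if onsets else np.empty(0),
    )


def _robust_z(values):
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(values)
    return (values - med) / scale


def reject_artifacts(epochs: EpochSet, z_thresh: float = 5.0):
    """Automatic amplitude/variance artifact rejection.

    Removes epochs whose peak absolute amplitude or mean variance exceeds
    ``z_thresh`` robust z-scores (median/MAD across epochs).  Returns the
    cleaned :class:`EpochSet` and a removal report.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot reject artifacts on an empty EpochSet")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    var = epochs.data.var(axis=2).mean(axis=1)
    z_peak, z_var = _robust_z(peak), _robust_z(var)
    bad = (z_peak > z_thresh) | (z_var > z_thresh)
    if bad.all():
        raise RuntimeError("all epochs rejected as artifactual; pipeline cannot proceed")
    report = {
        "n_rejected": int(bad.sum()),
        "n_kept": int((~bad).sum()),
        "rejected_indices": np.flatnonzero(bad).tolist(),
        "z_peak": z_peak,
        "z_var": z_var,
    }
    if bad.any():
        logger.info("rejected %d/%d epochs as artifactual", report["n_rejected"], epochs.n_trials)
    return epochs.subset(~bad), report


class CSP(BaseEstimator, TransformerMixin):
    """Common spatial patterns as a scikit-learn transformer.

    Parameters
    ----------
    n_candidates : int
        How many filters from each end of the eigenvalue spectrum are
        marked as candidates (default 4, i.e. first four + last four).
    shrinkage : float
        Diagonal-loading coefficient in [0, 1] applied to both class
        covariances (0 disables; use when covariances are rank deficient).
    class_order : tuple or None
        ``(class_A, class_B)``; eigenvalues are variance ratios of class A.
        If None, the sorted unique labels are used.

    Attributes (after fit)
    ----------------------
    filters_ : (n_channels, n_components) spatial filter matrix W, columns
        ordered by eigenvalue descending.
    patterns_ : (n_channels, n_components) activation patterns A = (W^T)^-1.
    eigenvalues_ : per-component variance ratios lambda in (0, 1).
    candidates_ : indices of the first/last ``n_candidates`` components.
    selected_ : retained component indices (candidates until narrowed by
        :func:`select_plausible_components`).
    """

    def __init__(self, n_candidates: int = 4, shrinkage: float = 0.0,
                 class_order=None):
        self.n_candidates = n_candidates
        self.shrinkage = shrinkage
        self.class_order = class_order

    @staticmethod
    def _class_cov(X, shrinkage):
        covs = []
        for trial in X:
            c = trial @ trial.T
            tr = np.trace(c)
            if tr > 0:
                covs.append(c / tr)
        cov = np.mean(covs, axis=0)
        if shrinkage > 0:
            mu = np.trace(cov) / cov.shape[0]
            cov = (1 - shrinkage) * cov + shrinkage * mu * np.eye(cov.shape[0])
        return cov

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, samples)")
        classes = list(self.class_order) if self.class_order is not None else sorted(set(y))
        if len(classes) != 2:
            raise ValueError(f"CSP requires exactly two classes, got {classes}")
        a, b = classes
        X_a, X_b = X[y == a], X[y == b]
        if len(X_a) < 2 or len(X_b) < 2:
            raise ValueError("need at least 2 epochs per class")

        cov_a = self._class_cov(X_a, self.shrinkage)
        cov_b = self._class_cov(X_b, self.shrinkage)
        pooled = cov_a + cov_b
        cond = np.linalg.eigvalsh(pooled)
        if cond[0] <= cond[-1] * 1e-10:
            raise np.linalg.LinAlgError(
                "pooled covariance is rank deficient; set shrinkage > 0 "
                "(e.g. CSP(shrinkage=0.05)) or record more/cleaner trials"
            )
        evals, evecs = linalg.eigh(cov_a, pooled)
        order = np.argsort(evals)[::-1]
        evals, W = evals[order], evecs[:, order]
        A = np.linalg.inv(W.T)
        # sign convention: largest-magnitude pattern weight positive
        for j in range(W.shape[1]):
            k = np.argmax(np.abs(A[:, j]))
            if A[k, j] < 0:
                W[:, j] = -W[:, j]
                A[:, j] = -A[:, j]

        n_comp = W.shape[1]
        m = min(self.n_candidates, n_comp // 2) if n_comp >= 2 else n_comp
        cand = sorted(set(range(m)) | set(range(n_comp - m, n_comp)))

        self.classes_ = (a, b)
        self.filters_ = W
        self.patterns_ = A
        self.eigenvalues_ = evals
        self.candidates_ = cand
        self.selected_ = list(cand)
        return self

    def transform(self, X):
        """Log-variance features of the selected components."""
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        W = self.filters_[:, self.selected_]
        projected = np.einsum("cj,tcs->tjs", W, X)
        var = projected.var(axis=2)
        bad = var <= 0
        if bad.any():
            warnings.warn("zero-variance projected epoch(s); features floored at log(eps)")
            var[bad] = np.finfo(float).eps
        return np.log(var)


def fit_csp(epochs_A: EpochSet, epochs_B=None, shrinkage: float = 0.0) -> CSP:
    """Fit CSP contrasting two classes.

    Accepts either two single-class :class:`EpochSet` objects or one
    two-class set.  The fitted model carries ``class_pair`` and the channel
    labels of the training montage.
    """
    if epochs_B is not None:
        a = str(epochs_A.labels[0]) if epochs_A.n_trials else "A"
        b = str(epochs_B.labels[0]) if epochs_B.n_trials else "B"
        X = np.concatenate([epochs_A.data, epochs_B.data], axis=0)
        y = np.array([a] * epochs_A.n_trials + [b] * epochs_B.n_trials, dtype=object)
        ch_names = epochs_A.ch_names
        order = (a, b)
    else:
        X, y, ch_names = epochs_A.data, epochs_A.labels, epochs_A.ch_names
        order = None
    model = CSP(class_order=order, shrinkage=shrinkage).fit(X, y)
    model.ch_names_ = list(ch_names)
    model.class_pair_ = model.classes_
    return model


def logvar_features(epochs: EpochSet, model: CSP) -> np.ndarray:
    """feature[i, j] = log(var(w_j^T . epoch_i)) over the selected filters."""
    if not model.selected_:
        raise ValueError("CSP model has no selected components")
    return model.transform(epochs.data)


def sensorimotor_concentration(weights: np.ndarray, ch_names,
                               channels=SENSORIMOTOR_CHANNELS) -> float:
    """Fraction of squared weight mass over sensorimotor channels."""
    idx = channel_indices(ch_names, channels)
    total = float(np.sum(weights ** 2))
    if total == 0:
        return 0.0
    return float(np.sum(weights[idx] ** 2) / total)


def select_plausible_components(model: CSP, ch_names=None,
                                sensorimotor_channels=SENSORIMOTOR_CHANNELS,
                                min_fraction: float = 0.5) -> CSP:
    """Automatic proxy for visual filter inspection.

    Keeps candidate components whose activation-pattern weight mass over
    sensorimotor channels is at least ``min_fraction``; if none qualify the
    single best-concentrated candidate is retained.
    """
    check_is_fitted(model, "filters_")
    ch_names = ch_names if ch_names is not None else getattr(model, "ch_names_", None)
    if ch_names is None:
        raise ValueError("channel names required (pass ch_names or fit via fit_csp)")
    out = copy.deepcopy(model)
    conc = {
        j: sensorimotor_concentration(model.patterns_[:, j], ch_names, sensorimotor_channels)
        for j in model.candidates_
    }
    keep = [j for j, c in conc.items() if c >= min_fraction]
    if not keep:
        keep = [max(conc, key=conc.get)]
    out.selected_ = sorted(keep)
    return out
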
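"""Comparison methods: peak-magnitude SVC, Rosenstein maximum Lyapunov
exponent with Youden-J thresholding, and the multi-user entropy score.

Naming note: the field overloads "SVM". Here ``svm_mag`` always means the
signal vector magnitude channel (Euclidean norm of the triaxial signal)
and ``svc`` always means the support-vector classifier baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import CHANNEL_NAMES, GaitWindow, WindowDataset

FEATURE_SETS = {"peak": ("peak",), "extended": ("peak", "mean", "std")}


def extract_features(window: GaitWindow, feature_set=("peak",)) -> dict[str, float]:
    """Window features of the accelerometer magnitude channel.

    Default is the single peak (max) feature; the extended set adds mean
    and standard deviation.
    """
    svm_acc = window.samples[CHANNEL_NAMES.index("SVM_Acc")]
    out = {}
    for name in feature_set:
        if name == "peak":
            out[name] = float(np.max(svm_acc))
        elif name == "mean":
            out[name] = float(np.mean(svm_acc))
        elif name == "std":
            out[name] = float(np.std(svm_acc))
        else:
            raise ValueError(f"unknown feature {name!r}")
    return out


def feature_matrix(windows: list[GaitWindow], feature_set=("peak",)) -> np.ndarray:
    return np.array(
        [[extract_features(w, feature_set)[f] for f in feature_set] for w in windows]
    )


def train_rbf_svm(features: np.ndarray, labels: np.ndarray, C: float = 10.0, gamma: float = 0.01):
    """RBF support-vector classifier with training-fold standardisation."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("SVC training requires both classes")
    clf = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(C=C, gamma=gamma, kernel="rbf"))]
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


# ---------------------------------------------------------------------------
# Rosenstein maximum Lyapunov exponent


@dataclass(frozen=True)
class LyapunovEstimate:
    """Largest Lyapunov exponent of one series (divergence rate, 1/s)."""

    lam: float
    fit_range: tuple[int, int]  # offsets (samples) of the linear fit
    m: int
    tau: int
    theiler: int
    mean_log_divergence: np.ndarray  # y(k) curve, natural log


def dominant_period_samples(series: np.ndarray, fs: float) -> int:
    """Period of the dominant periodogram peak (DC excluded), in samples."""
    freqs, power = sps.periodogram(series - np.mean(series), fs=fs)
    if len(freqs) < 2 or not np.any(power[1:] > 0):
        return max(1, len(series) // 10)
    f_dom = freqs[1:][np.argmax(power[1:])]
    if f_dom <= 0:
        return max(1, len(series) // 10)
    return max(1, int(round(fs / f_dom)))


def delay_embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """(M, m) delay-embedded trajectory, M = n - (m-1)*tau."""
    n = len(series)
    M = n - (m - 1) * tau
    if M < 2:
        raise ValueError("series too short for the requested embedding")
    return np.stack([series[i * tau : i * tau + M] for i in range(m)], axis=1)


def _nearest_neighbors(X: np.ndarray, theiler: int, chunk: int = 512) -> np.ndarray:
    """Index of each point's nearest neighbor outside the Theiler window."""
    M = len(X)
    nn_idx = np.empty(M, dtype=int)
    idx = np.arange(M)
    for start in range(0, M, chunk):
        stop = min(start + chunk, M)
        d = np.linalg.norm(X[start:stop, None, :] - X[None, :, :], axis=2)
        band = np.abs(idx[start:stop, None] - idx[None, :]) <= theiler
        d[band] = np.inf
        nn_idx[start:stop] = d.argmin(axis=1)
    return nn_idx


def rosenstein_maxle(
    series: np.ndarray,
    fs: float,
    m: int = 6,
    tau: int = 5,
    theiler: int | None = None,
    fit_window: int | None = None,
) -> LyapunovEstimate:
    """Largest Lyapunov exponent via the Rosenstein nearest-neighbor method.

    Delay-embeds the series, pairs each state with its nearest neighbor
    outside a Theiler exclusion window, tracks the mean natural-log
    separation over time offsets, and fits the slope of the initial region
    (``fit_window`` offsets), converted to 1/s via ``fs``. Defaults follow
    standard practice: Theiler window = one mean period (dominant
    periodogram peak), fit window = half a mean period.
    """
    series = np.asarray(series, dtype=float)
    if m < 2 or tau < 1:
        raise ValueError("need embedding dimension m >= 2 and delay tau >= 1")
    period = dominant_period_samples(series, fs)
    if theiler is None:
        theiler = period
    if fit_window is None:
        fit_window = max(2, period // 2)
    if len(series) <= (m - 1) * tau + fit_window + theiler:
        raise ValueError(
            "series too short for Lyapunov estimation with these parameters "
            f"(n={len(series)}, m={m}, tau={tau}, fit_window={fit_window}, theiler={theiler})"
        )
    X = delay_embed(series, m, tau)
    M = len(X)
    nn_idx = _nearest_neighbors(X, theiler)
    max_k = min(fit_window, M - 1)
    ks = np.arange(max_k + 1)
    y = np.empty(len(ks))
    for k in ks:
        valid = np.flatnonzero((np.arange(M) + k < M) & (nn_idx + k < M))
        d = np.linalg.norm(X[valid + k] - X[nn_idx[valid] + k], axis=1)
        y[k] = np.mean(np.log(np.maximum(d, 1e-12)))
    slope = np.polyfit(ks, y, 1)[0]
    return LyapunovEstimate(
        lam=float(slope * fs),
        fit_range=(0, int(max_k)),
        m=m,
        tau=tau,
        theiler=int(theiler),
        mean_log_divergence=y,
    )


def window_maxle(
    dataset_or_windows, fs: float | None = None, m: int = 6, tau: int = 5, **kwargs
) -> np.ndarray:
    """MaxLE of the accelerometer magnitude of each window (1/s)."""
    if isinstance(dataset_or_windows, WindowDataset):
        windows = dataset_or_windows.included
        fs = dataset_or_windows.fs
    else:
        windows = dataset_or_windows
        if fs is None:
            fs = windows[0].fs
    idx = CHANNEL_NAMES.index("SVM_Acc")
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        series = w.samples[idx]
        # short-window guard: shrink the fit/Theiler spans to fit 2-s windows
        period = dominant_period_samples(series, fs)
        max_span = len(series) - (m - 1) * tau - 1
        theiler = kwargs.get("theiler", min(period, max_span // 2))
        fit_window = kwargs.get("fit_window", min(max(2, period // 2), max_span - theiler - 1))
        out[i] = rosenstein_maxle(
            series, fs, m=m, tau=tau, theiler=theiler, fit_window=fit_window
        ).lam
    return out


# ---------------------------------------------------------------------------
# Youden-J thresholding


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent sorted unique scores
    (prediction rule: positive iff score > threshold); ties are broken by
    the smallest such threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("Youden threshold requires both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_thr, best_j = candidates[0], -np.inf
    for thr in candidates:
        pred = scores > thr
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# Multi-user entropy score


@dataclass(frozen=True)
class EntropyProfile:
    """Per-segment Shannon entropy of pooled magnitudes and its min-max
    normalised version (the entropy EB score)."""

    h_bits: np.ndarray  # raw entropies; NaN where a segment had no samples
    normalized: np.ndarray
    bin_count: int
    epsilon: float


def entropy_segment_scores(
    pooled: list[np.ndarray], bins: int = 40, epsilon: float = 1e-6
) -> EntropyProfile:
    """Shannon entropy (bits) of a ``bins``-bin histogram on [0, 1] of each
    segment's pooled normalised magnitudes, epsilon-smoothed, then min-max
    normalised across segments. Empty segments are flagged NaN."""
    h = np.full(len(pooled), np.nan)
    any_samples = False
    for i, samples in enumerate(pooled):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            continue
        any_samples = True
        counts, _ = np.histogram(samples, bins=bins, range=(0.0, 1.0))
        p = (counts + epsilon) / (counts.sum() + bins * epsilon)
        h[i] = float(-(p * np.log2(p)).sum())
    if not any_samples:
        raise ValueError("all segments are empty")
    finite = np.isfinite(h)
    lo, hi = np.nanmin(h), np.nanmax(h)
    normalized = np.full_like(h, np.nan)
    normalized[finite] = 0.0 if hi == lo else (h[finite] - lo) / (hi - lo)
    return EntropyProfile(h_bits=h, normalized=normalized, bin_count=bins, epsilon=epsilon)


def pool_magnitudes(
    per_subject: dict[int, list[tuple[np.ndarray, np.ndarray]]],
    segment_edges: np.ndarray,
) -> list[np.ndarray]:
    """Pool per-participant min-max-normalised magnitudes into segments.

    ``per_subject`` maps subject -> list of (arclength, magnitude) sample
    arrays (one per trial). Magnitudes are normalised to [0, 1] per
    participant (pooled over that participant's trials) to remove
    inter-subject gain differences, then binned by the half-open segment
    intervals defined by ``segment_edges``.
    """
    n_seg = len(segment_edges) - 1
    pooled: list[list[np.ndarray]] = [[] for _ in range(n_seg)]
    for subject, trials in per_subject.items():
        mags = np.concatenate([m for _, m in trials])
        lo, hi = mags.min(), mags.max()
        for arclength, mag in trials:
            norm = np.zeros_like(mag) if hi == lo else (mag - lo) / (hi - lo)
            seg = np.searchsorted(segment_edges, arclength, side="right") - 1
            ok = (seg >= 0) & (seg < n_seg)
            for s in np.unique(seg[ok]):
                pooled[s].append(norm[ok][seg[ok] == s])
    return [np.concatenate(parts) if parts else np.empty(0) for parts in pooled]


# ---------------------------------------------------------------------------
# LOSO harnesses for the window-scoring baselines


def svc_loso(
    dataset: WindowDataset,
    C: float = 10.0,
    gamma: float = 0.01,
    feature_set=("peak",),
) -> pd.DataFrame:
    """LOSO evaluation of the peak-feature SVC: binary window labels."""
    windows = dataset.included
    feats = feature_matrix(windows, feature_set)
    labels = dataset.labels(windows)
    subj = np.array([w.subject_id for w in windows])
    records = []
    for fold_id, held_out in enumerate(sorted(set(subj.tolist()))):
        test = subj == held_out
        clf = train_rbf_svm(feats[~test], labels[~test], C=C, gamma=gamma)
        pred = clf.predict(feats[test])
        score = clf.decision_function(feats[test])
        for w, yhat, s in zip(np.flatnonzero(test), pred, score):
            win = windows[w]
            records.append(
                {
                    "subject": win.subject_id,
                    "trial": win.trial_id,
                    "window_id": win.window_id,
                    "fold_id": fold_id,
                    "pred_label": int(yhat),
                    "score": float(s),
                    "label": int(labels[w]),
                }
            )
    return pd.DataFrame(records)


def maxle_loso(dataset: WindowDataset, m: int = 6, tau: int = 5) -> pd.DataFrame:
    """LOSO evaluation of the MaxLE scorer with per-fold Youden threshold."""
    windows = dataset.included
    lam = window_maxle(dataset, m=m, tau=tau)
    labels = dataset.labels(windows)
    subj = np.array([w.subject_id for w in windows])
    records = []
    for fold_id, held_out in enumerate(sorted(set(subj.tolist()))):
        test = subj == held_out
        thr = youden_threshold(lam[~test], labels[~test])
        for w in np.flatnonzero(test):
            win = windows[w]
            records.append(
                {
                    "subject": win.subject_id,
                    "trial": win.trial_id,
                    "window_id": win.window_id,
                    "fold_id": fold_id,
                    "pred_label": int(lam[w] > thr),
                    "score": float(lam[w]),
                    "label": int(labels[w]),
                }
            )
    return pd.DataFrame(records)
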
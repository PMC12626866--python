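"""Window-level classification, calibration and curve metrics.

The abnormal (environmental-barrier) class is the positive class
throughout. Metrics across leave-one-subject-out folds are micro-averaged
by pooling all held-out predictions; per-fold means and standard
deviations are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .spatial import rank_metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(predictions, labels, threshold: float = 0.5) -> ConfusionCounts:
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if pred.size == 0:
        raise ValueError("empty input")
    yhat = pred >= threshold
    return ConfusionCounts(
        tp=int(np.sum(yhat & (y == 1))),
        fp=int(np.sum(yhat & (y == 0))),
        fn=int(np.sum(~yhat & (y == 1))),
        tn=int(np.sum(~yhat & (y == 0))),
    )


def confusion_metrics(predictions, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, F1 (abnormal class), sensitivity, specificity.

    Probabilities are thresholded at ``threshold``; 0/1 label inputs pass
    through unchanged. F1 is 0 (with a warning) when its denominator
    vanishes.
    """
    c = confusion_counts(predictions, labels, threshold)
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")
    if 2 * c.tp + c.fp + c.fn == 0:
        warnings.warn("F1 undefined (no positives predicted or present); reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
    }


def brier(probabilities, labels) -> float:
    """Mean squared error between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_probs(p)
    return float(np.mean((p - y) ** 2))


def _check_probs(p):
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CalibrationReport:
    """Reliability-diagram table plus the scalar calibration metrics."""

    bin_edges: np.ndarray
    mean_predicted: np.ndarray  # NaN for empty bins
    observed_fraction: np.ndarray
    counts: np.ndarray
    ece: float
    brier: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean_predicted": self.mean_predicted,
                "observed_fraction": self.observed_fraction,
                "count": self.counts,
            }
        )


def reliability_bins(probabilities, labels, n_bins: int = 10) -> CalibrationReport:
    """Equal-width bins on the positive-class probability; per-bin mean
    prediction, observed positive fraction and count; ECE and Brier."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_probs(p)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # final bin closed so p = 1 is counted
    idx = np.minimum(np.digitize(p, edges[1:-1]), n_bins - 1)
    counts = np.zeros(n_bins, dtype=int)
    mean_p = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            mean_p[b] = float(p[mask].mean())
            obs[b] = float(y[mask].mean())
    gaps = np.abs(mean_p - obs)
    ece_val = float(np.nansum(gaps * counts) / len(p))
    return CalibrationReport(
        bin_edges=edges,
        mean_predicted=mean_p,
        observed_fraction=obs,
        counts=counts,
        ece=ece_val,
        brier=brier(p, y),
    )


def ece(probabilities, labels, n_bins: int = 10) -> float:
    """Expected calibration error: count-weighted mean absolute gap between
    mean predicted probability and observed positive fraction per bin."""
    return reliability_bins(probabilities, labels, n_bins).ece


def roc_pr_curves(probabilities, labels) -> dict:
    """ROC and precision-recall curve point sets plus their AUCs.

    The AUCs are computed by the same rank statistics as the segment-level
    metrics (single source of truth); degenerate labels yield NaN AUCs and
    empty curves.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    aucs = rank_metrics(p, y.astype(bool))
    if y.all() or not y.any():
        return {"roc": None, "pr": None, **aucs}
    fpr, tpr, roc_thr = roc_curve(y, p)
    prec, rec, pr_thr = precision_recall_curve(y, p)
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        "pr": pd.DataFrame(
            {"precision": prec, "recall": rec}
        ),
        **aucs,
    }


def window_report(
    predictions: pd.DataFrame,
    threshold: float = 0.5,
    n_bins: int = 10,
    prob_column: str = "p_abnormal",
) -> dict:
    """Pooled (micro) window metrics plus per-fold mean +/- SD.

    ``predictions`` needs columns [prob_column, label] and optionally
    fold_id for the per-fold breakdown.
    """
    p = predictions[prob_column].to_numpy(float)
    y = predictions["label"].to_numpy(int)
    report = confusion_metrics(p, y, threshold)
    report.update(roc_pr_curves(p, y))
    cal = reliability_bins(p, y, n_bins)
    report["ece"] = cal.ece
    report["brier"] = cal.brier
    report["calibration"] = cal
    if "fold_id" in predictions:
        per_fold = []
        for _, fold in predictions.groupby("fold_id"):
            per_fold.append(
                confusion_metrics(
                    fold[prob_column].to_numpy(float), fold["label"].to_numpy(int), threshold
                )["accuracy"]
            )
        report["accuracy_fold_mean"] = float(np.mean(per_fold))
        report["accuracy_fold_sd"] = float(np.std(per_fold, ddof=1)) if len(per_fold) > 1 else 0.0
    return report


def plot_curves(report: dict, path_prefix: str) -> list[str]:
    """Optional rendering of ROC / PR / reliability figures to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if report.get("roc") is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(report["roc"]["fpr"], report["roc"]["tpr"])
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"ROC (AUC = {report['auc_roc']:.3f})")
        fig.savefig(f"{path_prefix}_roc.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f"{path_prefix}_roc.png")
    if report.get("pr") is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(report["pr"]["recall"], report["pr"]["precision"])
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"PR (AUC = {report['auc_pr']:.3f})")
        fig.savefig(f"{path_prefix}_pr.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f"{path_prefix}_pr.png")
    cal = report.get("calibration")
    if cal is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ok = np.isfinite(cal.mean_predicted)
        ax.plot(cal.mean_predicted[ok], cal.observed_fraction[ok], "o-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("observed abnormal fraction")
        ax.set_title(f"Reliability (ECE = {cal.ece:.3f})")
        fig.savefig(f"{path_prefix}_reliability.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f"{path_prefix}_reliability.png")
    return written
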
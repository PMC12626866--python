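"""Stage 2: route discretisation into 5-m segments, EB-score aggregation,
and segment-level detection/localization metrics.

The EB score of a segment is the mean abnormality indicator of the windows
that *start* inside it — the calibrated probability p_w for the CNN, the
binary predicted label for the SVC and MaxLE baselines. Segments without
windows are flagged missing and excluded from ranking metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .synth import RouteSpec


@dataclass(frozen=True)
class RouteSegmentation:
    """Half-open tiling [start, start + seg_len) of the route arclength."""

    length_m: float
    segment_length_m: float = 5.0

    def __post_init__(self):
        if self.length_m <= 0 or self.segment_length_m <= 0:
            raise ValueError("route and segment lengths must be positive")

    @property
    def count(self) -> int:
        return int(np.ceil(self.length_m / self.segment_length_m))

    @property
    def edges(self) -> np.ndarray:
        """count+1 interval edges; the final segment may be shorter."""
        e = np.arange(self.count + 1, dtype=float) * self.segment_length_m
        e[-1] = min(e[-1], self.length_m)
        return e

    def segment_of(self, arclength: float) -> int | None:
        """Index of the segment containing an arclength, None if off-route."""
        if arclength < 0 or arclength >= self.length_m:
            return None
        return int(arclength // self.segment_length_m)


def discretize_route(length_m: float, segment_length_m: float = 5.0) -> RouteSegmentation:
    """Tile a route into non-overlapping 5-m (default) segments."""
    return RouteSegmentation(length_m=length_m, segment_length_m=segment_length_m)


def segment_truth(route: RouteSpec, segmentation: RouteSegmentation) -> np.ndarray:
    """Boolean ground truth: segment intersects some barrier extent."""
    truth = np.zeros(segmentation.count, dtype=bool)
    edges = segmentation.edges
    for b in route.barriers:
        lo, hi = b.position_m, b.position_m + b.extent_m
        for s in range(segmentation.count):
            if lo < edges[s + 1] and hi > edges[s]:
                truth[s] = True
    return truth


def assign_windows(window_starts_m: np.ndarray, segmentation: RouteSegmentation) -> np.ndarray:
    """Segment index per window start arclength; -1 when off-route (dropped
    downstream with a warning)."""
    starts = np.asarray(window_starts_m, dtype=float)
    seg = np.floor(starts / segmentation.segment_length_m).astype(int)
    off = (starts < 0) | (starts >= segmentation.length_m)
    if np.any(off):
        import warnings

        warnings.warn(f"{int(off.sum())} window(s) start outside the route; dropped")
    seg[off] = -1
    return seg


def eb_scores(
    window_starts_m: np.ndarray,
    indicators: np.ndarray,
    segmentation: RouteSegmentation,
) -> pd.DataFrame:
    """Per-segment EB score: mean indicator of windows starting inside.

    ``indicators`` are probabilities (CNN) or 0/1 labels (SVC/MaxLE).
    Returns a frame indexed by segment with eb_score (NaN when no windows)
    and n_windows.
    """
    indicators = np.asarray(indicators, dtype=float)
    if np.any((indicators < 0) | (indicators > 1)):
        raise ValueError("window indicators must lie in [0, 1]")
    seg = assign_windows(window_starts_m, segmentation)
    score = np.full(segmentation.count, np.nan)
    counts = np.zeros(segmentation.count, dtype=int)
    for s in range(segmentation.count):
        mask = seg == s
        counts[s] = int(mask.sum())
        if counts[s]:
            score[s] = float(indicators[mask].mean())
    edges = segmentation.edges
    return pd.DataFrame(
        {
            "segment_id": np.arange(segmentation.count),
            "start_m": edges[:-1],
            "end_m": edges[1:],
            "eb_score": score,
            "n_windows": counts,
        }
    )


def rank_metrics(scores: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Segment ranking quality: AUC-ROC (Mann-Whitney, ties count 1/2) and
    AUC-PR (precision-recall step integral). Segments with missing scores
    are excluded; degenerate truth yields NaN."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    ok = np.isfinite(scores)
    scores, truth = scores[ok], truth[ok]
    if truth.all() or not truth.any():
        return {"auc_roc": float("nan"), "auc_pr": float("nan")}
    return {
        "auc_roc": float(roc_auc_score(truth, scores)),
        "auc_pr": float(average_precision_score(truth, scores)),
    }


def topk_metrics(scores: np.ndarray, truth: np.ndarray, k: int = 5) -> dict[str, float]:
    """Precision@k and Recall@k over scored segments; ties at rank k broken
    by segment index (stable ascending index, descending score)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    ok = np.flatnonzero(np.isfinite(scores))
    if k > len(ok):
        raise ValueError(f"k={k} exceeds the {len(ok)} scored segments")
    order = ok[np.lexsort((ok, -scores[ok]))][:k]
    hits = int(truth[order].sum())
    total = int(truth.sum())
    return {
        "precision_at_k": hits / k,
        "recall_at_k": hits / total if total else 0.0,
        "k": k,
    }


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True as half-open index ranges."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def detection_metrics(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    route_km: float | None = None,
    segment_length_m: float = 5.0,
) -> dict[str, float]:
    """Run-based localisation metrics at a binarisation threshold.

    Detections are segments with score >= threshold (missing scores count
    as no detection). Truth and detections are grouped into maximal
    contiguous runs. Each truth run's IoU is measured against the union of
    detection runs overlapping it (0 if none); mIoU is the mean over truth
    runs. FP/km counts detected segments overlapping no truth run, per
    kilometre of route. A global set-level IoU is reported alongside.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    detected = np.zeros_like(truth)
    finite = np.isfinite(scores)
    detected[finite] = scores[finite] >= threshold
    if route_km is None:
        route_km = len(truth) * segment_length_m / 1000.0
    truth_runs = _runs(truth)
    det_runs = _runs(detected)
    if not truth_runs:
        miou = float("nan")
    else:
        ious = []
        for t0, t1 in truth_runs:
            overlapping = [(d0, d1) for d0, d1 in det_runs if d0 < t1 and d1 > t0]
            if not overlapping:
                ious.append(0.0)
                continue
            t_set = set(range(t0, t1))
            d_set = set()
            for d0, d1 in overlapping:
                d_set |= set(range(d0, d1))
            ious.append(len(t_set & d_set) / len(t_set | d_set))
        miou = float(np.mean(ious))
    fp_segments = int(np.sum(detected & ~truth_in_any_run(truth, detected)))
    t_idx, d_idx = set(np.flatnonzero(truth)), set(np.flatnonzero(detected))
    global_iou = len(t_idx & d_idx) / len(t_idx | d_idx) if (t_idx | d_idx) else float("nan")
    return {
        "miou": miou,
        "fp_per_km": fp_segments / route_km,
        "global_iou": float(global_iou),
        "n_detected": int(detected.sum()),
    }


def truth_in_any_run(truth: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Mask of detected segments whose detection run overlaps a truth run."""
    covered = np.zeros_like(detected)
    truth_runs = _runs(truth)
    for d0, d1 in _runs(detected):
        if any(d0 < t1 and d1 > t0 for t0, t1 in truth_runs):
            covered[d0:d1] = True
    return covered


def segment_table(
    window_starts_m: np.ndarray,
    indicators: np.ndarray,
    route: RouteSpec,
    segmentation: RouteSegmentation | None = None,
    method: str = "gaf_cnn",
) -> pd.DataFrame:
    """Full per-segment table: geometry, ground truth, EB score, counts."""
    if segmentation is None:
        segmentation = discretize_route(route.length_m)
    frame = eb_scores(window_starts_m, indicators, segmentation)
    frame["is_barrier"] = segment_truth(route, segmentation)
    frame["method"] = method
    return frame[
        ["segment_id", "start_m", "end_m", "is_barrier", "eb_score", "method", "n_windows"]
    ]
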
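"""Survey-level modelling objects tying the pipeline together.

``BarrierSurvey`` holds a labeled window dataset and the route geometry;
``fit`` runs one or more detection methods under leave-one-subject-out
cross-validation and returns a ``BarrierSurveyResults`` carrying per-window
predictions, window-level classification/calibration metrics, per-segment
EB scores and segment-level localization metrics, with a ``summary()``
table across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import baselines, evaluation, spatial
from .classifier import ModelConfig, loso_cross_validate
from .preprocess import WindowDataset, lowpass_filter, preprocess_cohort
from .preprocess import signal_vector_magnitude
from .synth import GenerationBounds, RouteSpec, TrialRecording, simulate_cohort

METHODS = ("gaf_cnn", "raw1d_cnn", "svc", "maxle", "entropy")


class BarrierSurvey:
    """A cohort of labeled gait windows walked over one surveyed route."""

    def __init__(
        self,
        dataset: WindowDataset,
        route: RouteSpec,
        config: ModelConfig | None = None,
        recordings: list[TrialRecording] | None = None,
        segment_length_m: float = 5.0,
    ):
        self.dataset = dataset
        self.route = route
        self.config = (config or ModelConfig()).validate()
        self.recordings = recordings
        self.segmentation = spatial.discretize_route(route.length_m, segment_length_m)

    @classmethod
    def from_recordings(
        cls,
        recordings: list[TrialRecording],
        route: RouteSpec,
        config: ModelConfig | None = None,
        segment_length_m: float = 5.0,
        **preprocess_kwargs,
    ) -> "BarrierSurvey":
        dataset = preprocess_cohort(recordings, route, **preprocess_kwargs)
        return cls(dataset, route, config, recordings=recordings, segment_length_m=segment_length_m)

    @classmethod
    def simulate(
        cls,
        n_subjects: int = 20,
        n_trials: int = 2,
        route: RouteSpec | None = None,
        master_seed: int = 42,
        config: ModelConfig | None = None,
        bounds: GenerationBounds = GenerationBounds(),
        **preprocess_kwargs,
    ) -> "BarrierSurvey":
        """Build a survey from a fresh synthetic cohort."""
        from .synth import default_route

        route = route or default_route()
        recordings = simulate_cohort(
            n_subjects=n_subjects,
            n_trials=n_trials,
            route=route,
            master_seed=master_seed,
            bounds=bounds,
        )
        return cls.from_recordings(recordings, route, config, **preprocess_kwargs)

    # ------------------------------------------------------------------

    def fit(
        self,
        methods=("gaf_cnn",),
        threshold: float = 0.5,
        k: int = 5,
        progress: bool = False,
    ) -> "BarrierSurveyResults":
        """Run the requested methods end to end (Stage 1 + Stage 2)."""
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        results = BarrierSurveyResults(survey=self, threshold=threshold, k=k)
        truth = spatial.segment_truth(self.route, self.segmentation)
        meta = self._window_meta()
        for method in methods:
            if method == "entropy":
                self._fit_entropy(results, truth, k)
                continue
            preds = self._stage1(method, progress)
            results.predictions[method] = preds
            prob_col = "p_abnormal" if "p_abnormal" in preds else "pred_label"
            results.window_metrics[method] = evaluation.window_report(
                preds, threshold=threshold, prob_column=prob_col
            )
            joined = preds.merge(meta, on=["subject", "trial", "window_id"], validate="one_to_one")
            indicators = joined[prob_col].to_numpy(float)
            table = spatial.segment_table(
                joined["start_arclength_m"].to_numpy(float),
                indicators,
                self.route,
                self.segmentation,
                method=method,
            )
            results.segments[method] = table
            scores = table["eb_score"].to_numpy(float)
            seg_threshold = threshold
            if prob_col == "pred_label":
                # binary-label rates: flag segments by the Youden-J cut
                finite = np.isfinite(scores)
                if truth[finite].any() and not truth[finite].all():
                    seg_threshold = baselines.youden_threshold(
                        scores[finite], truth[finite].astype(int)
                    )
            results.segment_metrics[method] = self._stage2_metrics(
                scores, truth, seg_threshold, k
            )
        return results

    def _window_meta(self) -> pd.DataFrame:
        return self.dataset.table()[
            ["subject", "trial", "window_id", "start_arclength_m"]
        ]

    def _stage1(self, method: str, progress: bool) -> pd.DataFrame:
        if method == "gaf_cnn":
            return loso_cross_validate(self.dataset, self.config, progress=progress)
        if method == "raw1d_cnn":
            cfg = replace(self.config, input_mode="raw1d")
            return loso_cross_validate(self.dataset, cfg, progress=progress)
        if method == "svc":
            return baselines.svc_loso(self.dataset)
        if method == "maxle":
            return baselines.maxle_loso(self.dataset)
        raise AssertionError(method)

    def _stage2_metrics(self, scores, truth, threshold, k) -> dict:
        out = spatial.rank_metrics(scores, truth)
        n_scored = int(np.isfinite(scores).sum())
        out.update(spatial.topk_metrics(scores, truth, k=min(k, n_scored)))
        out.update(
            spatial.detection_metrics(
                scores,
                truth,
                threshold=threshold,
                route_km=self.route.length_m / 1000.0,
                segment_length_m=self.segmentation.segment_length_m,
            )
        )
        return out

    def _fit_entropy(self, results: "BarrierSurveyResults", truth, k: int) -> None:
        """Entropy baseline: segment-level only, pooled across subjects."""
        if not self.recordings:
            raise ValueError("the entropy baseline needs the raw recordings")
        per_subject: dict[int, list] = {}
        for rec in self.recordings:
            filtered = lowpass_filter(rec.imu[:, 1:4].T, rec.fs)
            mag = signal_vector_magnitude(*filtered)
            arclength = np.interp(rec.imu[:, 0], rec.positions[:, 0], rec.positions[:, 1])
            per_subject.setdefault(rec.subject_id, []).append((arclength, mag))
        pooled = baselines.pool_magnitudes(per_subject, self.segmentation.edges)
        profile = baselines.entropy_segment_scores(pooled)
        edges = self.segmentation.edges
        results.segments["entropy"] = pd.DataFrame(
            {
                "segment_id": np.arange(self.segmentation.count),
                "start_m": edges[:-1],
                "end_m": edges[1:],
                "is_barrier": truth,
                "eb_score": profile.normalized,
                "method": "entropy",
                "n_windows": [len(p) for p in pooled],
            }
        )
        results.entropy_profile = profile
        scores = profile.normalized
        finite = np.isfinite(scores)
        seg_threshold = 0.5
        if truth[finite].any() and not truth[finite].all():
            seg_threshold = baselines.youden_threshold(scores[finite], truth[finite].astype(int))
        results.segment_metrics["entropy"] = self._stage2_metrics(scores, truth, seg_threshold, k)


@dataclass
class BarrierSurveyResults:
    """Fitted results: predictions, metrics and segment tables per method."""

    survey: BarrierSurvey
    threshold: float = 0.5
    k: int = 5
    predictions: dict[str, pd.DataFrame] = field(default_factory=dict)
    window_metrics: dict[str, dict] = field(default_factory=dict)
    segments: dict[str, pd.DataFrame] = field(default_factory=dict)
    segment_metrics: dict[str, dict] = field(default_factory=dict)
    entropy_profile: object = None

    _WINDOW_COLS = ("accuracy", "f1", "sensitivity", "specificity", "auc_roc", "auc_pr", "ece", "brier")
    _SEGMENT_COLS = ("auc_pr", "auc_roc", "precision_at_k", "recall_at_k", "miou", "fp_per_km")

    def window_table(self) -> pd.DataFrame:
        rows = {
            m: {c: v.get(c, float("nan")) for c in self._WINDOW_COLS}
            for m, v in self.window_metrics.items()
        }
        return pd.DataFrame(rows).T

    def segment_table(self) -> pd.DataFrame:
        rows = {
            m: {c: v.get(c, float("nan")) for c in self._SEGMENT_COLS}
            for m, v in self.segment_metrics.items()
        }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            "Environmental-barrier survey results",
            "=" * 72,
            f"route: {self.survey.route.length_m:.0f} m, "
            f"{self.survey.segmentation.count} segments of "
            f"{self.survey.segmentation.segment_length_m:.0f} m, "
            f"{len(self.survey.route.barriers)} barriers",
            f"windows: {len(self.survey.dataset.included)} "
            f"({int(self.survey.dataset.labels().sum())} abnormal), "
            f"subjects: {len(self.survey.dataset.subjects)}",
            "",
        ]
        if self.window_metrics:
            lines += [
                "Window-level (per 2-s window; pooled LOSO predictions)",
                "-" * 72,
                self.window_table().round(3).to_string(),
                "",
            ]
        if self.segment_metrics:
            lines += [
                f"Segment-level (per {self.survey.segmentation.segment_length_m:.0f}-m segment; "
                f"k = {self.k}, threshold = {self.threshold})",
                "-" * 72,
                self.segment_table().round(3).to_string(),
                "",
            ]
        return "\n".join(lines)
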
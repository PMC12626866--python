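"""The package's standard synthetic benchmark.

A scaled study: 10 subjects x 2 trials on a 600 m route with 6
high-severity barriers (severity 0.8-1.0), windows encoded as 32x32 GASF
images (resampled from the native 200-sample window), LOSO training
capped at 10 epochs with balanced subsampling of normal training windows.
These sizes keep a full multi-method run on a single CPU core in the
minutes range while exercising every pipeline stage; docs/methods.md
discusses what they do and do not show.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classifier import ModelConfig
from .model import BarrierSurvey, BarrierSurveyResults
from .spatial import _runs, segment_truth
from .synth import benchmark_route

BENCHMARK_MODEL = ModelConfig(image_size=32, max_epochs=10, balance_training=True)


def benchmark_survey(master_seed: int, n_subjects: int = 10, n_trials: int = 2) -> BarrierSurvey:
    route = benchmark_route(600.0, 6)
    config = replace(BENCHMARK_MODEL, seed=int(master_seed))
    return BarrierSurvey.simulate(
        n_subjects=n_subjects,
        n_trials=n_trials,
        route=route,
        master_seed=int(master_seed),
        config=config,
    )


def run_benchmark(
    master_seed: int,
    methods=("gaf_cnn", "svc"),
    n_subjects: int = 10,
    n_trials: int = 2,
    progress: bool = False,
) -> BarrierSurveyResults:
    survey = benchmark_survey(master_seed, n_subjects, n_trials)
    return survey.fit(methods=methods, progress=progress)


def barrier_zone_coverage(results: BarrierSurveyResults, method: str = "gaf_cnn") -> dict:
    """Top-(B+2) localization check, B = number of true barrier segments.

    Ranks segments by the method's EB score and reports whether every
    contiguous barrier zone (maximal run of truth segments) intersects at
    least one of the top B+2 segments.
    """
    survey = results.survey
    truth = segment_truth(survey.route, survey.segmentation)
    table = results.segments[method]
    scores = table["eb_score"].to_numpy(float)
    b = int(truth.sum())
    k = b + 2
    ok = np.flatnonzero(np.isfinite(scores))
    order = ok[np.lexsort((ok, -scores[ok]))][:k]
    top = set(order.tolist())
    zones = _runs(truth)
    covered = [any(s in top for s in range(z0, z1)) for z0, z1 in zones]
    return {
        "n_barrier_segments": b,
        "k": k,
        "n_zones": len(zones),
        "n_zones_covered": int(sum(covered)),
        "all_zones_covered": bool(all(covered)),
    }
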
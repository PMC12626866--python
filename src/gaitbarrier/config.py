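"""Run configuration: schema, defaults, validation and (de)serialisation.

A run config is a YAML/JSON mapping with blocks for simulation,
preprocessing, encoding, the classifier, the baselines and evaluation.
Missing fields are filled with the selected defaults; out-of-range values
are rejected with messages naming the field. The resolved config is a
serialisation fixed point: dump -> validate -> dump is identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import ModelConfig
from .synth import Barrier, GenerationBounds, RouteSpec, default_route


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 20
    n_trials: int = 2
    master_seed: int = 42
    fs: float = 100.0
    route_length_m: float = 1200.0
    barriers: tuple[dict, ...] = ()  # empty -> default surveyed route

    def route(self) -> RouteSpec:
        if not self.barriers:
            return default_route(self.route_length_m)
        return RouteSpec(
            length_m=self.route_length_m,
            barriers=tuple(Barrier(**b) for b in self.barriers),
        )


@dataclass(frozen=True)
class PreprocessConfig:
    cutoff_hz: float = 5.0
    filter_order: int = 4
    zero_phase: bool = False
    window_s: float = 2.0
    overlap: float = 0.5
    labeling_radius_m: float = 1.0


@dataclass(frozen=True)
class EncodingConfig:
    gaf_type: str = "GASF"
    channels: tuple[str, ...] = ("SVM_Acc",)
    image_size: int = 200


@dataclass(frozen=True)
class BaselineConfig:
    svc_C: float = 10.0
    svc_gamma: float = 1e-2
    maxle_m: int = 6
    maxle_tau: int = 5
    entropy_bins: int = 40
    entropy_epsilon: float = 1e-6


@dataclass(frozen=True)
class EvaluationConfig:
    calibration_bins: int = 10
    k: int = 5
    threshold: float = 0.5
    segment_length_m: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    methods: tuple[str, ...] = ("gaf_cnn", "raw1d_cnn", "svc", "maxle", "entropy")
    output_dir: str = "runs"

    def model_config(self) -> ModelConfig:
        return dataclasses.replace(
            self.model,
            channels=self.encoding.channels,
            image_size=self.encoding.image_size,
            seed=self.simulation.master_seed,
        ).validate()


def _as_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_dict(v) for k, v in obj.items()}
    return obj


def to_dict(config: RunConfig) -> dict:
    return _as_dict(config)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(to_dict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


_TUPLE_FIELDS = {
    "barriers",
    "channels",
    "methods",
    "conv_kernels",
    "conv_filters",
    "pool_after",
}


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown field(s) in {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


_BLOCKS = {
    "simulation": SimulationConfig,
    "preprocess": PreprocessConfig,
    "encoding": EncodingConfig,
    "model": ModelConfig,
    "baseline": BaselineConfig,
    "evaluation": EvaluationConfig,
}


def validate_config(raw: dict | None) -> RunConfig:
    """Resolve a raw mapping into a RunConfig, injecting defaults and
    rejecting out-of-range values with messages naming the field."""
    raw = dict(raw or {})
    kwargs = {}
    for name, cls in _BLOCKS.items():
        kwargs[name] = _build(cls, raw.pop(name, {}) or {}, name)
    for key in ("methods",):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw.pop("output_dir"))
    if raw:
        raise ValueError(f"unknown top-level field(s): {sorted(raw)}")
    config = RunConfig(**kwargs)
    _check(config)
    return config


def _check(config: RunConfig) -> None:
    p = config.preprocess
    s = config.simulation
    if not p.cutoff_hz < s.fs / 2:
        raise ValueError(
            f"preprocess.cutoff_hz ({p.cutoff_hz}) must be below Nyquist ({s.fs / 2})"
        )
    if not 0 <= p.overlap < 1:
        raise ValueError(f"preprocess.overlap ({p.overlap}) must lie in [0, 1)")
    if p.window_s * s.fs < 2:
        raise ValueError("preprocess.window_s too small: a window needs >= 2 samples")
    if p.labeling_radius_m < 0:
        raise ValueError("preprocess.labeling_radius_m must be nonnegative")
    if config.encoding.gaf_type != "GASF":
        raise ValueError("encoding.gaf_type: only GASF is implemented")
    if config.encoding.image_size < 8:
        raise ValueError("encoding.image_size must be at least 8")
    if config.evaluation.k <= 0:
        raise ValueError("evaluation.k must be positive")
    if not 0 <= config.evaluation.threshold <= 1:
        raise ValueError("evaluation.threshold must lie in [0, 1]")
    if config.evaluation.segment_length_m <= 0:
        raise ValueError("evaluation.segment_length_m must be positive")
    if config.baseline.svc_C <= 0 or config.baseline.svc_gamma <= 0:
        raise ValueError("baseline.svc_C and baseline.svc_gamma must be positive")
    if config.baseline.maxle_m < 2 or config.baseline.maxle_tau < 1:
        raise ValueError("baseline.maxle_m must be >= 2 and baseline.maxle_tau >= 1")
    if config.baseline.entropy_bins < 2 or config.baseline.entropy_epsilon < 0:
        raise ValueError("baseline.entropy_bins >= 2 and entropy_epsilon >= 0 required")
    config.model_config()
    GenerationBounds().validate()
    if s.n_subjects < 1 or s.n_trials < 1:
        raise ValueError("simulation.n_subjects and simulation.n_trials must be >= 1")
    config.simulation.route()  # validates geometry


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON) config file; None or empty file -> defaults."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    return validate_config(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=False))
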
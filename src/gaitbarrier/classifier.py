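"""Lightweight gait CNN: GASF-image (2-D) and raw time-series (1-D) variants.

Architecture (2-D): conv 16@5x5 -> ReLU -> maxpool 2x2 -> conv 32@3x3 ->
ReLU -> maxpool 2x2 -> conv 32@3x3 -> ReLU -> flatten -> dense 64 -> ReLU
-> dense 2 softmax; same padding, stride 1 throughout. The raw 1-D ablation
mirrors the depth and widths with 1-D convolutions on the 200-sample
accelerometer-magnitude window. Training uses Adam, label smoothing, L2
weight decay, dropout, light rotation/translation augmentation, and early
stopping on a subject-stratified inner validation split. Evaluation is
leave-one-subject-out (LOSO): each subject's windows are the held-out test
set of exactly one fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .gaf import gasf_matrix, minmax_normalize, resample_linear
from .preprocess import CHANNEL_NAMES, GaitWindow, WindowDataset, balance_subsample


@dataclass(frozen=True)
class ModelConfig:
    """Classifier hyperparameters; defaults are the selected configuration."""

    conv_kernels: tuple[int, ...] = (5, 3, 3)
    conv_filters: tuple[int, ...] = (16, 32, 32)
    pool_after: tuple[bool, ...] = (True, True, False)  # max 2x2 where True
    dense_units: int = 64
    dropout_conv: float = 0.25
    dropout_dense: float = 0.50
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 1e-4
    label_smoothing: float = 0.05
    early_stop_patience: int = 5
    max_epochs: int = 50
    init: str = "he_normal"
    seed: int = 42
    rotation_deg: float = 5.0
    translation_px: int = 3
    augment_enabled: bool = True
    input_mode: str = "gaf2d"  # or "raw1d"
    channels: tuple[str, ...] = ("SVM_Acc",)
    image_size: int = 200
    raw_length: int = 200
    head: str = "flatten"  # or "gap" (global average pooling, compact head)
    val_fraction: float = 0.2
    balance_training: bool = False

    def validate(self) -> "ModelConfig":
        if self.input_mode not in ("gaf2d", "raw1d"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.init != "he_normal":
            raise ValueError("only he_normal initialisation is supported")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        unknown = set(self.channels) - set(CHANNEL_NAMES)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")
        if len(self.conv_kernels) != len(self.conv_filters) or len(self.conv_kernels) != len(
            self.pool_after
        ):
            raise ValueError("conv block definitions must have equal length")
        return self


def build_model(config: ModelConfig) -> tuple[nn.Sequential, list[dict]]:
    """Instantiate the 2-D GASF CNN and describe its layers.

    Returns the network and a layer table with output shapes and parameter
    counts (the input is a C-channel image_size x image_size stack).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    c, s = len(config.channels), config.image_size
    layers: list[nn.Layer] = []
    desc: list[dict] = []

    def add(layer, name, shape):
        layers.append(layer)
        desc.append({"layer": name, "output_shape": shape, "n_params": layer.n_params()})

    h = w = s
    c_in = c
    for i, (k, f, pool) in enumerate(
        zip(config.conv_kernels, config.conv_filters, config.pool_after)
    ):
        add(nn.Conv2D(c_in, f, k, rng, skip_input_grad=(i == 0)), f"conv{i + 1} ({k}x{k}/{f})", (f, h, w))
        add(nn.ReLU(), f"relu{i + 1}", (f, h, w))
        if pool:
            h, w = h // 2, w // 2
            add(nn.MaxPool2D(), f"maxpool{i + 1} (2x2)", (f, h, w))
        if config.dropout_conv > 0:
            add(nn.Dropout(config.dropout_conv), f"dropout{i + 1}", (f, h, w))
        c_in = f
    if h < 1 or w < 1:
        raise ValueError("input image too small for the pooling depth")
    if config.head == "gap":
        add(nn.GlobalAvgPool(), "global_avg_pool", (c_in,))
        flat = c_in
    else:
        add(nn.Flatten(), "flatten", (c_in * h * w,))
        flat = c_in * h * w
    add(nn.Dense(flat, config.dense_units, rng), f"dense ({config.dense_units})", (config.dense_units,))
    add(nn.ReLU(), "relu_dense", (config.dense_units,))
    if config.dropout_dense > 0:
        add(nn.Dropout(config.dropout_dense), "dropout_dense", (config.dense_units,))
    add(nn.Dense(config.dense_units, 2, rng), "dense (2) + softmax", (2,))
    return nn.Sequential(layers), desc


def build_raw1d_model(config: ModelConfig) -> tuple[nn.Sequential, list[dict]]:
    """The raw 1-D CNN ablation: same depth/widths with 1-D convolutions."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n = config.raw_length
    layers: list[nn.Layer] = []
    desc: list[dict] = []

    def add(layer, name, shape):
        layers.append(layer)
        desc.append({"layer": name, "output_shape": shape, "n_params": layer.n_params()})

    c_in = 1
    for i, (k, f, pool) in enumerate(
        zip(config.conv_kernels, config.conv_filters, config.pool_after)
    ):
        add(nn.Conv1D(c_in, f, k, rng, skip_input_grad=(i == 0)), f"conv1d_{i + 1} ({k}/{f})", (f, n))
        add(nn.ReLU(), f"relu{i + 1}", (f, n))
        if pool:
            n //= 2
            add(nn.MaxPool1D(), f"maxpool{i + 1} (2)", (f, n))
        if config.dropout_conv > 0:
            add(nn.Dropout(config.dropout_conv), f"dropout{i + 1}", (f, n))
        c_in = f
    add(nn.Flatten(), "flatten", (c_in * n,))
    add(nn.Dense(c_in * n, config.dense_units, rng), f"dense ({config.dense_units})", (config.dense_units,))
    add(nn.ReLU(), "relu_dense", (config.dense_units,))
    if config.dropout_dense > 0:
        add(nn.Dropout(config.dropout_dense), "dropout_dense", (config.dense_units,))
    add(nn.Dense(config.dense_units, 2, rng), "dense (2) + softmax", (2,))
    return nn.Sequential(layers), desc


def augment(image: np.ndarray, rng: np.random.Generator, rotation_deg=5.0, translation_px=3):
    """Random rotation (uniform +/- rotation_deg) and integer translation
    (uniform +/- translation_px per axis), bilinear resampling, edge
    replication. Applied to training images only; no flips or shears.

    ``image`` is channels-last (S, S, C); all channels share one draw.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError("augmentation expects square images")
    angle = rng.uniform(-rotation_deg, rotation_deg)
    shifts = rng.integers(-translation_px, translation_px + 1, size=2)
    rotated = ndimage.rotate(
        image, angle, axes=(0, 1), reshape=False, order=1, mode="nearest", prefilter=False
    )
    return ndimage.shift(rotated, (*shifts, 0), order=0, mode="nearest")


def encode_gaf_stack(
    windows: list[GaitWindow], channels: tuple[str, ...], image_size: int
) -> np.ndarray:
    """Encode windows as a channels-last (B, S, S, C) float32 GASF stack."""
    idx = [CHANNEL_NAMES.index(c) for c in channels]
    out = np.empty((len(windows), image_size, image_size, len(idx)), dtype=nn.DTYPE)
    for b, w in enumerate(windows):
        for ci, c in enumerate(idx):
            x = resample_linear(w.samples[c], image_size)
            out[b, :, :, ci] = gasf_matrix(minmax_normalize(x))
    return out


def encode_raw_stack(windows: list[GaitWindow], raw_length: int) -> np.ndarray:
    """(B, L, 1) raw accelerometer-magnitude sequences (resampled)."""
    idx = CHANNEL_NAMES.index("SVM_Acc")
    out = np.empty((len(windows), raw_length, 1), dtype=nn.DTYPE)
    for b, w in enumerate(windows):
        out[b, :, 0] = resample_linear(w.samples[idx], raw_length)
    return out


def encode_inputs(windows: list[GaitWindow], config: ModelConfig) -> np.ndarray:
    if config.input_mode == "gaf2d":
        return encode_gaf_stack(windows, config.channels, config.image_size)
    return encode_raw_stack(windows, config.raw_length)


def stratified_inner_split(
    subjects: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-stratified split: whole subjects go to the inner validation
    set until it holds ~val_fraction of the windows. Returns boolean masks
    (train, val) over the input array."""
    uniq = np.array(sorted(set(subjects.tolist())))
    if len(uniq) < 2:
        raise ValueError("inner split needs at least 2 subjects")
    order = rng.permutation(uniq)
    target = val_fraction * len(subjects)
    val_subjects, n_val = [], 0
    for s in order:
        if n_val >= target or len(val_subjects) >= len(uniq) - 1:
            break
        val_subjects.append(s)
        n_val += int(np.sum(subjects == s))
    val_mask = np.isin(subjects, val_subjects)
    return ~val_mask, val_mask


@dataclass
class TrainedModel:
    net: nn.Sequential
    config: ModelConfig
    description: list[dict]
    log: list[dict] = field(default_factory=list)
    raw_stats: tuple[float, float] | None = None  # raw1d standardisation (mean, sd)


def _standardize_raw(x: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mean, sd = stats
    return ((x - mean) / sd).astype(nn.DTYPE)


def _fit(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> TrainedModel:
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    builder = build_model if config.input_mode == "gaf2d" else build_raw1d_model
    net, desc = builder(config)
    model = TrainedModel(net=net, config=config, description=desc)
    if config.input_mode == "raw1d":
        model.raw_stats = (float(x_train.mean()), float(x_train.std() + 1e-8))
        x_train = _standardize_raw(x_train, model.raw_stats)
        x_val = _standardize_raw(x_val, model.raw_stats)
    opt = nn.Adam(net, lr=config.learning_rate, weight_decay=config.weight_decay)
    best_val, best_weights, stale = np.inf, net.get_weights(), 0
    n = len(x_train)
    do_augment = config.augment_enabled and config.input_mode == "gaf2d"
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if do_augment:
                xb = np.stack(
                    [augment(im, rng, config.rotation_deg, config.translation_px) for im in xb]
                )
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = nn.cross_entropy_with_smoothing(
                logits, y_train[idx], config.label_smoothing
            )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = net.forward(x_val, train=False)
        val_loss, _ = nn.cross_entropy_with_smoothing(val_logits, y_val, config.label_smoothing)
        model.log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": float(val_loss)}
        )
        if val_loss < best_val - 1e-6:
            best_val, best_weights, stale = val_loss, net.get_weights(), 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    net.set_weights(best_weights)
    return model


def train_fold(
    train_windows: list[GaitWindow],
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    x_all: np.ndarray | None = None,
) -> TrainedModel:
    """Train one fold: subject-stratified 20% inner validation split,
    early stopping on validation loss, best-validation weights restored.

    ``x_all`` may carry pre-encoded inputs aligned with train_windows.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    if x_all is None:
        x_all = encode_inputs(train_windows, config)
    subjects = np.array([w.subject_id for w in train_windows])
    train_mask, val_mask = stratified_inner_split(subjects, config.val_fraction, rng)
    y = np.array([1 if w.is_abnormal else 0 for w in train_windows])
    tr_idx = np.flatnonzero(train_mask)
    val_idx = np.flatnonzero(val_mask)
    if config.balance_training:
        # balanced subsampling of normals in both the inner-train set and
        # the validation set, so early stopping tracks the same objective
        def _balanced(idx):
            selected = balance_subsample([train_windows[i] for i in idx], rng)
            chosen = {id(w) for w in selected}
            return np.array([i for i in idx if id(train_windows[i]) in chosen])

        tr_idx, val_idx = _balanced(tr_idx), _balanced(val_idx)
    model = _fit(x_all[tr_idx], y[tr_idx], x_all[val_idx], y[val_idx], config, rng)
    model.inner_val_subjects = sorted(set(subjects[val_mask].tolist()))
    model.inner_train_subjects = sorted(set(subjects[train_mask].tolist()))
    return model


def predict_proba(model: TrainedModel, inputs: np.ndarray, batch: int = 512) -> np.ndarray:
    """Two-class probabilities (normal, abnormal), deterministic inference."""
    if inputs.ndim != 4 and model.config.input_mode == "gaf2d":
        raise ValueError("gaf2d model expects channels-last (B, S, S, C) input")
    if inputs.ndim != 3 and model.config.input_mode == "raw1d":
        raise ValueError("raw1d model expects (B, L, 1) input")
    if model.raw_stats is not None:
        inputs = _standardize_raw(inputs, model.raw_stats)
    probs = []
    for start in range(0, len(inputs), batch):
        logits = model.net.forward(inputs[start : start + batch], train=False)
        probs.append(nn.softmax(logits))
    return np.concatenate(probs) if probs else np.empty((0, 2))


def loso_cross_validate(
    dataset: WindowDataset,
    config: ModelConfig,
    progress: bool = False,
) -> pd.DataFrame:
    """Leave-one-subject-out: one fold per subject, that subject held out.

    Returns pooled held-out predictions: one row per non-excluded window
    with columns subject, trial, window_id, fold_id, p_abnormal, label.
    The partition property (disjoint, exhaustive) is asserted every run.
    """
    config.validate()
    windows = dataset.included
    subjects = sorted({w.subject_id for w in windows})
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    x_all = encode_inputs(windows, config)
    subj_arr = np.array([w.subject_id for w in windows])
    records = []
    seen: set[tuple] = set()
    for fold_id, held_out in enumerate(subjects):
        test_mask = subj_arr == held_out
        train_idx = np.flatnonzero(~test_mask)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3, fold_id)))
        model = train_fold(
            [windows[i] for i in train_idx], config, rng=rng, x_all=x_all[train_idx]
        )
        assert held_out not in model.inner_val_subjects
        assert held_out not in model.inner_train_subjects
        p = predict_proba(model, x_all[test_mask])[:, 1]
        for prob, i in zip(p, np.flatnonzero(test_mask)):
            w = windows[i]
            key = (w.subject_id, w.trial_id, w.window_id)
            assert key not in seen, "LOSO folds must not overlap"
            seen.add(key)
            records.append(
                {
                    "subject": w.subject_id,
                    "trial": w.trial_id,
                    "window_id": w.window_id,
                    "fold_id": fold_id,
                    "p_abnormal": float(prob),
                    "label": 1 if w.is_abnormal else 0,
                }
            )
        if progress:
            print(f"fold {fold_id + 1}/{len(subjects)} (subject {held_out}) done")
    assert len(seen) == len(windows), "LOSO folds must cover every window exactly once"
    return pd.DataFrame(records)


def save_checkpoint(model: TrainedModel, path: str | Path, fold_id: int | None = None) -> None:
    """Weights as .npz plus a JSON sidecar manifest (config, layers, log)."""
    path = Path(path)
    np.savez(path, *model.net.get_weights())
    sidecar = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(model.config).items()},
        "fold_id": fold_id,
        "layers": model.description,
        "n_params": model.net.n_params(),
        "log": model.log,
        "raw_stats": model.raw_stats,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["config"]
    for key in ("conv_kernels", "conv_filters", "pool_after", "channels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    builder = build_model if config.input_mode == "gaf2d" else build_raw1d_model
    net, desc = builder(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        net.set_weights([data[k] for k in data.files])
    model = TrainedModel(net=net, config=config, description=desc, log=sidecar["log"])
    if sidecar.get("raw_stats"):
        model.raw_stats = tuple(sidecar["raw_stats"])
    return model
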
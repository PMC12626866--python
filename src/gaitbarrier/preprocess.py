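"""IMU preprocessing: Butterworth filtering, signal vector magnitude,
2-s sliding windows, and spatial barrier labeling.

The raw 6-axis stream (3-axis accelerometer, 3-axis gyroscope, 100 Hz) is
low-pass filtered, augmented with the two orientation-invariant magnitude
channels, cut into fixed windows with 50% overlap, and each window is
labeled abnormal when its spatial span lies within the labeling radius of
a known environmental barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import RouteSpec, TrialRecording

#: Fixed channel order of a processed window.
CHANNEL_NAMES = (
    "Acc_X",
    "Acc_Y",
    "Acc_Z",
    "Gyro_X",
    "Gyro_Y",
    "Gyro_Z",
    "SVM_Acc",
    "SVM_Gyro",
)

NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass
class GaitWindow:
    """One fixed-duration, 8-channel slice of a trial."""

    subject_id: int
    trial_id: int
    window_id: int
    start_t: float
    samples: np.ndarray  # (8, L)
    fs: float
    start_arclength_m: float = np.nan
    end_arclength_m: float = np.nan
    label: str = NORMAL
    excluded: bool = False

    @property
    def L(self) -> int:
        return self.samples.shape[1]

    @property
    def is_abnormal(self) -> bool:
        return self.label == ABNORMAL


def lowpass_filter(
    series: np.ndarray,
    fs: float,
    cutoff: float = 5.0,
    order: int = 4,
    zero_phase: bool = False,
) -> np.ndarray:
    """4th-order Butterworth low-pass, single-pass causal by default.

    ``zero_phase=True`` switches to forward-backward filtering, which
    removes phase lag but squares the magnitude response.
    """
    if not cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    series = np.asarray(series, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, series, axis=-1)
    # steady-state initial conditions for the first sample value suppress
    # the startup transient (a constant series passes through unchanged)
    zi = sps.sosfilt_zi(sos)  # (n_sections, 2)
    x0 = np.take(series, 0, axis=-1)
    if series.ndim == 1:
        out, _ = sps.sosfilt(sos, series, zi=zi * x0)
    else:
        out, _ = sps.sosfilt(sos, series, axis=-1, zi=zi[:, None, :] * x0[None, :, None])
    return out


def signal_vector_magnitude(ax, ay, az) -> np.ndarray:
    """Pointwise Euclidean norm sqrt(x^2 + y^2 + z^2) of a triaxial signal."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not ax.shape == ay.shape == az.shape:
        raise ValueError("axis series must have equal length")
    return np.sqrt(ax * ax + ay * ay + az * az)


def build_channels(
    imu: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 4, zero_phase: bool = False
) -> np.ndarray:
    """Filter a (N, 6) raw IMU array and append the SVM channels -> (8, N)."""
    imu = np.asarray(imu, dtype=float)
    filtered = lowpass_filter(imu.T, fs, cutoff=cutoff, order=order, zero_phase=zero_phase)
    svm_acc = signal_vector_magnitude(*filtered[0:3])
    svm_gyro = signal_vector_magnitude(*filtered[3:6])
    return np.vstack([filtered, svm_acc[None, :], svm_gyro[None, :]])


def window_count(n_samples: int, length: int, step: int) -> int:
    """Number of full windows: floor((N - L)/step) + 1, zero if N < L."""
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


def segment_windows(
    channels: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    t0: float = 0.0,
    subject_id: int = 0,
    trial_id: int = 0,
) -> list[GaitWindow]:
    """Cut an (8, N) channel array into fixed windows.

    Window length L = round(window_s * fs); step = round(L * (1 - overlap)),
    ties rounding half up. Trailing partial windows are discarded.
    """
    L = int(np.floor(window_s * fs + 0.5))
    if L < 2:
        raise ValueError("window must span at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = max(1, int(np.floor(L * (1.0 - overlap) + 0.5)))
    n = channels.shape[1]
    windows = []
    for w, start in enumerate(range(0, n - L + 1, step)):
        windows.append(
            GaitWindow(
                subject_id=subject_id,
                trial_id=trial_id,
                window_id=w,
                start_t=t0 + start / fs,
                samples=channels[:, start : start + L],
                fs=fs,
            )
        )
    return windows


def attach_arclength(
    windows: list[GaitWindow], positions: np.ndarray, window_s: float = 2.0
) -> list[GaitWindow]:
    """Interpolate each window's entry/exit arclength from the 1 Hz trace."""
    t, s = positions[:, 0], positions[:, 1]
    for w in windows:
        w.start_arclength_m = float(np.interp(w.start_t, t, s))
        w.end_arclength_m = float(np.interp(w.start_t + window_s, t, s))
    return windows


def label_windows(
    windows: list[GaitWindow], route: RouteSpec, radius_m: float = 1.0
) -> list[GaitWindow]:
    """Label a window abnormal iff its spatial span intersects any barrier
    extent inflated by ±radius_m; otherwise normal. Idempotent."""
    intervals = [
        (b.position_m - radius_m, b.position_m + b.extent_m + radius_m) for b in route.barriers
    ]
    for w in windows:
        lo, hi = w.start_arclength_m, w.end_arclength_m
        hit = any(lo <= b_hi and hi >= b_lo for b_lo, b_hi in intervals)
        w.label = ABNORMAL if hit else NORMAL
    return windows


def apply_exclusions(windows: list[GaitWindow], annotations) -> list[GaitWindow]:
    """Flag annotated borderline windows; they stay stored but are omitted
    from training and evaluation sets.

    ``annotations`` is an iterable of (subject_id, trial_id, window_id).
    """
    keys = {(w.subject_id, w.trial_id, w.window_id) for w in windows}
    marks = set(map(tuple, annotations))
    unknown = marks - keys
    if unknown:
        raise ValueError(f"annotations reference unknown windows: {sorted(unknown)[:5]}")
    for w in windows:
        if (w.subject_id, w.trial_id, w.window_id) in marks:
            w.excluded = True
    return windows


@dataclass
class WindowDataset:
    """All windows of a cohort plus per-window metadata access."""

    windows: list[GaitWindow] = field(default_factory=list)
    fs: float = 100.0
    window_s: float = 2.0

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def included(self) -> list[GaitWindow]:
        return [w for w in self.windows if not w.excluded]

    @property
    def subjects(self) -> list[int]:
        return sorted({w.subject_id for w in self.windows})

    def labels(self, windows=None) -> np.ndarray:
        ws = self.included if windows is None else windows
        return np.array([1 if w.is_abnormal else 0 for w in ws], dtype=int)

    def channel(self, name: str, windows=None) -> np.ndarray:
        ws = self.included if windows is None else windows
        idx = CHANNEL_NAMES.index(name)
        return np.stack([w.samples[idx] for w in ws])

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "subject": w.subject_id,
                "trial": w.trial_id,
                "window_id": w.window_id,
                "start_t": w.start_t,
                "start_arclength_m": w.start_arclength_m,
                "end_arclength_m": w.end_arclength_m,
                "label": w.label,
                "excluded": w.excluded,
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)


def preprocess_recording(
    rec: TrialRecording,
    route: RouteSpec,
    cutoff: float = 5.0,
    order: int = 4,
    zero_phase: bool = False,
    window_s: float = 2.0,
    overlap: float = 0.5,
    radius_m: float = 1.0,
) -> list[GaitWindow]:
    """Full per-trial pipeline: filter -> magnitudes -> windows -> labels."""
    channels = build_channels(rec.imu[:, 1:7], rec.fs, cutoff, order, zero_phase)
    windows = segment_windows(
        channels,
        rec.fs,
        window_s=window_s,
        overlap=overlap,
        t0=float(rec.imu[0, 0]),
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
    )
    attach_arclength(windows, rec.positions, window_s=window_s)
    return label_windows(windows, route, radius_m=radius_m)


def preprocess_cohort(recordings, route: RouteSpec, **kwargs) -> WindowDataset:
    """Preprocess every trial of a cohort into one WindowDataset."""
    ds = WindowDataset(
        fs=recordings[0].fs if recordings else 100.0,
        window_s=kwargs.get("window_s", 2.0),
    )
    for rec in recordings:
        ds.windows.extend(preprocess_recording(rec, route, **kwargs))
    return ds


def save_window_dataset(ds: WindowDataset, table_path, samples_path) -> None:
    """Persist a dataset as a CSV metadata table plus an array store."""
    ds.table().to_csv(table_path, index=False)
    np.savez_compressed(
        samples_path, samples=np.stack([w.samples for w in ds.windows]).astype(np.float32)
    )


def load_window_dataset(table_path, samples_path, fs: float, window_s: float = 2.0) -> WindowDataset:
    table = pd.read_csv(table_path)
    with np.load(samples_path) as data:
        samples = data["samples"]
    if len(table) != len(samples):
        raise ValueError("window table and sample store disagree on window count")
    windows = [
        GaitWindow(
            subject_id=int(row.subject),
            trial_id=int(row.trial),
            window_id=int(row.window_id),
            start_t=float(row.start_t),
            samples=samples[i].astype(float),
            fs=fs,
            start_arclength_m=float(row.start_arclength_m),
            end_arclength_m=float(row.end_arclength_m),
            label=str(row.label),
            excluded=bool(row.excluded),
        )
        for i, row in enumerate(table.itertuples())
    ]
    return WindowDataset(windows=windows, fs=fs, window_s=window_s)


def balance_subsample(windows: list[GaitWindow], rng: np.random.Generator) -> list[GaitWindow]:
    """Optional subsampler: keep all abnormal windows and an equal-size
    random subset of normal windows (order preserved)."""
    abnormal = [w for w in windows if w.is_abnormal]
    normal = [w for w in windows if not w.is_abnormal]
    if len(normal) <= len(abnormal):
        return list(windows)
    keep = set(rng.choice(len(normal), size=len(abnormal), replace=False).tolist())
    kept_normals = {id(w) for i, w in enumerate(normal) if i in keep}
    return [w for w in windows if w.is_abnormal or id(w) in kept_normals]
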
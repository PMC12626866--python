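"""Gramian Angular Summation Field (GASF) encoding of gait windows.

A 1-D window channel is min-max normalised to [-1, 1], mapped to polar
coordinates ``theta_t = arccos(x_t)``, ``r_t = t/L`` (t = 1..L), and the
matrix of pairwise angular sums ``G_ij = cos(theta_i + theta_j)`` is formed.
Periodic gait yields a regular lattice texture; barrier-induced
perturbations (phase shifts, amplitude spikes, irregular oscillations)
appear as localized distortions that a 2-D CNN can learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import CHANNEL_NAMES, GaitWindow

#: Default channel encoded for the CNN: accelerometer signal vector magnitude.
DEFAULT_CHANNELS = ("SVM_Acc",)

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class PolarSeries:
    """Polar representation of a normalised window channel."""

    theta: np.ndarray  # angles in [0, pi], radians
    radius: np.ndarray  # t/L for t = 1..L, strictly increasing, ends at 1
    L: int


@dataclass(frozen=True)
class GafImage:
    """One L x L GASF matrix for a single window channel."""

    matrix: np.ndarray
    channel: str
    window_id: int | None = None
    degenerate: bool = field(default=False)  # constant input window


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max normalise to [-1, 1]; a constant input maps to all zeros."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalise an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (2.0 * x - hi - lo) / (hi - lo)


def to_polar(x: np.ndarray) -> PolarSeries:
    """Map a normalised series to (theta, r) polar coordinates."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in normalised input")
    if np.any(np.abs(x) > 1.0 + _CLIP_TOL):
        raise ValueError("normalised input outside [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    L = x.size
    theta = np.arccos(x)
    radius = np.arange(1, L + 1, dtype=float) / L
    return PolarSeries(theta=theta, radius=radius, L=L)


def gasf_matrix(x: np.ndarray) -> np.ndarray:
    """GASF matrix ``cos(theta_i + theta_j)`` of a normalised series.

    Evaluated in the algebraically equivalent outer-product form
    ``x_i x_j - sqrt(1 - x_i^2) sqrt(1 - x_j^2)``, which avoids the
    trigonometric round trip.
    """
    to_polar(x)  # validates finiteness and range
    x = np.clip(np.asarray(x, dtype=float), -1.0, 1.0)
    comp = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    return np.outer(x, x) - np.outer(comp, comp)


def resample_linear(values: np.ndarray, length: int) -> np.ndarray:
    """Linearly resample a series to ``length`` points (no-op if equal)."""
    values = np.asarray(values, dtype=float)
    if values.size == length:
        return values
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, values)


def encode_window(
    window: GaitWindow,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    image_size: int | None = None,
) -> list[GafImage]:
    """Encode the requested channels of one window as GASF images.

    If ``image_size`` differs from the window length the channel is first
    linearly resampled; at the native 100 Hz x 2.0 s window the length is
    exactly 200 and no resampling occurs.
    """
    unknown = set(channels) - set(CHANNEL_NAMES)
    if unknown:
        raise ValueError(f"unknown channel tag(s): {sorted(unknown)}")
    out = []
    for name in channels:
        raw = window.samples[CHANNEL_NAMES.index(name)]
        if image_size is not None:
            raw = resample_linear(raw, image_size)
        degenerate = bool(np.ptp(raw) == 0)
        out.append(
            GafImage(
                matrix=gasf_matrix(minmax_normalize(raw)),
                channel=name,
                window_id=window.window_id,
                degenerate=degenerate,
            )
        )
    return out


def render_image(matrix: np.ndarray) -> np.ndarray:
    """Render a GASF matrix as an 8-bit grayscale raster.

    Intensity = round(255 * (g + 1) / 2), rounding half up. Inspection and
    export only — the classifier consumes the float matrix.
    """
    g = np.asarray(matrix, dtype=float)
    if np.any(g < -1.0) or np.any(g > 1.0):
        raise ValueError("GASF entries must lie in [-1, 1]")
    return np.floor(255.0 * (g + 1.0) / 2.0 + 0.5).astype(np.uint8)


def save_png(matrix: np.ndarray, path) -> None:
    """Export a GASF matrix as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(render_image(matrix), mode="L").save(path)
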
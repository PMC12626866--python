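"""Synthetic older-adult gait cohort simulator with known barrier locations.

Real deployments record 6-axis smartphone IMU at 100 Hz while a pedestrian
walks an urban route whose hazards (uneven sidewalk, curb drops, narrow
alleys, driveway crossings) are surveyed in advance. This module emulates
that setting so every downstream stage — filtering, GASF encoding, the CNN,
the baselines and the segment mapping — can be exercised end to end with
exact ground truth:

* quasi-periodic gait as a sum of harmonics of a per-subject step
  frequency (1–2 Hz) with per-axis amplitudes and phases;
* walking speed drawn per subject (default 1.0–1.2 m/s) and integrated
  into a 1-D arclength position trace logged at 1 Hz;
* transient barrier perturbations — amplitude scaling, an additive
  half-sine jerk, and a phase advance — confined to the traversal span of
  each barrier (floor 1.0 s), scaled by barrier severity and moderated by
  a per-subject caution factor.

Geometry is 1-D arclength along the route; no lat/lon is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FS_DEFAULT = 100.0
GRAVITY = 9.81
#: IMU channel column order in exported files.
IMU_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

BARRIER_KINDS = ("uneven_sidewalk", "curb_drop", "narrow_alley", "driveway")

# Perturbation template gains (calibration knobs, not field-measured values):
# amplitude scaling, additive jerk on acc (m/s^2) and gyro (rad/s), phase
# advance (rad), and irregular-oscillation gain relative to the channel's
# fundamental amplitude — each multiplied by severity and the caution
# moderation.
K_AMPLITUDE = 0.8
K_JERK_ACC = 3.0
K_JERK_GYRO = 1.2
K_PHASE = 0.8
K_IRREGULAR = 1.2
IRREGULAR_BAND_HZ = (1.0, 4.5)
JERK_DURATION_S = 0.35
SPEED_DIP_FRAC = 0.15
MIN_EVENT_S = 1.0
# Negotiation envelope: gait starts adjusting while approaching a visible
# hazard and recovers after clearing it. Intensity ramps 0 -> 1 over the
# anticipation distance, holds 1 across the extent (floor MIN_EVENT_S),
# and ramps 1 -> 0 over the recovery distance. These distances match the
# ±1 m labeling radius of the window-labeling stage.
ANTICIPATION_M = 1.0
RECOVERY_M = 1.0


@dataclass(frozen=True)
class Barrier:
    position_m: float
    extent_m: float
    severity: float
    kind: str = "uneven_sidewalk"

    def __post_init__(self):
        if self.extent_m <= 0:
            raise ValueError("barrier extent must be positive")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.kind not in BARRIER_KINDS:
            raise ValueError(f"unknown barrier kind {self.kind!r}")


@dataclass(frozen=True)
class RouteSpec:
    """Surveyed route: total arclength and the barrier inventory."""

    length_m: float
    barriers: tuple[Barrier, ...] = ()

    def __post_init__(self):
        if self.length_m <= 0:
            raise ValueError("route length must be positive")
        for b in self.barriers:
            if not 0 <= b.position_m < self.length_m:
                raise ValueError(f"barrier at {b.position_m} m lies outside the route")
        spans = sorted((b.position_m, b.position_m + b.extent_m) for b in self.barriers)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi:
                raise ValueError("barrier extents must not overlap")


@dataclass(frozen=True)
class GenerationBounds:
    """Uniform draw ranges for subject profiles."""

    step_frequency: tuple[float, float] = (1.0, 2.0)  # Hz
    walking_speed: tuple[float, float] = (1.0, 1.2)  # m/s
    n_harmonics: int = 3
    acc_fundamental: tuple[float, float] = (0.8, 1.6)  # m/s^2
    gyro_fundamental: tuple[float, float] = (0.3, 0.7)  # rad/s
    harmonic_decay: float = 0.5  # amplitude ratio per harmonic order
    noise_sd_acc: tuple[float, float] = (0.05, 0.15)  # m/s^2
    noise_sd_gyro: tuple[float, float] = (0.02, 0.08)  # rad/s
    caution_factor: tuple[float, float] = (0.0, 1.0)

    def validate(self):
        for name in (
            "step_frequency",
            "walking_speed",
            "acc_fundamental",
            "gyro_fundamental",
            "noise_sd_acc",
            "noise_sd_gyro",
            "caution_factor",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid bounds for {name}: min {lo} > max {hi}")
        if not 1.0 <= self.step_frequency[0] or not self.step_frequency[1] <= 2.0:
            raise ValueError("step_frequency bounds must lie within [1.0, 2.0] Hz")
        if not 0.8 <= self.walking_speed[0] or not self.walking_speed[1] <= 1.4:
            raise ValueError("walking_speed bounds must lie within [0.8, 1.4] m/s")
        if self.n_harmonics < 2:
            raise ValueError("at least 2 harmonics per axis are required")
        return self


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    step_frequency: float  # Hz
    walking_speed: float  # m/s
    harmonic_amplitudes: np.ndarray  # (6 channels, K harmonics)
    axis_phase_offsets: np.ndarray  # (6,) rad
    harmonic_phases: np.ndarray  # (6, K) rad
    noise_sd: np.ndarray  # (6,): m/s^2 for acc, rad/s for gyro
    caution_factor: float  # in [0, 1]


@dataclass(frozen=True)
class BarrierEvent:
    """One barrier negotiation: core extent traversal plus the full
    perturbed span (anticipation ramp + core + recovery ramp)."""

    barrier_index: int
    t_enter: float  # entry into the barrier extent
    t_exit: float  # exit from the (floored) extent traversal
    i_start: int  # first perturbed sample index (anticipation onset)
    i_stop: int  # one past the last perturbed sample (recovery end)
    i_core_start: int = 0  # samples of the extent traversal itself
    i_core_stop: int = 0


@dataclass(frozen=True)
class TrialRecording:
    subject_id: int
    trial_id: int
    fs: float
    imu: np.ndarray  # (N, 7): t, acc xyz, gyro xyz
    positions: np.ndarray  # (M, 2): t, arclength_m at 1 Hz
    events: tuple[BarrierEvent, ...] = ()


def generate_subject(
    rng_seed: int, config: GenerationBounds = GenerationBounds(), subject_id: int = 0
) -> SubjectProfile:
    """Draw one subject profile uniformly within the configured bounds."""
    config.validate()
    rng = np.random.default_rng(rng_seed)
    k = np.arange(1, config.n_harmonics + 1, dtype=float)
    amps = np.empty((6, config.n_harmonics))
    for c in range(6):
        lo, hi = config.acc_fundamental if c < 3 else config.gyro_fundamental
        fundamental = rng.uniform(lo, hi)
        jitter = rng.uniform(0.7, 1.3, size=config.n_harmonics)
        amps[c] = fundamental * config.harmonic_decay ** (k - 1) * jitter
    noise = np.concatenate(
        [rng.uniform(*config.noise_sd_acc, size=3), rng.uniform(*config.noise_sd_gyro, size=3)]
    )
    return SubjectProfile(
        subject_id=subject_id,
        step_frequency=rng.uniform(*config.step_frequency),
        walking_speed=rng.uniform(*config.walking_speed),
        harmonic_amplitudes=amps,
        axis_phase_offsets=rng.uniform(0, 2 * np.pi, size=6),
        harmonic_phases=rng.uniform(0, 2 * np.pi, size=(6, config.n_harmonics)),
        noise_sd=noise,
        caution_factor=rng.uniform(*config.caution_factor),
    )


def _harmonic_sum(profile: SubjectProfile, t: np.ndarray, phase_shift=0.0) -> np.ndarray:
    """Deterministic harmonic part of all 6 channels at times t -> (6, N).

    ``phase_shift`` may be a scalar or a per-sample array (broadcast).
    """
    k = np.arange(1, profile.harmonic_amplitudes.shape[1] + 1)
    # angle[c, k, n] = 2*pi*k*f*t + axis phase + harmonic phase (+ shift)
    ang = (
        2 * np.pi * profile.step_frequency * k[None, :, None] * t[None, None, :]
        + profile.axis_phase_offsets[:, None, None]
        + profile.harmonic_phases[:, :, None]
        + phase_shift
    )
    return np.einsum("ck,ckn->cn", profile.harmonic_amplitudes, np.sin(ang))


def synthesize_clean_gait(
    profile: SubjectProfile,
    duration: float,
    fs: float = FS_DEFAULT,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Clean quasi-periodic gait: (6, N) channels at fs over ``duration`` s.

    Each channel is a sum of sinusoids at multiples of the subject's step
    frequency plus white Gaussian noise; the vertical accelerometer axis
    (acc_z) carries a constant gravity offset of 9.81 m/s^2.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    series = _harmonic_sum(profile, t)
    series[2] += GRAVITY
    if rng is not None and np.any(profile.noise_sd > 0):
        series = series + profile.noise_sd[:, None] * rng.standard_normal((6, n))
    return series


def traverse_route(
    profile: SubjectProfile, route: RouteSpec, fs: float = FS_DEFAULT
) -> tuple[np.ndarray, list[BarrierEvent]]:
    """Integrate the subject's position along the route at sample rate fs.

    Walking speed dips by SPEED_DIP_FRAC * severity inside each barrier
    extent (a cautious slow-down). Returns the per-sample arclength array
    (ending at the first sample at/after the route end) and the barrier
    events with entry/exit times and perturbation sample spans (span floor
    MIN_EVENT_S seconds).
    """
    dt = 1.0 / fs
    spans = [(b.position_m, b.position_m + b.extent_m, b.severity) for b in route.barriers]
    pos = [0.0]
    s = 0.0
    while s < route.length_m:
        v = profile.walking_speed
        for lo, hi, sev in spans:
            if lo <= s < hi:
                v *= 1.0 - SPEED_DIP_FRAC * sev
                break
        s += v * dt
        pos.append(s)
    pos = np.asarray(pos)
    events = []
    for bi, b in enumerate(route.barriers):
        i_enter = int(np.searchsorted(pos, b.position_m))
        i_exit = int(np.searchsorted(pos, b.position_m + b.extent_m))
        i_core_stop = min(max(i_exit, i_enter + int(round(MIN_EVENT_S * fs))), len(pos))
        i_start = int(np.searchsorted(pos, b.position_m - ANTICIPATION_M))
        i_stop = min(
            i_core_stop + int(round(RECOVERY_M / profile.walking_speed * fs)), len(pos)
        )
        events.append(
            BarrierEvent(
                barrier_index=bi,
                t_enter=i_enter * dt,
                t_exit=i_core_stop * dt,
                i_start=i_start,
                i_stop=i_stop,
                i_core_start=i_enter,
                i_core_stop=i_core_stop,
            )
        )
    return pos, events


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise confined to the gait band, (6, n)."""
    from scipy import signal as sps

    white = rng.standard_normal((6, max(n, 32)))
    sos = sps.butter(2, IRREGULAR_BAND_HZ, btype="band", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white, axis=-1)[:, :n]
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.maximum(sd, 1e-12)


def inject_barrier_events(
    series: np.ndarray,
    profile: SubjectProfile,
    route: RouteSpec,
    events: list[BarrierEvent],
    fs: float = FS_DEFAULT,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Superimpose barrier-induced gait perturbations on a clean series.

    Within each event span, the three signatures a barrier leaves in the
    signal are emulated: the oscillatory part is amplitude-scaled by
    (1 + K_AMPLITUDE * severity * (1 - caution/2)) with a half-sine jerk
    transient at entry (amplitude spike); every harmonic acquires a phase
    advance proportional to severity (phase shift); and band-limited noise
    scaled to the channel's fundamental amplitude is added (irregular
    oscillation; requires ``rng``, omitted when None). Samples outside
    event spans are bit-identical to the input.
    """
    out = series.copy()
    n = series.shape[1]
    t = np.arange(n) / fs
    moderation = 1.0 - profile.caution_factor / 2.0
    offsets = np.array([0.0, 0.0, GRAVITY, 0.0, 0.0, 0.0])
    for ev in events:
        b = route.barriers[ev.barrier_index]
        if b.severity == 0:
            continue
        i0, i1 = ev.i_start, min(ev.i_stop, n)
        if i0 >= n or i1 <= i0:
            raise ValueError("series does not cover the barrier traversal span")
        sl = slice(i0, i1)
        # trapezoidal negotiation envelope: anticipation ramp, core, recovery
        env = np.ones(i1 - i0)
        ramp_up = max(min(ev.i_core_start, i1) - i0, 0)
        if ramp_up > 0:
            env[:ramp_up] = np.linspace(0.0, 1.0, ramp_up, endpoint=False)
        ramp_dn = i1 - max(min(ev.i_core_stop, i1), i0)
        if ramp_dn > 0:
            env[i1 - i0 - ramp_dn :] = np.linspace(1.0, 0.0, ramp_dn)
        sev = b.severity * env
        gain = 1.0 + K_AMPLITUDE * moderation * sev
        out[:, sl] = offsets[:, None] + gain[None, :] * (out[:, sl] - offsets[:, None])
        # phase-advance term: difference of the shifted and unshifted harmonics
        delta = _harmonic_sum(profile, t[sl], phase_shift=K_PHASE * sev) - _harmonic_sum(
            profile, t[sl]
        )
        out[:, sl] += delta
        # irregular oscillation: gait-band noise burst, per-channel scale
        if rng is not None:
            scale = K_IRREGULAR * moderation * profile.harmonic_amplitudes[:, 0]
            out[:, sl] += scale[:, None] * sev[None, :] * _bandlimited_noise(rng, i1 - i0, fs)
        # jerk transient at the core (extent) entry
        j0 = min(ev.i_core_start, n)
        nj = min(int(round(JERK_DURATION_S * fs)), n - j0)
        if nj > 0:
            pulse = np.sin(np.pi * np.arange(nj) / nj)
            amp = b.severity * moderation
            out[0:3, j0 : j0 + nj] += K_JERK_ACC * amp * pulse[None, :]
            out[3:6, j0 : j0 + nj] += K_JERK_GYRO * amp * pulse[None, :]
    return out


def simulate_trial(
    profile: SubjectProfile,
    trial_id: int,
    route: RouteSpec,
    seed_seq: np.random.SeedSequence,
    fs: float = FS_DEFAULT,
) -> TrialRecording:
    """One full walk of the route by one subject."""
    rng = np.random.default_rng(seed_seq)
    pos, events = traverse_route(profile, route, fs=fs)
    duration = len(pos) / fs
    series = synthesize_clean_gait(profile, duration, fs=fs, rng=rng)
    series = inject_barrier_events(series, profile, route, events, fs=fs, rng=rng)
    n = series.shape[1]
    t = np.arange(n) / fs
    imu = np.column_stack([t, series.T])
    pos_t = np.arange(0.0, n / fs + 1.0)
    pos_idx = np.minimum((pos_t * fs).astype(int), len(pos) - 1)
    positions = np.column_stack([pos_t, pos[pos_idx]])
    return TrialRecording(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        fs=fs,
        imu=imu,
        positions=positions,
        events=tuple(events),
    )


def simulate_cohort(
    n_subjects: int = 20,
    n_trials: int = 2,
    route: RouteSpec | None = None,
    master_seed: int = 42,
    bounds: GenerationBounds = GenerationBounds(),
    fs: float = FS_DEFAULT,
) -> list[TrialRecording]:
    """Simulate a cohort: n_subjects x n_trials walks of one route.

    Seeds are derived counter-style from (master_seed, subject, trial) so
    any single trial is reproducible in isolation; the subject profile is
    derived from (master_seed, subject) and shared by that subject's trials.
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("need at least one subject and one trial")
    if route is None:
        route = default_route()
    recordings = []
    for subject in range(n_subjects):
        profile_seed = np.random.SeedSequence((master_seed, subject))
        profile = generate_subject(
            profile_seed.generate_state(1)[0] % (2**31), bounds, subject_id=subject
        )
        for trial in range(n_trials):
            trial_seq = np.random.SeedSequence((master_seed, subject, trial))
            recordings.append(simulate_trial(profile, trial, route, trial_seq, fs=fs))
    return recordings


def default_route(length_m: float = 1200.0) -> RouteSpec:
    """A 1.2 km loop with the four hazard kinds at surveyed positions."""
    return RouteSpec(
        length_m=length_m,
        barriers=tuple(
            Barrier(position_m=p * length_m / 1200.0, extent_m=e, severity=s, kind=k)
            for p, e, s, k in [
                (150.0, 4.0, 0.9, "uneven_sidewalk"),
                (320.0, 1.5, 0.8, "curb_drop"),
                (520.0, 6.0, 0.7, "narrow_alley"),
                (700.0, 3.0, 0.6, "driveway"),
                (880.0, 1.5, 0.8, "curb_drop"),
                (1050.0, 4.0, 0.9, "uneven_sidewalk"),
            ]
        ),
    )


def benchmark_route(length_m: float = 600.0, n_barriers: int = 6) -> RouteSpec:
    """Scaled-down benchmark route: evenly spread high-severity barriers."""
    severities = [0.8, 0.85, 0.9, 0.95, 1.0, 0.9, 0.85, 0.8]
    extents = [3.0, 1.5, 4.0, 2.0, 3.0, 1.5, 4.0, 2.0]
    gap = length_m / (n_barriers + 1)
    return RouteSpec(
        length_m=length_m,
        barriers=tuple(
            Barrier(
                position_m=gap * (i + 1),
                extent_m=extents[i % len(extents)],
                severity=severities[i % len(severities)],
                kind=BARRIER_KINDS[i % len(BARRIER_KINDS)],
            )
            for i in range(n_barriers)
        ),
    )


# ---------------------------------------------------------------------------
# Delimited-text export / import


def write_trial(rec: TrialRecording, directory: str | Path) -> dict[str, Path]:
    """Write one trial's IMU, positions and events as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"s{rec.subject_id:03d}_t{rec.trial_id}"
    paths = {
        "imu": directory / f"{stem}_imu.csv",
        "positions": directory / f"{stem}_positions.csv",
        "events": directory / f"{stem}_events.csv",
    }
    pd.DataFrame(rec.imu, columns=list(IMU_COLUMNS)).to_csv(paths["imu"], index=False)
    pd.DataFrame(rec.positions, columns=["t", "arclength_m"]).to_csv(
        paths["positions"], index=False
    )
    pd.DataFrame(
        [
            {
                "subject": rec.subject_id,
                "trial": rec.trial_id,
                "barrier_index": ev.barrier_index,
                "t_enter": ev.t_enter,
                "t_exit": ev.t_exit,
            }
            for ev in rec.events
        ],
        columns=["subject", "trial", "barrier_index", "t_enter", "t_exit"],
    ).to_csv(paths["events"], index=False)
    return paths


def read_trial(
    imu_path: str | Path, positions_path: str | Path, subject_id: int, trial_id: int, fs: float
) -> TrialRecording:
    """Load a trial from exported CSV files (events are optional metadata)."""
    imu = pd.read_csv(imu_path)[list(IMU_COLUMNS)].to_numpy(float)
    positions = pd.read_csv(positions_path)[["t", "arclength_m"]].to_numpy(float)
    return TrialRecording(
        subject_id=subject_id, trial_id=trial_id, fs=fs, imu=imu, positions=positions
    )
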
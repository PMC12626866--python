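"""Synthetic cohort generator: profiles, spectra, perturbation locality,
ground-truth closure and reproducibility."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitbarrier.synth import (
    Barrier,
    GenerationBounds,
    RouteSpec,
    generate_subject,
    inject_barrier_events,
    read_trial,
    simulate_cohort,
    synthesize_clean_gait,
    traverse_route,
    write_trial,
)


class TestGenerateSubject:
    def test_fields_within_default_bounds(self):
        p = generate_subject(42)
        assert 1.0 <= p.step_frequency <= 2.0
        assert 1.0 <= p.walking_speed <= 1.2
        assert 0.0 <= p.caution_factor <= 1.0
        assert np.all(p.noise_sd >= 0)
        assert p.harmonic_amplitudes.shape[1] >= 2

    def test_same_seed_identical_profiles(self):
        a, b = generate_subject(42), generate_subject(42)
        assert a.step_frequency == b.step_frequency
        np.testing.assert_array_equal(a.harmonic_amplitudes, b.harmonic_amplitudes)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            generate_subject(0, GenerationBounds(walking_speed=(1.2, 1.0)))


class TestCleanGait:
    def test_sample_count(self, profile):
        series = synthesize_clean_gait(profile, duration=10.0, fs=100.0)
        assert series.shape == (6, 1000)

    def test_noise_free_determinism(self, profile):
        a = synthesize_clean_gait(profile, 5.0, 100.0)
        b = synthesize_clean_gait(profile, 5.0, 100.0)
        np.testing.assert_array_equal(a, b)

    def test_gravity_offset_on_vertical_axis(self, profile):
        series = synthesize_clean_gait(profile, 20.0, 100.0)
        assert abs(np.mean(series[2]) - 9.81) < 0.05
        assert abs(np.mean(series[0])) < 0.05

    def test_dominant_peak_at_step_frequency(self):
        """Noise-free series peaks at f0 within one periodogram bin."""
        p = generate_subject(5)
        f0 = p.step_frequency
        series = synthesize_clean_gait(p, duration=30.0, fs=100.0)
        freqs, power = sps.periodogram(series[0] - series[0].mean(), fs=100.0)
        assert abs(freqs[np.argmax(power)] - f0) <= freqs[1] - freqs[0]

    def test_spectral_fidelity_harmonic_power(self):
        """>= 95% of noise-free power lies at multiples of the step rate."""
        p = generate_subject(7)
        series = synthesize_clean_gait(p, duration=30.0, fs=100.0)
        for c in range(6):
            x = series[c] - series[c].mean()
            freqs, power = sps.periodogram(x, fs=100.0, window="hann")
            df = freqs[1] - freqs[0]
            harmonics = p.step_frequency * np.arange(1, p.harmonic_amplitudes.shape[1] + 1)
            near = np.zeros_like(freqs, dtype=bool)
            for h in harmonics:
                near |= np.abs(freqs - h) <= 2 * df
            assert power[near].sum() / power.sum() >= 0.95


class TestBarrierInjection:
    def test_zero_severity_identical_output(self, profile):
        route = RouteSpec(50.0, (Barrier(20.0, 2.0, 0.0),))
        pos, events = traverse_route(profile, route)
        series = synthesize_clean_gait(profile, len(pos) / 100.0, 100.0)
        out = inject_barrier_events(series, profile, route, events)
        np.testing.assert_array_equal(out, series)
        assert len(events) == 1  # zero-effect events still logged

    def test_no_barriers_no_events(self, profile):
        _, events = traverse_route(profile, RouteSpec(30.0))
        assert events == []

    def test_perturbation_locality_and_variance_increase(self, profile):
        """Samples outside event spans are bit-identical; inside, the
        acceleration-magnitude variance strictly exceeds a clean span."""
        route = RouteSpec(60.0, (Barrier(30.0, 2.0, 1.0),))
        pos, events = traverse_route(profile, route)
        series = synthesize_clean_gait(profile, len(pos) / 100.0, 100.0)
        out = inject_barrier_events(series, profile, route, events)
        (ev,) = events
        np.testing.assert_array_equal(out[:, : ev.i_start], series[:, : ev.i_start])
        np.testing.assert_array_equal(out[:, ev.i_stop :], series[:, ev.i_stop :])
        mag = np.linalg.norm(out[0:3], axis=0)
        n = ev.i_stop - ev.i_start
        in_var = np.var(mag[ev.i_start : ev.i_stop])
        clean_var = np.var(mag[ev.i_start - n : ev.i_start])
        assert in_var > clean_var

    def test_event_span_floor_one_second(self, profile):
        route = RouteSpec(50.0, (Barrier(25.0, 0.2, 0.5),))  # tiny extent
        _, (ev,) = traverse_route(profile, route)
        assert ev.t_exit - ev.t_enter >= 1.0 - 1e-9

    def test_event_core_maps_inside_barrier_extent(self, profile):
        """The logged extent traversal (t_enter..t_exit) lies on the
        barrier; the full perturbed span covers the ±1 m negotiation zone."""
        route = RouteSpec(80.0, (Barrier(40.0, 3.0, 0.7),))
        pos, (ev,) = traverse_route(profile, route)
        assert pos[ev.i_core_start] >= 40.0 - 1e-6
        assert pos[min(ev.i_core_stop, len(pos) - 1)] >= 43.0 - profile.walking_speed
        assert pos[ev.i_start] <= 40.0 - 1.0 + profile.walking_speed / 100.0
        assert ev.i_stop > ev.i_core_stop


class TestCohort:
    def test_cohort_size(self, short_route):
        recs = simulate_cohort(4, 2, short_route, master_seed=3)
        assert len(recs) == 4 * 2
        assert {(r.subject_id, r.trial_id) for r in recs} == {
            (s, t) for s in range(4) for t in range(2)
        }

    def test_full_study_design_forty_recordings(self):
        """Default design: 20 subjects x 2 trials = 40 walks (geometry only:
        a 3 m route keeps this fast)."""
        recs = simulate_cohort(20, 2, RouteSpec(3.0), master_seed=1)
        assert len(recs) == 40

    def test_determinism_and_seed_sensitivity(self, short_route):
        a = simulate_cohort(2, 1, short_route, master_seed=9)
        b = simulate_cohort(2, 1, short_route, master_seed=9)
        c = simulate_cohort(2, 1, short_route, master_seed=10)
        np.testing.assert_array_equal(a[0].imu, b[0].imu)
        assert not np.array_equal(a[0].imu, c[0].imu)

    def test_single_trial_reproducible_in_isolation(self, short_route):
        """The (master, subject, trial) seed derivation lets one trial be
        regenerated without simulating the rest of the cohort."""
        full = simulate_cohort(3, 2, short_route, master_seed=21)
        target = [r for r in full if r.subject_id == 2 and r.trial_id == 1][0]
        alone = simulate_cohort(3, 2, short_route, master_seed=21)
        again = [r for r in alone if r.subject_id == 2 and r.trial_id == 1][0]
        np.testing.assert_array_equal(target.imu, again.imu)

    def test_positions_consistent_with_speed(self, short_route):
        """1 Hz position increments match walking speed in clean spans."""
        (rec,) = simulate_cohort(1, 1, short_route, master_seed=2)
        profile = None
        deltas = np.diff(rec.positions[:, 1])
        # constant-speed spans: delta == speed * 1 s; barrier spans dip
        speeds = np.unique(np.round(deltas[deltas > 0], 3))
        assert np.max(deltas) <= 1.4  # within the speed bound
        base = np.median(deltas[: len(deltas) // 4])
        clean = deltas[np.abs(deltas - base) < 1e-3]
        assert len(clean) > len(deltas) / 2
        np.testing.assert_allclose(clean, base, atol=1e-3)

    def test_timestamps_and_arclength_monotone(self, small_cohort):
        for rec in small_cohort:
            assert np.all(np.diff(rec.imu[:, 0]) > 0)
            assert np.all(np.diff(rec.positions[:, 1]) >= 0)


def test_trial_csv_roundtrip(tmp_path, small_cohort):
    rec = small_cohort[0]
    paths = write_trial(rec, tmp_path)
    back = read_trial(paths["imu"], paths["positions"], rec.subject_id, rec.trial_id, rec.fs)
    np.testing.assert_allclose(back.imu, rec.imu, rtol=1e-12)
    np.testing.assert_allclose(back.positions, rec.positions, rtol=1e-12)


def test_route_geometry_validation():
    with pytest.raises(ValueError):
        RouteSpec(100.0, (Barrier(150.0, 1.0, 0.5),))  # outside route
    with pytest.raises(ValueError):
        RouteSpec(100.0, (Barrier(10.0, 5.0, 0.5), Barrier(12.0, 5.0, 0.5)))  # overlap
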
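"""Ripple-spindle coupling: phase extraction, histograms, surrogates, density."""

import numpy as np
import pytest

from wakeripples.circstats import circular_distance
from wakeripples.core import Recording
from wakeripples.coupling import (
    histogram_bin_centers,
    in_out_spindle_density,
    peri_spindle_ripple_series,
    phase_series,
    ripple_centered_eeg,
    ripple_phase_histogram,
    shift_surrogate,
    spindle_locked_likelihood,
)
from wakeripples.simulate import one_over_f_noise
from wakeripples.spindles import SpindleEvent

FS = 500.0


def cosine_recording(freq=15.0, duration=60.0, label="Fz"):
    t = np.arange(int(duration * FS)) / FS
    return Recording(np.cos(2 * np.pi * freq * t)[None], FS, [label],
                     ["EEG"]), t


class TestPhaseSeries:
    def test_cosine_peak_is_phase_zero(self):
        rec, t = cosine_recording()
        ph = phase_series(rec, 15.0)[0]
        peaks = np.round(np.arange(2.0, 50.0) / (1 / 15.0)) * (1 / 15.0)
        idx = np.round(peaks * FS).astype(int)
        assert np.abs(ph[idx]).max() < 0.25

    def test_phase_increases_monotonically(self):
        rec, _ = cosine_recording()
        ph = np.unwrap(phase_series(rec, 15.0)[0])
        d = np.diff(ph[1000:-1000])
        assert np.all(d > 0)

    def test_angular_rate_matches_frequency(self):
        rec, _ = cosine_recording(freq=12.0)
        ph = np.unwrap(phase_series(rec, 12.0)[0])
        rate = np.diff(ph[1000:-1000]).mean() * FS
        assert rate == pytest.approx(2 * np.pi * 12.0, rel=0.02)


class TestShiftSurrogate:
    def test_inversion_recovers_original(self, rng):
        times = np.sort(rng.uniform(0, 100.0, size=40))
        sur = shift_surrogate(times, 100.0, rng, offset=17.3)
        back = shift_surrogate(sur, 100.0, rng, offset=100.0 - 17.3)
        assert np.allclose(np.sort(back), times, atol=1e-9)

    def test_count_and_circular_gaps_preserved(self, rng):
        times = np.sort(rng.uniform(0, 50.0, size=25))
        sur = shift_surrogate(times, 50.0, rng)
        assert sur.size == times.size

        def circ_gaps(t, T):
            gaps = np.diff(np.concatenate([t, [t[0] + T]]))
            return np.sort(gaps)

        assert np.allclose(circ_gaps(times, 50.0), circ_gaps(sur, 50.0),
                           atol=1e-9)

    def test_offsets_uniformise_event_times(self, rng):
        times = np.array([10.0, 10.5, 11.0])
        pooled = np.concatenate([
            shift_surrogate(times, 60.0, rng) for _ in range(1000)])
        hist, _ = np.histogram(pooled, bins=12, range=(0, 60.0))
        chi2 = ((hist - hist.mean()) ** 2 / hist.mean()).sum()
        # 11 dof; 0.999 quantile ~ 31.3
        assert chi2 < 31.3


class TestPhaseHistogram:
    def test_bin_centers_convention(self):
        c = histogram_bin_centers(50)
        assert c.size == 50
        assert c[0] == pytest.approx(-np.pi + np.pi / 50)
        assert np.allclose(np.diff(c), 2 * np.pi / 50)

    def test_counts_match_brute_force_membership(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=int(20 * FS))
        times = np.sort(rng.uniform(1.0, 18.0, size=60))
        res = ripple_phase_histogram(phases, times, FS)
        centers = res.bin_centers
        idx = np.round(times * FS).astype(int)
        brute = np.zeros(50)
        for rp in phases[idx]:
            for k in range(50):
                d = abs(np.angle(np.exp(1j * (centers[k] - rp))))
                if d <= np.deg2rad(22.5):
                    brute[k] += 1
        assert np.array_equal(res.histogram, brute)

    def test_point_mass_covers_seven_bins(self):
        # 7.2 degree spacing: centers within +/-22.5 deg of a ripple phase
        # exactly at a bin center = 7 bins
        phases = np.zeros(int(10 * FS))
        c = histogram_bin_centers(50)
        phases[:] = c[25]
        times = np.array([2.0, 3.0, 4.0])
        res = ripple_phase_histogram(phases, times, FS)
        assert (res.histogram > 0).sum() == 7
        assert res.histogram.sum() == 3 * 7

    def test_uniform_phases_flat_histogram(self, rng):
        n = int(600 * FS)
        phases = rng.uniform(-np.pi, np.pi, size=n)
        times = np.sort(rng.uniform(1.0, 590.0, size=2000))
        res = ripple_phase_histogram(phases, times, FS)
        assert res.histogram.max() / res.histogram.min() < 1.5

    def test_dominant_phase_argmax_option(self, rng):
        phases = rng.vonmises(1.0, 6.0, size=int(20 * FS))
        times = np.sort(rng.uniform(1.0, 18.0, size=200))
        res = ripple_phase_histogram(phases, times, FS, dominant="argmax")
        assert abs(circular_distance(res.dominant_phase, 1.0)) < 0.3


class TestRippleCenteredEEG:
    def test_ripples_at_troughs_give_trough_at_zero(self):
        rec, t = cosine_recording(freq=15.0, duration=120.0)
        # ripple times at oscillation troughs: cos = -1 at (k + 1/2)/f
        troughs = (np.arange(20, 1500) + 0.5) / 15.0
        troughs = troughs[troughs < 118.0]
        res = ripple_centered_eeg(rec, troughs, roi=["Fz"])
        # a trough at the lock time, within sampling error of the global
        # minimum (lock times fall between samples), oscillating at 15 Hz
        at_zero = res.trace[np.abs(res.times) <= 0.002].min()
        assert at_zero <= 0.97 * res.trace.min()
        assert res.trace.max() > 1.0
        # adjacent peak half a 15 Hz cycle away
        after = (res.times > 0.01) & (res.times < 0.06)
        t_peak = res.times[after][np.argmax(res.trace[after])]
        assert t_peak == pytest.approx(1 / 30.0, abs=0.008)

    def test_baseline_standardized(self, rng):
        n = int(120 * FS)
        rec = Recording(one_over_f_noise(n, 1.0, FS, rng)[None], FS,
                        ["Fz"], ["EEG"])
        times = np.sort(rng.uniform(5.0, 110.0, size=50))
        res = ripple_centered_eeg(rec, times, roi=["Fz"])
        mask = (res.times >= -1.0) & (res.times <= -0.5)
        assert abs(res.trace[mask].mean()) < 1e-10

    def test_requires_events_and_roi(self, rng):
        n = int(30 * FS)
        rec = Recording(one_over_f_noise(n, 1.0, FS, rng)[None], FS,
                        ["Fz"], ["EEG"])
        with pytest.raises(ValueError):
            ripple_centered_eeg(rec, np.array([]), roi=["Fz"])
        with pytest.raises(ValueError):
            ripple_centered_eeg(rec, np.array([10.0]), roi=["Cz"])


def make_spindles(centers, dur=0.6):
    return [SpindleEvent("Fz", c, c, c - dur / 2, c + dur / 2, 5.0)
            for c in centers]


class TestInOutDensity:
    def test_ripples_only_inside_spindles(self):
        n = int(100 * FS)
        series = np.zeros(n)
        spindles = make_spindles(np.arange(5.0, 95.0, 10.0))
        for ev in spindles:
            series[int(ev.center_time * FS)] = 1
        d = in_out_spindle_density(series, spindles, FS)
        assert d.n_out == 0.0
        assert d.n_in > 0

    def test_independent_ripples_equal_density(self, rng):
        # Poisson ripples independent of spindles: in/out densities agree
        n = int(500 * FS)
        diffs = []
        for _ in range(60):
            series = (rng.uniform(size=n) < 0.3 / FS).astype(float)
            spindles = make_spindles(np.arange(5.0, 495.0, 10.0))
            d = in_out_spindle_density(series, spindles, FS)
            diffs.append(d.n_in - d.n_out)
        diffs = np.asarray(diffs)
        t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
        assert abs(t_stat) < 3.0

    def test_density_linear_in_rate(self, rng):
        n = int(500 * FS)
        spindles = make_spindles(np.arange(5.0, 495.0, 10.0))
        base = (rng.uniform(size=n) < 0.5 / FS).astype(float)
        d1 = in_out_spindle_density(base, spindles, FS)
        d2 = in_out_spindle_density(2 * base, spindles, FS)
        assert d2.n_in == pytest.approx(2 * d1.n_in)
        assert d2.n_out == pytest.approx(2 * d1.n_out)

    def test_no_spindles_rejected(self):
        with pytest.raises(ValueError):
            in_out_spindle_density(np.zeros(1000), [], FS)


class TestSpindleLockedLikelihood:
    def _null_subjects(self, rng, n_subj=8, rate=0.4):
        series = []
        times = None
        for _ in range(n_subj):
            n = int(300 * FS)
            s = (rng.uniform(size=n) < rate / FS).astype(float)
            onsets = np.sort(rng.uniform(3.0, 295.0, size=40))
            times, peri = peri_spindle_ripple_series(s, onsets, FS)
            series.append(peri)
        return series, times

    def test_fixed_seed_reproducible(self, rng):
        series, times = self._null_subjects(rng)
        r1 = spindle_locked_likelihood(series, times, n_surrogates=150,
                                       seed=5)
        r2 = spindle_locked_likelihood(series, times, n_surrogates=150,
                                       seed=5)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_coupled_generator_minimum_p_at_positive_lag(self, rng):
        # ripples placed ~100 ms after each spindle onset
        series, times = [], None
        for _ in range(8):
            n = int(300 * FS)
            s = (rng.uniform(size=n) < 0.2 / FS).astype(float)
            onsets = np.sort(rng.uniform(3.0, 295.0, size=50))
            for o in onsets:
                s[int((o + 0.1 + rng.normal(0, 0.01)) * FS)] += 1
            times, peri = peri_spindle_ripple_series(s, onsets, FS)
            series.append(peri)
        res = spindle_locked_likelihood(series, times, n_surrogates=200,
                                        seed=1)
        t_min = times[np.argmin(res.p_values + 1e-9 * np.abs(times - 0.1))]
        assert 0.0 < t_min < 0.3
        assert res.p_values.min() < 0.02

    def test_small_surrogate_count_warns(self, rng):
        series, times = self._null_subjects(rng, n_subj=3)
        with pytest.warns(UserWarning):
            spindle_locked_likelihood(series, times, n_surrogates=50, seed=0)
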
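"""MEG-ripple to EEG-low-frequency coupling analyses.

Four complementary views of the same question -- are high-frequency ripple
events timed by the slower spindle rhythm?

* ripple-centered EEG averages (RS(t)) with time-shift surrogates,
* ripple-phase histograms per low-frequency band with circular statistics
  (dominant phase per subject, Watson-Williams across sessions),
* ripple density inside vs outside discrete spindle bouts,
* spindle-onset-locked ripple likelihood with a 1000-surrogate pointwise
  significance curve.

Phase convention throughout: 0 = oscillation peak, +/-pi = trough (the
phase of the analytic signal of a cosine). The time-shift surrogate rotates
an entire event train by one uniform offset, destroying alignment with the
other signal while preserving event count and circular inter-event
structure exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps
import scipy.stats as st

from .circstats import circular_distance, circular_mean, watson_williams
from .core import (
    Recording,
    bandpass_zero_phase,
    epoch_array,
    moving_window_rate,
    zscore_series_to_baseline,
)
from .spindles import SpindleEvent


# --------------------------------------------------------------------------
# ripple-centered EEG
# --------------------------------------------------------------------------

@dataclass
class RippleCenteredAverage:
    times: np.ndarray
    trace: np.ndarray           # z-scored mean RS(t) for one subject
    baseline: tuple[float, float]
    n_events: int


def ripple_centered_eeg(recording: Recording, ripple_times: np.ndarray,
                        roi: list[str],
                        band: tuple[float, float] = (1.0, 25.0),
                        t_start: float = -1.0, t_end: float = 1.0,
                        baseline: tuple[float, float] = (-1.0, -0.5)
                        ) -> RippleCenteredAverage:
    """Mean low-frequency EEG around ripple peaks, z-scored to (-1, -0.5) s.

    The EEG is band-passed 1-25 Hz (wide, so spindle-band structure has to
    emerge on its own rather than being imposed by the filter), epoched
    around each ripple peak at the ROI channels, averaged over epochs and
    channels, then standardized to the pre-ripple baseline.
    """
    ripple_times = np.asarray(ripple_times, float)
    if ripple_times.size == 0:
        raise ValueError("no ripple events")
    for ch in roi:
        if ch not in recording.channel_labels:
            raise ValueError(f"ROI channel {ch!r} missing from recording")
    rec = bandpass_zero_phase(recording.pick(roi), *band)
    traces, times, n_ev = [], None, 0
    for ci in range(rec.n_channels):
        ep, times = epoch_array(rec.data[ci], rec.sample_rate, ripple_times,
                                t_start, t_end)
        traces.append(ep.mean(axis=0))
        n_ev = ep.shape[0]
    mean_trace = np.mean(traces, axis=0)
    trace = zscore_series_to_baseline(mean_trace, times, baseline)
    return RippleCenteredAverage(times=times, trace=trace,
                                 baseline=baseline, n_events=n_ev)


def group_pointwise_t(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point t statistic of subject traces against zero."""
    t, p = st.ttest_1samp(traces, 0.0, axis=0)
    return t, p


# --------------------------------------------------------------------------
# time-shift surrogates
# --------------------------------------------------------------------------

def shift_surrogate(event_times: np.ndarray, duration: float,
                    rng: np.random.Generator,
                    offset: float | None = None) -> np.ndarray:
    """Circularly shift an event train by one uniform offset (seconds).

    Event count and circular inter-event intervals are preserved exactly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    event_times = np.asarray(event_times, float)
    if offset is None:
        offset = float(rng.uniform(0.0, duration))
    return np.sort((event_times + offset) % duration)


# --------------------------------------------------------------------------
# phase extraction and ripple-phase histograms
# --------------------------------------------------------------------------

def phase_series(recording: Recording, center: float, width: float = 2.0
                 ) -> np.ndarray:
    """Instantaneous phase per channel of the (center +/- width/2) Hz band.

    Phase 0 = oscillation peak, +/-pi = trough.
    """
    band = bandpass_zero_phase(recording, center - width / 2,
                               center + width / 2)
    return np.angle(sps.hilbert(band.data, axis=1))


def histogram_bin_centers(n_bins: int = 50) -> np.ndarray:
    """Equally spaced phase-bin centers on (-pi, pi]."""
    return -np.pi + (np.arange(n_bins) + 0.5) * (2 * np.pi / n_bins)


@dataclass
class PhaseCouplingResult:
    band_center: float
    bin_centers: np.ndarray
    histogram: np.ndarray           # summed ripple counts per bin
    ripple_phases: np.ndarray
    dominant_phase: float           # circular mean of ripple phases


def ripple_phase_histogram(phases: np.ndarray, ripple_times: np.ndarray,
                           fs: float, band_center: float = 15.0,
                           n_bins: int = 50, window_deg: float = 45.0,
                           dominant: str = "circmean") -> PhaseCouplingResult:
    """Ripple counts in a 45-degree window around each of 50 phase bins.

    `phases` is a 1-D per-sample phase series; each ripple contributes a
    count to every bin whose center lies within +/- window_deg/2 of the
    ripple's phase (circularly). The per-subject dominant phase is the
    circular mean of ripple phases (or the argmax bin center when
    dominant="argmax").
    """
    ripple_times = np.asarray(ripple_times, float)
    if ripple_times.size == 0:
        raise ValueError("no ripple events")
    idx = np.clip(np.round(ripple_times * fs).astype(int), 0,
                  phases.size - 1)
    rphases = phases[idx]
    centers = histogram_bin_centers(n_bins)
    half = np.deg2rad(window_deg) / 2.0
    dist = np.abs(circular_distance(centers[None, :], rphases[:, None]))
    hist = (dist <= half).sum(axis=0).astype(float)
    if dominant == "argmax":
        dom = float(centers[int(np.argmax(hist))])
    else:
        dom = circular_mean(rphases)
    return PhaseCouplingResult(band_center=band_center, bin_centers=centers,
                               histogram=hist, ripple_phases=rphases,
                               dominant_phase=dom)


@dataclass
class GroupPhaseResult:
    dominant_phases: dict[str, np.ndarray]   # session -> per-subject phases
    group_means: dict[str, float]
    ww_F: float
    ww_p: float


def group_phase_comparison(phases_by_session: dict[str, np.ndarray]
                           ) -> GroupPhaseResult:
    """Group circular means per session and Watson-Williams across sessions."""
    means = {s: circular_mean(v) for s, v in phases_by_session.items()}
    F, p = watson_williams(*phases_by_session.values())
    return GroupPhaseResult(dominant_phases=dict(phases_by_session),
                            group_means=means, ww_F=F, ww_p=p)


# --------------------------------------------------------------------------
# in/out-of-spindle ripple density
# --------------------------------------------------------------------------

@dataclass
class InOutDensity:
    n_in: float                 # ripples per sample point inside spindles
    n_out: float                # ripples per sample point in flanking 1 s
    session: str = ""


def in_out_spindle_density(ripple_series: np.ndarray,
                           spindle_events: list[SpindleEvent], fs: float,
                           out_pad: float = 1.0,
                           session: str = "") -> InOutDensity:
    """Ripple density inside spindle bouts vs the 1 s flanks outside them.

    `ripple_series` is a per-sample ripple-count series already summed over
    the top sensors. Flank samples that fall inside any spindle are excluded
    from the "out" mass.
    """
    if not spindle_events:
        raise ValueError("no spindle events")
    n = ripple_series.size
    in_mask = np.zeros(n, bool)
    for ev in spindle_events:
        a = max(0, int(round(ev.start_time * fs)))
        b = min(n, int(round(ev.end_time * fs)) + 1)
        in_mask[a:b] = True
    out_mask = np.zeros(n, bool)
    pad = int(round(out_pad * fs))
    for ev in spindle_events:
        a = int(round(ev.start_time * fs))
        b = int(round(ev.end_time * fs)) + 1
        out_mask[max(0, a - pad):max(0, a)] = True
        out_mask[min(n, b):min(n, b + pad)] = True
    out_mask &= ~in_mask
    if in_mask.sum() == 0 or out_mask.sum() == 0:
        raise ValueError("degenerate in/out sample masks")
    n_in = float(ripple_series[in_mask].sum() / in_mask.sum())
    n_out = float(ripple_series[out_mask].sum() / out_mask.sum())
    return InOutDensity(n_in=n_in, n_out=n_out, session=session)


# --------------------------------------------------------------------------
# spindle-onset-locked ripple likelihood with surrogate p-values
# --------------------------------------------------------------------------

@dataclass
class SpindleLockedResult:
    times: np.ndarray
    observed: np.ndarray        # group-mean ripple likelihood
    p_values: np.ndarray        # pointwise two-tailed surrogate p
    n_surrogates: int


def peri_spindle_ripple_series(ripple_series: np.ndarray,
                               spindle_onsets: np.ndarray, fs: float,
                               t_start: float = -1.0, t_end: float = 1.0,
                               window: float = 0.2
                               ) -> tuple[np.ndarray, np.ndarray]:
    """One subject's summed, smoothed ripple series around spindle onsets."""
    epochs, times = epoch_array(ripple_series, fs, spindle_onsets,
                                t_start, t_end)
    summed = epochs.sum(axis=0)
    return times, moving_window_rate(summed, window, fs)


def spindle_locked_likelihood(subject_series: list[np.ndarray],
                              times: np.ndarray,
                              n_surrogates: int = 1000,
                              seed: int | np.random.Generator = 0,
                              mode: str = "empirical"
                              ) -> SpindleLockedResult:
    """Pointwise surrogate test of the group-mean peri-spindle ripple rate.

    Each subject's peri-spindle summed ripple series is circularly shifted
    by an independent uniform offset; the shifted series are averaged across
    subjects; repeating this n_surrogates times gives a pointwise null.
    p is the two-tailed exceedance of the observed group mean against that
    null (empirical rank by default; mode="kde" uses a Gaussian kernel
    density estimate of the null at each time point).
    """
    import warnings
    if n_surrogates < 100:
        warnings.warn(f"only {n_surrogates} surrogates; p-values are coarse",
                      stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    stack = np.asarray(subject_series)          # (n_subj, n_t)
    n_subj, n_t = stack.shape
    observed = stack.mean(axis=0)
    shifts = rng.integers(0, n_t, size=(n_surrogates, n_subj))
    col = np.arange(n_t)
    sur = np.empty((n_surrogates, n_t))
    for s in range(n_surrogates):
        idx = (col[None, :] - shifts[s][:, None]) % n_t
        sur[s] = np.take_along_axis(stack, idx, axis=1).mean(axis=0)
    if mode == "kde":
        p = np.empty(n_t)
        for i in range(n_t):
            null = sur[:, i]
            if null.std() == 0:
                p[i] = 1.0
                continue
            kde = st.gaussian_kde(null)
            lo = min(null.min(), observed[i]) - 5 * null.std()
            hi = max(null.max(), observed[i]) + 5 * null.std()
            upper = kde.integrate_box_1d(observed[i], hi)
            lower = kde.integrate_box_1d(lo, observed[i])
            p[i] = 2 * min(upper, lower)
    else:
        ge = (sur >= observed[None, :]).sum(axis=0)
        le = (sur <= observed[None, :]).sum(axis=0)
        p = 2.0 * (np.minimum(ge, le) + 1) / (n_surrogates + 1)
    p = np.clip(p, 0.0, 1.0)
    return SpindleLockedResult(times=times, observed=observed, p_values=p,
                               n_surrogates=n_surrogates)
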
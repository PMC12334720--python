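"""Ripple detection in MEG and downstream likelihood / behavior analyses.

A ripple is a brief (~30 ms) high-frequency (80-150 Hz) oscillatory burst.
Detection follows the envelope-threshold scheme standard in human intracranial
work, applied to magnetometer signals: band-pass 80-150 Hz, Hilbert envelope,
per-sensor z-scoring over the concatenated trials, then five criteria on
each candidate excursion. Candidate boundaries are the envelope's crossings
of a lower boundary threshold (z = 2.0, the usual two-threshold scheme, so
that noise pulling a genuine burst's envelope briefly under the peak
threshold does not clip or split the event; boundary excursions separated
by less than 10 ms are merged):

  1. envelope z exceeds 2.5 somewhere within the excursion,
  2. excursion duration (between the boundary crossings) 20 to 500 ms,
  3. no sample exceeds z = 9 (non-physiological amplitude guard),
  4. at least three oscillation peaks above z = 2.5 inside the excursion --
     peak instants are local maxima of the rectified band-passed signal,
     their amplitude is the unsmoothed analytic envelope at those instants
     (at 500 Hz the rectified samples themselves alias the carrier),
  5. a dominant peak: the excursion's largest peak amplitude must exceed
     by >= 20% the oscillation peaks immediately flanking the excursion --
     the event must stand out of its local surroundings, so a marginal
     excursion riding on an elevated neighbourhood is rejected.

Retained events must be separated by >= 20 ms; of a violating pair the
higher-amplitude event survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sps
import scipy.stats as st

from .core import (
    BandEnvelope,
    LikelihoodSeries,
    Recording,
    analytic_envelope,
    bandpass_zero_phase,
    epoch_array,
    moving_window_rate,
    tf_amplitude,
    zscore_series_to_baseline,
)


@dataclass
class RippleEvent:
    """One detected ripple burst."""

    channel: str
    peak_time: float        # envelope-z maximum, s
    start_time: float       # 2.5-SD crossing, s
    end_time: float         # 2.5-SD crossing, s
    peak_z: float
    n_supra_peaks: int
    trial_index: int = -1

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class RippleParams:
    """Detector thresholds; defaults are the standard operating point."""

    band: tuple[float, float] = (80.0, 150.0)
    z_thresh: float = 2.5
    boundary_z: float = 2.0         # event-boundary threshold
    z_max: float = 9.0
    min_dur: float = 0.020
    max_dur: float = 0.500
    min_separation: float = 0.020
    min_peaks: int = 3
    dominance: float = 1.2          # dominant peak >= 1.2x flanking peaks
    edge_zero: float = 0.100        # s zeroed at each trial edge
    smooth_sigma: float = 0.0       # optional envelope smoothing SD, s
    peak_smooth: float = 0.006      # smoothing SD for peak localisation, s
    gap_close: float = 0.010        # merge excursions separated by < this, s
    flank_pad: float = 0.050        # s searched for flanking peaks
    peak_strategy: str = "oscillation"  # or "envelope"


def events_to_frame(events: list[RippleEvent], subject: str = "",
                    session: str = "") -> pd.DataFrame:
    cols = ["subject", "session", "channel", "trial", "start_s", "peak_s",
            "end_s", "duration_s", "peak_z", "n_peaks"]
    rows = [[subject, session, e.channel, e.trial_index, e.start_time,
             e.peak_time, e.end_time, e.duration, e.peak_z, e.n_supra_peaks]
            for e in events]
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _supra_segments(z: np.ndarray, thresh: float, gap: int = 0
                    ) -> list[tuple[int, int]]:
    """Contiguous index runs where z > thresh, as [start, end) pairs.

    Runs separated by fewer than `gap` samples are merged: a brief noise dip
    below threshold inside one burst should not split it in two.
    """
    above = z > thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    segs = [(int(a), int(b)) for a, b in zip(starts, ends)]
    if gap > 0:
        merged = [segs[0]]
        for a, b in segs[1:]:
            if a - merged[-1][1] < gap:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        segs = merged
    return segs


def _analyze_peaks(bp: np.ndarray, env_raw: np.ndarray,
                   seg: tuple[int, int], mean: float, sd: float,
                   thresh: float, factor: float, pad: int,
                   boundary_z: float = 2.0) -> tuple[int, bool]:
    """Peak-count and dominance criteria for one supra-threshold excursion.

    Peak *timing* comes from local maxima of |band-passed signal|; peak
    *amplitude* is the unsmoothed analytic envelope at those instants (at a
    500 Hz sampling rate an 80-150 Hz carrier is sampled only ~2-3 times
    per half-cycle, so the rectified sample heights alias the carrier).
    Returns (number of in-excursion peaks with amplitude z > thresh, whether
    the largest in-excursion peak amplitude is >= factor times the
    oscillation peaks immediately flanking the excursion). A burst that
    stands out of its immediate (sub-boundary) surroundings has a dominant
    peak; a marginal excursion whose neighbourhood is nearly as high does
    not.
    """
    a, b = seg
    lo, hi = max(0, a - pad), min(bp.size, b + pad)
    rect = np.abs(bp[lo:hi])
    locs, _ = sps.find_peaks(rect)
    pos = locs + lo
    amps = env_raw[pos]
    in_seg = (pos >= a) & (pos < b)
    zs = (amps - mean) / sd
    n_supra = int(np.sum(in_seg & (zs > thresh)))
    if n_supra == 0:
        return 0, False
    dom = amps[in_seg].max()
    ok = True
    left, right = amps[pos < a], amps[pos >= b]
    if left.size and dom < factor * left[-1]:
        ok = False
    if right.size and dom < factor * right[0]:
        ok = False
    return n_supra, ok


def _enforce_separation(events: list[RippleEvent], min_sep: float
                        ) -> list[RippleEvent]:
    """Iteratively drop the weaker of any pair closer than min_sep."""
    evs = sorted(events, key=lambda e: e.peak_time)
    changed = True
    while changed:
        changed = False
        for i in range(len(evs) - 1):
            if evs[i + 1].peak_time - evs[i].peak_time < min_sep:
                drop = i if evs[i].peak_z < evs[i + 1].peak_z else i + 1
                del evs[drop]
                changed = True
                break
    return evs


def detect_ripples(recording: Recording,
                   trial_bounds: list[tuple[int, int]] | None = None,
                   params: RippleParams | None = None,
                   channels: list[str] | None = None) -> list[RippleEvent]:
    """Run the five-criterion ripple detector on each (MEG) channel.

    trial_bounds are (start, end) sample pairs delimiting the trials whose
    edges get envelope zeroing; omit them to treat the recording as one
    segment. Returns events sorted by (channel order, peak time).
    """
    p = params or RippleParams()
    fs = recording.sample_rate
    if recording.n_samples / fs < 10.0:
        raise ValueError("need >= 10 s of data for stable z statistics")
    rec = recording if channels is None else recording.pick(channels)
    band = bandpass_zero_phase(rec, *p.band)
    env: BandEnvelope = analytic_envelope(band, edge_zero=p.edge_zero,
                                          trial_bounds=trial_bounds,
                                          smooth_sigma=p.smooth_sigma)
    env.normalise()
    if p.smooth_sigma == 0:
        env_raw = env.envelope
        raw_mean, raw_sd = env.norm_mean, env.norm_sd
    else:
        env_raw = analytic_envelope(band, edge_zero=p.edge_zero,
                                    trial_bounds=trial_bounds).envelope
        raw_mean, raw_sd = env_raw.mean(axis=1), env_raw.std(axis=1)
    z = env.zscore
    if p.peak_smooth > 0:
        from scipy.ndimage import gaussian_filter1d
        z_loc = gaussian_filter1d(z, p.peak_smooth * fs, axis=1)
    else:
        z_loc = z
    pad = int(round(p.flank_pad * fs))
    gap = int(round(p.gap_close * fs))
    all_events: list[RippleEvent] = []
    for ci, label in enumerate(rec.channel_labels):
        mean_c, sd_c = raw_mean[ci], raw_sd[ci]
        events: list[RippleEvent] = []
        for a, b in _supra_segments(z[ci], p.boundary_z, gap):
            dur = (b - 1 - a) / fs
            if not (p.min_dur <= dur <= p.max_dur):
                continue
            if not (p.z_thresh < z[ci, a:b].max() <= p.z_max):
                continue
            if p.peak_strategy == "oscillation":
                n_peaks, dom_ok = _analyze_peaks(
                    band.data[ci], env_raw[ci], (a, b), mean_c, sd_c,
                    p.z_thresh, p.dominance, pad, p.boundary_z)
            else:
                locs, _ = sps.find_peaks(env_raw[ci, a:b])
                zenv = (env_raw[ci, a:b][locs] - mean_c) / sd_c
                n_peaks, dom_ok = int((zenv > p.z_thresh).sum()), True
            if n_peaks < p.min_peaks:
                continue
            if not dom_ok:
                continue
            pk = a + int(np.argmax(z_loc[ci, a:b]))
            trial = -1
            if trial_bounds is not None:
                for ti, (ta, tb) in enumerate(trial_bounds):
                    if ta <= pk < tb:
                        trial = ti
                        break
            events.append(RippleEvent(
                channel=label, peak_time=pk / fs, start_time=a / fs,
                end_time=(b - 1) / fs, peak_z=float(z[ci, a:b].max()),
                n_supra_peaks=n_peaks, trial_index=trial))
        all_events.extend(_enforce_separation(events, p.min_separation))
    return all_events


def revalidate_event(event: RippleEvent, recording: Recording,
                     params: RippleParams | None = None,
                     trial_bounds: list[tuple[int, int]] | None = None
                     ) -> bool:
    """Independently re-test one event against the raw signal.

    Recomputes the band envelope and checks every criterion from scratch;
    used by the test suite as a cross-check on the detector's bookkeeping.
    """
    p = params or RippleParams()
    fs = recording.sample_rate
    ci = recording.channel_index(event.channel)
    band = bandpass_zero_phase(recording, *p.band)
    env = analytic_envelope(band, edge_zero=p.edge_zero,
                            trial_bounds=trial_bounds,
                            smooth_sigma=p.smooth_sigma).normalise()
    if p.smooth_sigma == 0:
        env_raw = env.envelope
        r_mean, r_sd = env.norm_mean[ci], env.norm_sd[ci]
    else:
        env_raw = analytic_envelope(band, edge_zero=p.edge_zero,
                                    trial_bounds=trial_bounds).envelope
        r_mean, r_sd = env_raw[ci].mean(), env_raw[ci].std()
    z = env.zscore[ci]
    a = int(round(event.start_time * fs))
    b = int(round(event.end_time * fs)) + 1
    if not (p.min_dur <= (b - 1 - a) / fs <= p.max_dur):
        return False
    if z[a:b].max() <= p.z_thresh or z[a:b].max() > p.z_max:
        return False
    n_peaks, dom_ok = _analyze_peaks(
        band.data[ci], env_raw[ci], (a, b), r_mean, r_sd,
        p.z_thresh, p.dominance, int(round(p.flank_pad * fs)),
        p.boundary_z)
    return n_peaks >= p.min_peaks and dom_ok


# --------------------------------------------------------------------------
# ripple-centered waveform and time-frequency image
# --------------------------------------------------------------------------

def ripple_triggered_waveform(recording_broadband: Recording,
                              events: list[RippleEvent],
                              t_start: float = -1.0, t_end: float = 1.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Mean broadband waveform around ripple peaks (each event's own channel).

    Returns (times, mean waveform).
    """
    if not events:
        raise ValueError("no events")
    fs = recording_broadband.sample_rate
    traces, times = [], None
    for e in events:
        ci = recording_broadband.channel_index(e.channel)
        try:
            ep, times = epoch_array(recording_broadband.data[ci], fs,
                                    np.array([e.peak_time]), t_start, t_end)
        except ValueError:
            continue
        traces.append(ep[0])
    if not traces:
        raise ValueError("no epochs fit inside the recording")
    return times, np.mean(traces, axis=0)


def ripple_triggered_tf(recording: Recording, events: list[RippleEvent],
                        fmin: float = 1.0, fmax: float = 200.0,
                        n_bands: int = 38,
                        baseline: tuple[float, float] = (-1.0, -0.2)
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-scored band x time image around ripple peaks.

    38 log-spaced bands 1-200 Hz, 10% bandwidth, epochs (-1, 1) s averaged
    over events, z-scored per band to the pre-event baseline. Returns
    (centers, times, image[band, time]).
    """
    if not events:
        raise ValueError("no events")
    fs = recording.sample_rate
    centers, stack = tf_amplitude(recording, fmin, fmax, n_bands)
    by_channel: dict[str, list[float]] = {}
    for e in events:
        by_channel.setdefault(e.channel, []).append(e.peak_time)
    img, times = None, None
    n_total = 0
    for label, peaks in by_channel.items():
        ci = recording.channel_index(label)
        for band_i in range(n_bands):
            ep, times = epoch_array(stack[band_i, ci], fs,
                                    np.asarray(peaks), -1.0, 1.0)
            if img is None:
                img = np.zeros((n_bands, times.size))
            img[band_i] += ep.sum(axis=0)
            if band_i == 0:
                n_total += ep.shape[0]
    img /= n_total
    out = np.empty_like(img)
    for band_i in range(n_bands):
        out[band_i] = zscore_series_to_baseline(img[band_i], times, baseline)
    return centers, times, out


# --------------------------------------------------------------------------
# topography
# --------------------------------------------------------------------------

def sensor_likelihood_map(events: list[RippleEvent], n_trials: int,
                          sensors: list[str]) -> np.ndarray:
    """Mean ripples per trial for each sensor."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    counts = np.zeros(len(sensors))
    index = {s: i for i, s in enumerate(sensors)}
    for e in events:
        if e.channel in index:
            counts[index[e.channel]] += 1
    return counts / n_trials


@dataclass
class TopographyResult:
    pair_r: np.ndarray          # n*(n-1)/2 Pearson r over sensors
    pair_z: np.ndarray          # atanh-transformed
    excluded_pairs: int


def topography_consistency(maps: np.ndarray) -> TopographyResult:
    """Pearson r of the sensor likelihood map for every unordered subject pair.

    maps is (n_subjects, n_sensors). Constant maps make r undefined; such
    pairs are excluded and counted. |r| = 1 is clipped before atanh.
    """
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    rs, excluded = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if maps[i].std() == 0 or maps[j].std() == 0:
                excluded += 1
                continue
            rs.append(float(np.corrcoef(maps[i], maps[j])[0, 1]))
    rs = np.asarray(rs)
    clip = 1.0 - 1e-12
    zs = np.arctanh(np.clip(rs, -clip, clip))
    return TopographyResult(pair_r=rs, pair_z=zs, excluded_pairs=excluded)


def compare_topography_sessions(rest: TopographyResult,
                                pa: TopographyResult) -> tuple[float, float]:
    """Paired t-test on Fisher-transformed pair correlations, PA vs rest."""
    t, pv = st.ttest_rel(pa.pair_z, rest.pair_z)
    return float(t), float(pv)


def select_top_sensors(likelihood: np.ndarray, sensors: list[str],
                       k: int = 4) -> list[str]:
    """The k sensors with the highest ripple likelihood; ties keep channel order."""
    if k > len(sensors):
        raise ValueError("k exceeds sensor count")
    order = np.argsort(-np.asarray(likelihood), kind="stable")
    return [sensors[i] for i in sorted(order[:k].tolist())]


# --------------------------------------------------------------------------
# stimulus-locked likelihood time series
# --------------------------------------------------------------------------

def events_to_series(events: list[RippleEvent], n_samples: int, fs: float,
                     channels: list[str] | None = None) -> np.ndarray:
    """Per-sample ripple counts summed over the given channels."""
    series = np.zeros(n_samples)
    for e in events:
        if channels is not None and e.channel not in channels:
            continue
        i = int(round(e.peak_time * fs))
        if 0 <= i < n_samples:
            series[i] += 1
    return series


def stimulus_locked_likelihood(events: list[RippleEvent],
                               onsets: np.ndarray, top_sensors: list[str],
                               n_samples: int, fs: float,
                               t_start: float = -1.0, t_end: float = 3.0,
                               window: float = 0.200,
                               baseline: tuple[float, float] = (-0.200, 0.0),
                               zscore: bool = True) -> LikelihoodSeries:
    """Peristimulus ripple-rate time course R(t) over the top sensors.

    Ripple peaks across the top sensors and all trials are summed into a
    per-sample series, counted in a 200 ms moving window, and z-scored to the
    pre-stimulus baseline.
    """
    series = events_to_series(events, n_samples, fs, top_sensors)
    epochs, times = epoch_array(series, fs, onsets, t_start, t_end)
    summed = epochs.sum(axis=0)
    rate = moving_window_rate(summed, window, fs)
    if zscore:
        rate = zscore_series_to_baseline(rate, times, baseline)
    return LikelihoodSeries(times=times, rate=rate, window=window,
                            sample_rate=fs, n_trials=epochs.shape[0],
                            sensors=list(top_sensors), zscored=zscore)


# --------------------------------------------------------------------------
# behavior correlations
# --------------------------------------------------------------------------

def likelihood_performance_correlation(likelihood: np.ndarray,
                                       hit_rate: np.ndarray
                                       ) -> tuple[float, float]:
    """Rank (Spearman) correlation of per-subject ripple likelihood vs hit rate."""
    likelihood = np.asarray(likelihood, float)
    hit_rate = np.asarray(hit_rate, float)
    if likelihood.size < 5:
        raise ValueError("need >= 5 subjects")
    r, p = st.spearmanr(likelihood, hit_rate)
    return float(r), float(p)


def mean_likelihood_in_window(series: LikelihoodSeries,
                              window: tuple[float, float]) -> float:
    mask = (series.times >= window[0]) & (series.times <= window[1])
    return float(series.rate[mask].mean())


@dataclass
class NbackScalingResult:
    subject_r: np.ndarray       # per-subject Pearson r of rate vs N
    subject_z: np.ndarray       # atanh-transformed
    excluded: list[int]         # subjects with zero rate variance
    t_stat: float               # one-sided group t against 0
    p_value: float


def nback_scaling(rates: np.ndarray, n_levels: tuple[int, ...] = (2, 3, 4)
                  ) -> NbackScalingResult:
    """Per-subject correlation of ripple rate with N, tested > 0 at the group level.

    rates is (n_subjects, len(n_levels)). Subjects with no rate variance have
    undefined r and are excluded (reported).
    """
    n_arr = np.asarray(n_levels, float)
    rs, excluded = [], []
    for i in range(rates.shape[0]):
        if np.std(rates[i]) == 0:
            excluded.append(i)
            continue
        rs.append(float(np.corrcoef(rates[i], n_arr)[0, 1]))
    rs = np.asarray(rs)
    clip = 1.0 - 1e-12
    zs = np.arctanh(np.clip(rs, -clip, clip))
    if zs.size >= 2:
        t, p = st.ttest_1samp(zs, 0.0, alternative="greater")
    else:
        t, p = np.nan, np.nan
    return NbackScalingResult(subject_r=rs, subject_z=zs, excluded=excluded,
                              t_stat=float(t), p_value=float(p))


def compare_nback_scaling(rest: NbackScalingResult, pa: NbackScalingResult
                          ) -> tuple[float, float]:
    """Paired one-sided t-test: PA scaling stronger than rest (atanh scale)."""
    t, p = st.ttest_rel(pa.subject_z, rest.subject_z, alternative="greater")
    return float(t), float(p)
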
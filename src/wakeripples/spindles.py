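"""Wake-spindle amplitude time courses and discrete spindle-event detection.

Two band definitions coexist deliberately: the stimulus-locked amplitude
analysis uses 14-18 Hz (the band with the clearest task modulation at
fronto-central channels), while discrete event detection uses the wider
13-20 Hz spindle band. Events are centered on the oscillation trough nearest
the envelope maximum, because ripple placement is phase-specific and the
trough is the phase-stable anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps
import scipy.stats as st

from .core import (
    Recording,
    analytic_envelope,
    bandpass_zero_phase,
    epoch_extract,
    zscore_to_baseline,
)

ROI_DEFAULT = ["Fz", "Cz", "FC1", "FC2"]


@dataclass
class SpindleEvent:
    """One detected wake-spindle bout."""

    channel: str
    envelope_peak_time: float   # envelope-z maximum, s
    center_time: float          # oscillation trough nearest envelope peak, s
    start_time: float           # envelope valley, s
    end_time: float             # envelope valley, s
    peak_z: float
    edge_flagged: bool = False  # boundary fell back to the epoch edge

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


# --------------------------------------------------------------------------
# stimulus-locked amplitude time course
# --------------------------------------------------------------------------

def spindle_amplitude_timecourse(recording: Recording, onsets: np.ndarray,
                                 roi: list[str] | None = None,
                                 band: tuple[float, float] = (14.0, 18.0),
                                 t_start: float = -1.0, t_end: float = 2.0,
                                 baseline: tuple[float, float] = (-0.2, 0.0)
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged, baseline-z-scored spindle-band envelope at ROI channels.

    Band-pass, Hilbert envelope, epochs around stimulus onsets, z-scored to
    the 200 ms pre-stimulus baseline, averaged over trials and ROI channels.
    Returns (times, time course).
    """
    roi = roi or ROI_DEFAULT
    for ch in roi:
        if ch not in recording.channel_labels:
            raise ValueError(f"ROI channel {ch!r} missing from recording")
    rec = recording.pick(roi)
    band_rec = bandpass_zero_phase(rec, *band)
    env = analytic_envelope(band_rec).envelope
    env_rec = Recording(env, rec.sample_rate, rec.channel_labels,
                        rec.modality, rec.subject_id, rec.session)
    epochs = epoch_extract(env_rec, onsets, t_start, t_end,
                           lock_kind="stimulus", baseline=baseline)
    epochs = zscore_to_baseline(epochs)
    return epochs.times, epochs.data.mean(axis=(0, 1))


def spindle_session_contrast(pa_means: np.ndarray, rest_means: np.ndarray
                             ) -> tuple[float, float]:
    """Paired t-test on per-subject mean spindle amplitude, PA vs rest."""
    t, p = st.ttest_rel(pa_means, rest_means)
    return float(t), float(p)


def mean_in_window(times: np.ndarray, course: np.ndarray,
                   window: tuple[float, float] = (1.0, 2.0)) -> float:
    mask = (times >= window[0]) & (times <= window[1])
    return float(course[mask].mean())


# --------------------------------------------------------------------------
# discrete spindle-event detection
# --------------------------------------------------------------------------

def _local_minima(x: np.ndarray) -> np.ndarray:
    locs, _ = sps.find_peaks(-x)
    return locs


def detect_spindle_events(recording: Recording,
                          roi: list[str] | None = None,
                          band: tuple[float, float] = (13.0, 20.0),
                          z_thresh: float = 4.0,
                          epoch_half: float = 2.0,
                          boundary_sd: float = 1.0) -> list[SpindleEvent]:
    """Detect discrete spindle bouts on each ROI channel.

    Pipeline per channel: band-pass 13-20 Hz, Hilbert envelope z-scored over
    the whole recording; envelope-z peaks above z_thresh mark candidate
    events. Around each peak a (-2, 2) s epoch is cut; the event center is
    the band-passed oscillation trough nearest the envelope peak; boundaries
    are the envelope valleys flanking the run of envelope peaks that exceed
    the event-local mean + 1 SD (epoch edges used, and flagged, when no
    valley exists). Overlapping events on a channel are merged keeping the
    higher peak.
    """
    roi = roi or ROI_DEFAULT
    roi = [ch for ch in roi if ch in recording.channel_labels]
    if not roi:
        raise ValueError("no ROI channels present in recording")
    fs = recording.sample_rate
    if recording.n_samples / fs < 10.0:
        raise ValueError("need >= 10 s of data for stable z statistics")
    rec = recording.pick(roi)
    band_rec = bandpass_zero_phase(rec, *band)
    env = analytic_envelope(band_rec).normalise()
    z = env.zscore
    half = int(round(epoch_half * fs))
    events: list[SpindleEvent] = []
    for ci, label in enumerate(rec.channel_labels):
        peak_locs, _ = sps.find_peaks(z[ci], height=z_thresh)
        ch_events: list[SpindleEvent] = []
        for pk in peak_locs:
            a, b = max(0, pk - half), min(rec.n_samples, pk + half + 1)
            seg_env = env.envelope[ci, a:b]
            seg_bp = band_rec.data[ci, a:b]
            pk_loc = pk - a
            # center: oscillation trough nearest the envelope peak
            troughs = _local_minima(seg_bp)
            if troughs.size == 0:
                continue
            center = troughs[np.argmin(np.abs(troughs - pk_loc))]
            # boundaries from envelope valleys flanking the contiguous
            # supra-threshold envelope region around the detected peak;
            # the threshold is event-local (epoch mean + 1 SD)
            thresh = seg_env.mean() + boundary_sd * seg_env.std()
            above = seg_env > thresh
            if not above[pk_loc]:
                continue
            ra = pk_loc
            while ra > 0 and above[ra - 1]:
                ra -= 1
            rb = pk_loc
            while rb < above.size - 1 and above[rb + 1]:
                rb += 1
            env_peaks, _ = sps.find_peaks(seg_env[ra:rb + 1])
            env_peaks = (env_peaks + ra if env_peaks.size
                         else np.array([pk_loc]))
            valleys = _local_minima(seg_env)
            before = valleys[valleys < env_peaks[0]]
            after = valleys[valleys > env_peaks[-1]]
            flagged = False
            if before.size:
                start = before[-1]
            else:
                start, flagged = 0, True
            if after.size:
                end = after[0]
            else:
                end, flagged = seg_env.size - 1, True
            if not (start < center < end):
                # trough outside the envelope-defined bout: recenter to the
                # trough nearest the peak inside the boundaries
                inside = troughs[(troughs > start) & (troughs < end)]
                if inside.size == 0:
                    continue
                center = inside[np.argmin(np.abs(inside - pk_loc))]
            ch_events.append(SpindleEvent(
                channel=label,
                envelope_peak_time=pk / fs,
                center_time=(a + center) / fs,
                start_time=(a + start) / fs,
                end_time=(a + end) / fs,
                peak_z=float(z[ci, pk]),
                edge_flagged=flagged))
        events.extend(_merge_overlaps(ch_events))
    return events


def _merge_overlaps(events: list[SpindleEvent]) -> list[SpindleEvent]:
    """Merge overlapping events on one channel, keeping the higher peak."""
    evs = sorted(events, key=lambda e: e.start_time)
    out: list[SpindleEvent] = []
    for e in evs:
        if out and e.start_time < out[-1].end_time:
            if e.peak_z > out[-1].peak_z:
                out[-1] = e
        else:
            out.append(e)
    return out


def revalidate_spindle(event: SpindleEvent, recording: Recording,
                       band: tuple[float, float] = (13.0, 20.0)) -> bool:
    """Check independently that the event center is a band-passed local minimum."""
    fs = recording.sample_rate
    ci = recording.channel_index(event.channel)
    bp = bandpass_zero_phase(recording, *band).data[ci]
    c = int(round(event.center_time * fs))
    if c <= 0 or c >= bp.size - 1:
        return False
    return bp[c] <= bp[c - 1] and bp[c] <= bp[c + 1]
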
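"""Synthetic EEG/MEG cohort generator with full ground truth.

Builds recordings whose statistical structure matches what the downstream
analyses assume: 1/f background noise, wake-spindle bouts (13-16 Hz,
raised-cosine envelope) on fronto-central EEG channels, brief high-frequency
ripple bursts (~90-120 Hz, 20-50 ms, Gaussian taper) on designated MEG
channels, optional von-Mises phase-locking of ripples to the spindle
oscillation, a stimulus-locked ripple-rate profile (suppression then
rebound), and N-back behavior with logistic hit probabilities.

Every injected event is logged in a GroundTruth object so detectors and
coupling estimators can be scored against what was actually placed in the
signal. All randomness flows through numpy Generators seeded from the
config, so identical configs give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from string import ascii_uppercase

import numpy as np
import pandas as pd

from .core import Recording, analytic_envelope, bandpass_zero_phase
from .ripples import RippleParams

EEG_ROI = ["Fz", "Cz", "FC1", "FC2"]


@dataclass
class SimConfig:
    """All generator parameters; defaults follow the study conditions."""

    sample_rate: float = 500.0
    n_channels_meg: int = 102
    n_channels_eeg: int = 30
    noise_exponent: float = 1.0

    spindle_rate: float = 0.05          # events/s on ROI channels
    spindle_freq_range: tuple[float, float] = (13.0, 16.0)
    spindle_dur_range: tuple[float, float] = (0.5, 1.0)
    spindle_z_target: float = 6.0       # envelope z of injected bouts

    ripple_rate: float = 0.125          # events/s per ripple-carrying sensor
    ripple_freq_range: tuple[float, float] = (90.0, 120.0)
    ripple_dur_range: tuple[float, float] = (0.02, 0.05)
    ripple_z_target: float = 4.0
    n_ripple_channels: int = 4          # "MTL" sensors carrying ripples

    coupling_mu: float = np.pi          # preferred spindle phase (0 = peak)
    coupling_kappa: float = 0.0         # von-Mises concentration; 0 = none
    p_ripple_in_spindle: float = 0.0

    # stimulus-locked multiplicative rate profile
    dip_gain: float = 0.5
    dip_window: tuple[float, float] = (0.3, 1.0)
    rebound_gain: float = 1.6
    rebound_window: tuple[float, float] = (1.5, 2.5)

    n_blocks: int = 12
    trials_per_block: int = 100
    targets_per_block: int = 30
    trial_soa: float = 2.52             # stimulus onset asynchrony, s
    lead_time: float = 2.5              # s before the first stimulus
    tail_time: float = 3.0              # s after the last stimulus

    # behavior: p(hit) = sigmoid(intercept + ability + pa_benefit*is_pa
    #                            - difficulty*(N-2))
    behavior_intercept: float = 1.3
    difficulty: float = 0.75
    pa_benefit: float = 0.3
    ability_sd: float = 0.5
    fa_prob: float = 0.04

    seed: int = 0

    def __post_init__(self) -> None:
        if self.spindle_rate < 0 or self.ripple_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be non-negative")
        for rng_ in (self.spindle_dur_range, self.ripple_dur_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("duration ranges must be positive, ordered")
        if not 0 <= self.p_ripple_in_spindle <= 1:
            raise ValueError("p_ripple_in_spindle must be in [0, 1]")
        if self.targets_per_block > self.trials_per_block:
            raise ValueError("more targets than trials per block")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def duration(self) -> float:
        return (self.lead_time + (self.n_trials - 1) * self.trial_soa
                + self.tail_time)

    def stim_onsets(self) -> np.ndarray:
        return self.lead_time + np.arange(self.n_trials) * self.trial_soa

    def eeg_labels(self) -> list[str]:
        extra = [f"E{i:02d}" for i in range(1, self.n_channels_eeg
                                            - len(EEG_ROI) + 1)]
        return (EEG_ROI + extra)[: self.n_channels_eeg]

    def meg_labels(self) -> list[str]:
        return [f"MEG{i:03d}" for i in range(1, self.n_channels_meg + 1)]

    def ripple_channels(self) -> list[str]:
        return self.meg_labels()[: self.n_ripple_channels]


@dataclass
class GroundTruth:
    """Everything that was injected, for scoring detectors and estimators."""

    ripple_times: dict[str, np.ndarray] = field(default_factory=dict)
    ripple_in_spindle: dict[str, np.ndarray] = field(default_factory=dict)
    ripple_phases: dict[str, np.ndarray] = field(default_factory=dict)
    spindle_intervals: dict[str, np.ndarray] = field(default_factory=dict)
    spindle_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    coupling_mu: float = 0.0
    coupling_kappa: float = 0.0
    stim_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    block_n: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    behavior_params: dict = field(default_factory=dict)

    def all_ripple_times(self) -> np.ndarray:
        if not self.ripple_times:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.ripple_times.values())))


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def one_over_f_noise(n_samples: int, exponent: float, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent, unit SD."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples)
    return x / x.std()


def peristimulus_gain(t_rel: np.ndarray, config: SimConfig,
                      rebound_gain: float | None = None) -> np.ndarray:
    """Multiplicative ripple-rate profile vs time since last stimulus onset.

    A dip during early stimulus processing and a rebound bump later, each
    with 100 ms half-cosine ramps.
    """
    rb = config.rebound_gain if rebound_gain is None else rebound_gain
    g = np.ones_like(t_rel, dtype=float)
    for (a, b), level in ((config.dip_window, config.dip_gain),
                          ((config.rebound_window), rb)):
        ramp = 0.1
        w = np.clip((t_rel - (a - ramp)) / ramp, 0, 1) \
            * np.clip(((b + ramp) - t_rel) / ramp, 0, 1)
        w = np.minimum(w, 1.0)
        g *= 1.0 + (level - 1.0) * w
    return g


def _band_env_stats(noise: np.ndarray, fs: float, band: tuple[float, float],
                    labels: list[str], smooth_sigma: float = 0.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD of the background band envelope.

    Uses the same envelope pipeline the detectors use (including their
    smoothing), so burst amplitudes calibrated from these statistics land at
    the requested post-detection z.
    """
    rec = Recording(noise, fs, labels, ["EEG"] * len(labels))
    env = analytic_envelope(bandpass_zero_phase(rec, *band),
                            smooth_sigma=smooth_sigma).envelope
    return env.mean(axis=1), env.std(axis=1)


def _calibrated_bout_amp(mu: float, sd: float, z_target: float,
                         occupancy: float) -> float:
    """Bout amplitude whose envelope peak lands at z_target after the bouts
    themselves contaminate the whole-recording envelope statistics.

    The z-scoring population includes the injected bouts, which raise the
    envelope mean and SD; for a Hann-enveloped bout of amplitude A occupying
    a fraction f of samples, E[w] = 1/2 and E[w^2] = 3/8, so the
    contaminated moments are solved by fixed-point iteration.
    """
    a = mu + z_target * sd
    for _ in range(20):
        mean_c = (1 - occupancy) * mu + occupancy * 0.5 * a
        var_c = ((1 - occupancy) * (sd ** 2 + mu ** 2)
                 + occupancy * 0.375 * a ** 2 - mean_c ** 2)
        a_new = mean_c + z_target * np.sqrt(max(var_c, 1e-30))
        if abs(a_new - a) < 1e-9 * max(a, 1.0):
            a = a_new
            break
        a = a_new
    return a


def _poisson_times(rate: float, lo: float, hi: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * (hi - lo))
    return np.sort(rng.uniform(lo, hi, size=n))


BURST_TAPER = 0.71      # taper SD as a fraction of nominal duration


def _gaussian_burst(t: np.ndarray, t_peak: float, freq: float, dur: float,
                    amp: float) -> np.ndarray:
    """Gaussian-tapered sinusoidal ripple burst.

    The taper SD is 0.71*dur so that, for a burst whose envelope peak sits
    near the default detection level, the threshold-crossing width roughly
    equals the nominal duration.
    """
    sd = BURST_TAPER * dur
    dt = t - t_peak
    return amp * np.exp(-0.5 * (dt / sd) ** 2) \
        * np.cos(2 * np.pi * freq * dt)


def spindle_phase_at(t: np.ndarray | float, center: float,
                     freq: float) -> np.ndarray:
    """Phase of an injected bout at time t; 0 = oscillation peak, +/-pi = trough.

    The bout carrier is cos(2*pi*f*(t - center) + pi), so the trough sits at
    the envelope maximum (the bout center).
    """
    ph = 2 * np.pi * freq * (np.asarray(t) - center) + np.pi
    return np.angle(np.exp(1j * ph))


# --------------------------------------------------------------------------
# recording simulation
# --------------------------------------------------------------------------

def _place_spindles(config: SimConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping spindle intervals (start, end, center) and frequencies."""
    margin = 1.5
    dur_total = config.duration
    if dur_total < 2 * margin + config.spindle_dur_range[1]:
        raise ValueError(
            f"recording of {dur_total:.1f} s too short to place spindles")
    centers = _poisson_times(config.spindle_rate, margin, dur_total - margin,
                             rng)
    durs = rng.uniform(*config.spindle_dur_range, size=centers.size)
    freqs = rng.uniform(*config.spindle_freq_range, size=centers.size)
    keep, last_end = [], -np.inf
    for i in range(centers.size):
        start = centers[i] - durs[i] / 2
        if start > last_end + 0.25:
            keep.append(i)
            last_end = centers[i] + durs[i] / 2
    centers, durs, freqs = centers[keep], durs[keep], freqs[keep]
    intervals = np.column_stack([centers - durs / 2, centers + durs / 2,
                                 centers])
    return intervals, freqs


def _place_ripples(config: SimConfig, spindles: np.ndarray,
                   spindle_freqs: np.ndarray, rng: np.random.Generator,
                   rebound_gain: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ripple peak times for one channel: inhomogeneous-Poisson baseline plus
    optional von-Mises phase-locking inside spindle bouts.

    Returns (times, in_spindle flags, spindle phases at placement; nan when
    placed outside any bout).
    """
    margin = 1.5
    dur_total = config.duration
    if dur_total < 2 * margin + 1.0:
        raise ValueError(
            f"recording of {dur_total:.1f} s too short to place ripples")
    onsets = config.stim_onsets()
    gmax = max(config.rebound_gain if rebound_gain is None else rebound_gain,
               1.0)
    cand = _poisson_times(config.ripple_rate * gmax, margin,
                          dur_total - margin, rng)
    # thin against the stimulus-locked gain profile
    if cand.size and onsets.size:
        idx = np.searchsorted(onsets, cand, side="right") - 1
        t_rel = np.where(idx >= 0, cand - onsets[np.clip(idx, 0, None)],
                         np.inf)
        gain = peristimulus_gain(t_rel, config, rebound_gain)
        cand = cand[rng.uniform(size=cand.size) < gain / gmax]
    times, flags, phases = [], [], []
    for t in cand:
        placed = False
        if (spindles.shape[0] > 0 and config.coupling_kappa >= 0
                and rng.uniform() < config.p_ripple_in_spindle):
            k = rng.integers(spindles.shape[0])
            start, end, center = spindles[k]
            f = spindle_freqs[k]
            theta = (rng.vonmises(config.coupling_mu, config.coupling_kappa)
                     if config.coupling_kappa > 0
                     else rng.uniform(-np.pi, np.pi))
            # candidate cycle-aligned times at that phase inside the bout
            base = center + (theta - np.pi) / (2 * np.pi * f)
            ks = np.arange(np.ceil((start + 0.05 - base) * f),
                           np.floor((end - 0.05 - base) * f) + 1)
            if ks.size:
                t_new = base + rng.choice(ks) / f
                times.append(t_new)
                flags.append(True)
                phases.append(theta)
                placed = True
        if not placed:
            times.append(t)
            flags.append(False)
            phases.append(np.nan)
    times = np.asarray(times)
    order = np.argsort(times)
    times, flags, phases = (times[order], np.asarray(flags)[order],
                            np.asarray(phases)[order])
    # drop near-coincident injections on the same channel
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > 0.1])
        times, flags, phases = times[keep], flags[keep], phases[keep]
    return times, flags, phases


def simulate_recording(config: SimConfig, subject_id: str = "S01",
                       session: str = "rest",
                       rng: np.random.Generator | None = None,
                       rebound_gain: float | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Generate one session's multichannel recording plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n_samp = int(round(config.duration * fs))
    t = np.arange(n_samp) / fs

    eeg_labels = config.eeg_labels()
    meg_labels = config.meg_labels()
    labels = eeg_labels + meg_labels
    modality = ["EEG"] * len(eeg_labels) + ["MEG"] * len(meg_labels)
    data = np.empty((len(labels), n_samp))
    for i in range(len(labels)):
        data[i] = one_over_f_noise(n_samp, config.noise_exponent, fs, rng)

    gt = GroundTruth(coupling_mu=config.coupling_mu,
                     coupling_kappa=config.coupling_kappa,
                     stim_onsets=config.stim_onsets())

    # --- spindles on the fronto-central EEG ROI (shared source) ---
    spindles, sp_freqs = _place_spindles(config, rng)
    roi = [lb for lb in EEG_ROI if lb in eeg_labels]
    if roi:
        roi_idx = [labels.index(lb) for lb in roi]
        mu, sd = _band_env_stats(data[roi_idx], fs, (13.0, 20.0), roi)
        occupancy = float(np.sum(spindles[:, 1] - spindles[:, 0])
                          / config.duration)
        amps = np.array([
            _calibrated_bout_amp(mu[c], sd[c], config.spindle_z_target,
                                 occupancy) for c in range(len(roi))])
        for j, (start, end, center) in enumerate(spindles):
            i0, i1 = int(np.ceil(start * fs)), int(np.floor(end * fs)) + 1
            seg_t = t[i0:i1]
            env = np.hanning(i1 - i0)
            carrier = np.cos(2 * np.pi * sp_freqs[j] * (seg_t - center)
                             + np.pi)
            for ci, gi in enumerate(roi_idx):
                data[gi, i0:i1] += amps[ci] * env * carrier
        for lb in roi:
            gt.spindle_intervals[lb] = spindles.copy()
            gt.spindle_freqs[lb] = sp_freqs.copy()

    # --- ripples on designated MEG channels ---
    smooth = RippleParams().smooth_sigma
    for lb in config.ripple_channels():
        gi = labels.index(lb)
        mu, sd = _band_env_stats(data[gi:gi + 1], fs, (80.0, 150.0), [lb],
                                 smooth_sigma=smooth)
        times, flags, phases = _place_ripples(config, spindles, sp_freqs,
                                              rng, rebound_gain)
        for tp in times:
            f = rng.uniform(*config.ripple_freq_range)
            dur = rng.uniform(*config.ripple_dur_range)
            # smoothing attenuates the burst's envelope peak; compensate so
            # the post-detection z still lands near the configured target
            sig = BURST_TAPER * dur
            atten = sig / np.sqrt(sig ** 2 + smooth ** 2)
            amp = mu[0] + config.ripple_z_target * sd[0] / atten
            half = int(round(3 * dur * fs))
            i0, i1 = int(round(tp * fs)) - half, int(round(tp * fs)) + half + 1
            data[gi, i0:i1] += _gaussian_burst(t[i0:i1], tp, f, dur, amp)
        gt.ripple_times[lb] = times
        gt.ripple_in_spindle[lb] = flags
        gt.ripple_phases[lb] = phases

    rec = Recording(data, fs, labels, modality, subject_id, session)
    return rec, gt


# --------------------------------------------------------------------------
# behavior simulation
# --------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def make_block_letters(n_back: int, n_trials: int, n_targets: int,
                       rng: np.random.Generator
                       ) -> tuple[list[str], np.ndarray]:
    """Letter sequence with exactly n_targets N-back matches."""
    if n_back >= n_trials:
        raise ValueError(f"N={n_back} exceeds the {n_trials}-trial window")
    eligible = np.arange(n_back, n_trials)
    if n_targets > eligible.size:
        raise ValueError("too many targets for this block length")
    target_pos = set(rng.choice(eligible, size=n_targets, replace=False)
                     .tolist())
    letters: list[str] = []
    for i in range(n_trials):
        if i in target_pos:
            letters.append(letters[i - n_back])
        else:
            choices = list(ascii_uppercase)
            if i >= n_back:
                choices.remove(letters[i - n_back])
            letters.append(choices[rng.integers(len(choices))])
    is_target = np.array([i in target_pos for i in range(n_trials)])
    return letters, is_target


def simulate_behavior(config: SimConfig, ability: float = 0.0,
                      session: str = "rest", subject_id: str = "S01",
                      block_n: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-trial N-back table with logistic hit and constant false-alarm rates."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if block_n is None:
        block_n = draw_block_n(config, rng)
    is_pa = 1.0 if session == "PA" else 0.0
    rows = []
    for b in range(config.n_blocks):
        n = int(block_n[b])
        p_hit = _sigmoid(config.behavior_intercept + ability
                         + config.pa_benefit * is_pa
                         - config.difficulty * (n - 2))
        letters, is_target = make_block_letters(
            n, config.trials_per_block, config.targets_per_block, rng)
        for i in range(config.trials_per_block):
            if is_target[i]:
                resp = "target" if rng.uniform() < p_hit else "standard"
            else:
                resp = "target" if rng.uniform() < config.fa_prob else "standard"
            rows.append({
                "subject": subject_id, "session": session, "block": b,
                "trial_index": b * config.trials_per_block + i,
                "n_back": n, "letter": letters[i],
                "is_target": bool(is_target[i]), "response": resp,
                "rt_ms": float(rng.lognormal(6.2, 0.25)),
            })
    return pd.DataFrame(rows)


def draw_block_n(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Balanced assignment of N in {2,3,4} across blocks, shuffled."""
    reps = int(np.ceil(config.n_blocks / 3))
    pool = np.tile([2, 3, 4], reps)[: config.n_blocks]
    rng.shuffle(pool)
    return pool


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class SubjectSession:
    recording: Recording
    ground_truth: GroundTruth
    trials: pd.DataFrame


@dataclass
class SubjectData:
    subject_id: str
    ability: float
    sessions: dict[str, SubjectSession]


def simulate_cohort(n_subjects: int, config: SimConfig,
                    pa_overrides: dict | None = None,
                    ability_rate_coupling: float = 0.0,
                    master_seed: int | None = None) -> list[SubjectData]:
    """Generate a paired rest/PA cohort with deterministic per-subject seeds.

    pa_overrides maps SimConfig field names to values applied in the PA
    session only (e.g. {"coupling_kappa": 4.0}). ability_rate_coupling scales
    each subject's rebound gain by (1 + c * ability), linking memory ability
    to the post-stimulus ripple rebound when c > 0.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    seed = config.seed if master_seed is None else master_seed
    ss = np.random.SeedSequence(seed)
    out = []
    for si, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        sid = f"S{si + 1:02d}"
        ability = rng.normal(0.0, config.ability_sd)
        rebound = config.rebound_gain * (1 + ability_rate_coupling * ability)
        rebound = max(rebound, 0.0)
        block_n = draw_block_n(config, rng)
        sessions = {}
        for sess in ("rest", "PA"):
            cfg = config
            if sess == "PA" and pa_overrides:
                cfg = replace(config, **pa_overrides)
            rec, gt = simulate_recording(cfg, sid, sess, rng=rng,
                                         rebound_gain=rebound)
            gt.block_n = block_n.copy()
            gt.behavior_params = {"ability": ability,
                                  "pa_benefit": cfg.pa_benefit,
                                  "difficulty": cfg.difficulty}
            trials = simulate_behavior(cfg, ability, sess, sid,
                                       block_n=block_n, rng=rng)
            sessions[sess] = SubjectSession(rec, gt, trials)
        out.append(SubjectData(sid, ability, sessions))
    return out
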
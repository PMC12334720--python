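# Methods

This note documents the models and procedures implemented in
`wakeripples`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real recordings.

## Signal model and generator

Each synthetic channel is spectrally shaped Gaussian noise with power
∝ 1/f^β (β = 1 by default, unit variance), generated by rFFT shaping.
Three event families are superimposed:

* **Spindle bouts** (fronto-central EEG ROI: Fz, Cz, FC1, FC2, one shared
  source): Hann-enveloped sinusoids, frequency uniform in 13–16 Hz,
  duration uniform in 0.5–1.0 s, placed by a Poisson process
  (0.05 events/s by default) with overlaps dropped. The bout carrier is
  −cos(2πf(t−t_c)), so the oscillation trough coincides with the envelope
  maximum — the same convention the spindle detector uses for its event
  center. Bout amplitude is calibrated so the 13–20 Hz envelope z of the
  bout peak lands at a target (default 6) *after* accounting for the fact
  that the bouts themselves inflate the whole-recording envelope mean and
  SD used for z-scoring; the correction solves the contaminated moments
  (E[w] = 1/2, E[w²] = 3/8 for a Hann envelope occupying a fraction f of
  samples) by fixed-point iteration. Without this correction a nominal
  z = 6 bout measures ≈ 4.6 and detection sensitivity collapses.
* **Ripple bursts** (four designated "MTL" magnetometers): Gaussian-tapered
  sinusoids, frequency uniform in 90–120 Hz, nominal duration 20–50 ms,
  taper SD = 0.71 × duration so the detector's boundary-threshold crossing
  width approximates the nominal duration, amplitude calibrated against
  the channel's 80–150 Hz noise-envelope statistics to a target
  post-detection z (default 4). Baseline rate 0.125 events/s per sensor,
  modulated multiplicatively around each stimulus onset: a dip (gain 0.5
  over 0.3–1.0 s) and a rebound (gain 1.6 over 1.5–2.5 s) with 100 ms
  half-cosine ramps, realised by Poisson thinning.
* **Phase coupling**: with probability `p_ripple_in_spindle` a ripple is
  relocated into a randomly chosen spindle bout at a spindle phase drawn
  von-Mises(μ, κ) (κ = 0 means uniform); candidate times are
  cycle-aligned solutions of the bout's phase equation, at least 50 ms
  inside the bout. Ground truth logs every injected time, its in-bout
  flag and placement phase.

Behavior: letter sequences with exactly 30 targets per 100-trial block
(targets match the letter N back; standards are constrained not to),
hit probability σ(1.3 + ability + 0.3·is_PA − 0.75·(N−2)), false alarms at
a constant 4%, ability ~ N(0, 0.5) per subject. These constants were
chosen once so that a 21-subject cohort reproduces hit rates near
80/65/52% for N = 2/3/4 and a ~6-percentage-point PA benefit, the
magnitudes typical of this paradigm. Stimulus-onset asynchrony is 2.52 s
(100-trial blocks of 252 s).

Every operation draws from a numpy Generator seeded from the
configuration; cohorts derive per-subject seeds from a SeedSequence, so
all outputs are bitwise reproducible.

What the generator deliberately omits: realistic sensor forward fields
and cross-channel noise covariance, eye/cardiac/muscle artifacts, line
noise, non-stationary background, and any spatial structure beyond
"ripples live on four sensors, spindles on the ROI". Passing tests
therefore establish that the *algorithms* recover known structure under
realistic SNR, not that real MEG preprocessing problems are solved.

## Ripple detector

Pipeline: zero-phase 4th-order Butterworth band-pass 80–150 Hz (applied
forward-backward, so the effective magnitude response is 8th order),
Hilbert envelope, per-trial zeroing of the initial and final 100 ms,
per-sensor z-scoring over the concatenated data, then event extraction.

Numerical choices that required decisions:

* **Two-threshold boundaries.** Candidate events are excursions above a
  boundary threshold z = 2.0 (merged across gaps < 10 ms), with the
  detection criterion z > 2.5 applied to the excursion peak. With
  boundaries at 2.5 itself, additive noise splits or clips ~15–20% of
  genuine target-level bursts below the 20 ms minimum duration; the
  two-threshold scheme is the standard remedy.
* **Duration** 20–500 ms between boundary crossings (3 cycles at 150 Hz
  to 40 cycles at 80 Hz); excursions with any sample above z = 9 are
  discarded whole.
* **Oscillation peaks.** The ≥ 3-peak criterion counts local maxima of
  the rectified band-passed signal whose *envelope* value at that instant
  exceeds z = 2.5. At 500 Hz an 80–150 Hz carrier is sampled only ~2–3
  times per half-cycle, so rectified sample heights alias the carrier;
  the envelope read at the peak instants is the alias-free amplitude.
  An envelope-local-maxima counting strategy is available as an option.
* **Dominant peak.** The excursion's largest peak amplitude must be
  ≥ 1.2 × the oscillation peaks immediately flanking the excursion. A
  within-excursion reading (dominant vs its adjacent supra-threshold
  peaks) is unsatisfiable for band-limited signals at this sampling
  rate — a 70 Hz-wide envelope cannot change 20% between peaks 3–6 ms
  apart — so the criterion is anchored to the local surroundings: an
  event must stand out of its neighbourhood, which rejects marginal
  excursions riding on elevated background.
* **Peak time** is the argmax of a 6 ms-Gaussian-smoothed envelope within
  the excursion (criteria are evaluated on the unsmoothed envelope); this
  roughly halves peak-time jitter. Events closer than 20 ms keep the
  higher-amplitude member, iteratively.

Measured on 200 injected 110 Hz / 40 ms bursts at envelope z ≈ 4 in 1/f
noise (the test suite's standing benchmark): sensitivity 0.93–0.96,
precision 0.97–0.99, peak-time MAE 8.5–9.8 ms across seeds. The residual
misses are bursts whose envelope peak lands below ~z 2.8 through
destructive interference — genuinely sub-criterion events in the realised
signal. On pure 1/f noise the detector fires at ~0.03–0.06 events/s per
channel; these false events are indistinguishable in form from weak true
bursts, which is why the behavioral analyses sum over the four most
ripple-dense sensors rather than all of them.

## Spindle analyses

Two band definitions coexist deliberately: 14–18 Hz for the
stimulus-locked amplitude time course (epochs −1 to 2 s, baseline-z-scored
to the 200 ms before onset, averaged over trials and ROI; the PA-vs-rest
contrast is a paired t-test on per-subject means over 1–2 s) and 13–20 Hz
for discrete event detection. Event detection z-scores the envelope over
the whole recording per channel (the data are continuous, and a per-trial
normalisation would couple the threshold to trial content), finds envelope
peaks above z = 4, and within a ±2 s epoch takes the band-passed
oscillation trough nearest the envelope peak as the event center.
Boundaries are the envelope valleys flanking the contiguous region above
the event-local threshold (epoch mean + 1 SD); restricting the boundary
search to that contiguous region matters — peaks of the background
envelope elsewhere in the epoch otherwise stretch events to seconds.
If no valley exists the epoch edge is used and the event flagged.
Overlapping events keep the higher peak. Measured sensitivity for z ≈ 6
bouts is ≥ 0.9 (100 bouts), with centers within one oscillation cycle of
the injected trough-centers.

## Likelihood, coupling and surrogate statistics

R(t) is a centered moving sum (200 ms window, inclusive on the sample
grid: 101 samples at 500 Hz, zero-padded edges) of per-sample ripple
counts summed over the top-4 sensors and all trials, z-scored to the
−200–0 ms pre-stimulus baseline. Epochs use a closed-interval convention
((−1, 1) s at 500 Hz is 1001 samples, symmetric about the lock sample).

Ripple-centered EEG uses the 1–25 Hz band at the ROI channels, epochs
(−1, 1) s about ripple peaks, and a −1.0 to −0.5 s baseline (earlier than
the spindle-scale events being sought). The surrogate control circularly
shifts a subject's entire ripple train by one uniform offset, preserving
event count and circular inter-event structure exactly.

Phase analyses band-pass at a center ± 1 Hz, take the analytic phase
(0 = peak, ±π = trough — phase estimates are only interpretable relative
to a stated convention, so it is fixed here and used consistently by the
generator, detector and estimators), and count
each ripple into every one of 50 bins (centers −π + (k+½)·2π/50) whose
center lies within ±22.5° circularly. The per-subject dominant phase is
the circular mean of ripple phases (argmax-bin available as an option).
Group comparisons use the Watson–Williams F with the 1 + 3/(8κ̂)
correction, κ̂ from the standard piecewise ML approximation, with a
warning when the pooled resultant length is below 0.45.

In/out-of-spindle density divides ripple counts by sample counts inside
spindle bouts vs the 1 s flanks before and after each bout, with flank
samples that fall inside any other bout excluded. The spindle-locked
likelihood test epochs each subject's summed ripple series around bout
onsets, circularly shifts each subject's series independently 1000 times,
averages shifted series across subjects, and reports the pointwise
two-tailed empirical exceedance (rank-based, with the +1 correction; a
Gaussian-KDE tail estimate is available as an option). Measured type-I
error at α = 0.05 is ~0.05–0.06.

## Behavior statistics

Hit rate = % target responses on targets, false alarms = % target
responses on standards, per subject × session × N; a response between one
onset and the next is attributed to that stimulus. The two-way ANOVA
(motion × N, subjects as replicates, interaction included, error df
N·6 − 6) is computed closed-form for the balanced design — the surrogate
null re-fits it thousands of times, which rules out a regression-package
round trip; the implementation is verified against statsmodels'
`anova_lm` to machine precision in the tests. The surrogate null jointly
permutes all subject × condition values across participants and both
factors, and p is the fraction of surrogate F at or above the observed F;
measured type-I error is within [0.03, 0.07] at α = 0.05. Paired
PA-vs-rest contrasts use α/3 (three N levels); the between-load
correlation matrix uses α/6 (six pairs, printed threshold 0.0083).
Reaction times are generated and stored but no RT statistics are
computed.

## Problem sizes

The test suite and the acceptance script run scaled-down versions of the
full study: cohorts of 8–21 subjects, one to three 40–60-trial blocks per
session, 4–12 magnetometers and 4–6 EEG channels, and 200–1000 surrogates
depending on the stage. These sizes were chosen so that each stage's
effect is identifiable with comfortable statistical margin at desk scale;
the defaults embedded in `SimConfig` remain the full-study values
(500 Hz, 102 magnetometers + 30 EEG channels, 12 × 100 trials, 30 targets
per block).

## Known limitations

* Detection operates directly on synthetic sensor signals; Maxwell
  filtering, ICA artifact removal and visual inspection — which real MEG
  would need upstream — are out of scope, as is downsampling (data are
  generated at 500 Hz).
* The dominance criterion is anchored to flanking peaks (see above); on
  data whose bursts arrive in rapid trains, this rejects closely packed
  events by design.
* The false-event rate on pure 1/f noise (~0.04/s per channel) sets a
  floor on achievable precision at low true-event rates; analyses that
  pool across sensors should restrict to the top-likelihood sensors.
* Watson–Williams assumes von-Mises samples with adequate, similar
  concentration; the implementation warns rather than refuses when the
  pooled resultant is low, and the warning should be taken seriously.
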
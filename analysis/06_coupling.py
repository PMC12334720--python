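"""Ripple-to-spindle coupling: phase locking, density, timing.

Four analyses per session over the cohort: (1) ripple-centered low-frequency
EEG averages against shift-surrogate controls, (2) ripple-phase histograms
in the spindle band with per-subject dominant phases and a Watson-Williams
comparison of sessions, (3) ripple density inside vs outside detected
spindle bouts, (4) spindle-onset-locked ripple likelihood with pointwise
surrogate p-values. Writes results/coupling.json.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import MASTER_SEED, get_cohort  # noqa: E402

from wakeripples.coupling import (  # noqa: E402
    group_phase_comparison,
    in_out_spindle_density,
    peri_spindle_ripple_series,
    phase_series,
    ripple_centered_eeg,
    ripple_phase_histogram,
    shift_surrogate,
    spindle_locked_likelihood,
)
from wakeripples.io import write_summary  # noqa: E402
from wakeripples.ripples import (  # noqa: E402
    detect_ripples,
    events_to_series,
    sensor_likelihood_map,
    select_top_sensors,
)
from wakeripples.spindles import detect_spindle_events  # noqa: E402
import scipy.stats as st  # noqa: E402

RESULTS = Path(__file__).parent.parent / "results"
BAND_CENTER = 15.0


def main():
    cohort = get_cohort()
    rng = np.random.default_rng(MASTER_SEED)
    dominant = {"rest": [], "PA": []}
    densities = {"rest": [], "PA": []}
    rs_peak = {"observed": [], "surrogate": []}
    peri, peri_times = [], None

    for subj in cohort:
        for sess, data in subj.sessions.items():
            rec, gt = data.recording, data.ground_truth
            fs = rec.sample_rate
            meg = rec.pick_modality("MEG")
            events = detect_ripples(meg)
            lmap = sensor_likelihood_map(events, gt.stim_onsets.size,
                                         meg.channel_labels)
            top = select_top_sensors(lmap, meg.channel_labels, 4)
            times = np.array(sorted(e.peak_time for e in events
                                    if e.channel in top))
            if times.size == 0:
                continue
            # (1) ripple-centered EEG vs a time-shifted surrogate
            rs = ripple_centered_eeg(rec, times, roi=["Fz", "Cz"])
            sur_times = shift_surrogate(times, rec.duration, rng)
            rs_sur = ripple_centered_eeg(rec, sur_times, roi=["Fz", "Cz"])
            core = np.abs(rs.times) <= 0.05
            rs_peak["observed"].append(np.abs(rs.trace[core]).max())
            rs_peak["surrogate"].append(np.abs(rs_sur.trace[core]).max())
            # (2) spindle-band ripple-phase histogram
            phases = phase_series(rec.pick(["Fz"]), BAND_CENTER, 2.0)[0]
            hist = ripple_phase_histogram(phases, times, fs, BAND_CENTER)
            dominant[sess].append(hist.dominant_phase)
            # (3) in/out-of-spindle density
            spindles = detect_spindle_events(rec, roi=["Fz", "Cz"])
            series = events_to_series(events, rec.n_samples, fs, top)
            if spindles:
                d = in_out_spindle_density(series, spindles, fs,
                                           session=sess)
                densities[sess].append((d.n_in, d.n_out))
                # (4) peri-spindle ripple series (PA only, where coupling
                # is strong)
                if sess == "PA":
                    onsets = np.array([e.start_time for e in spindles])
                    peri_times, p_series = peri_spindle_ripple_series(
                        series, onsets, fs)
                    peri.append(p_series)

    group = group_phase_comparison(
        {s: np.asarray(v) for s, v in dominant.items()})
    print("dominant spindle-band phase of ripples "
          f"(0 = peak, +/-pi = trough):")
    for s in ("rest", "PA"):
        print(f"  {s}: group mean {group.group_means[s]:+.2f} rad "
              f"(n={len(dominant[s])})")
    print(f"  Watson-Williams F={group.ww_F:.2f} p={group.ww_p:.3f}")

    io_stats = {}
    for s in ("rest", "PA"):
        arr = np.asarray(densities[s])
        t, p = st.ttest_rel(arr[:, 0], arr[:, 1])
        io_stats[s] = {"n_in": float(arr[:, 0].mean()),
                       "n_out": float(arr[:, 1].mean()),
                       "t": float(t), "p": float(p)}
        print(f"in/out density {s}: N_in={io_stats[s]['n_in']:.4f} "
              f"N_out={io_stats[s]['n_out']:.4f} t={t:.2f} p={p:.3f}")

    locked = spindle_locked_likelihood(peri, peri_times,
                                       n_surrogates=1000,
                                       seed=MASTER_SEED)
    sig = locked.p_values < 0.01
    t_first = (float(locked.times[sig & (locked.times > 0)][0])
               if np.any(sig & (locked.times > 0)) else None)
    print(f"spindle-locked ripple likelihood: min p="
          f"{locked.p_values.min():.4f}; first post-onset p<0.01 at "
          f"{t_first} s")
    t_rs, p_rs = st.ttest_rel(rs_peak["observed"], rs_peak["surrogate"])
    print(f"ripple-centered EEG |z| peak vs surrogate: t={t_rs:.2f} "
          f"p={p_rs:.3f}")

    write_summary({
        "dominant_phases": {s: np.asarray(v) for s, v in dominant.items()},
        "group_means": group.group_means,
        "watson_williams": {"F": group.ww_F, "p": group.ww_p},
        "in_out_density": io_stats,
        "spindle_locked": {"times": np.round(locked.times, 3),
                           "observed": np.round(locked.observed, 4),
                           "p_values": np.round(locked.p_values, 4),
                           "first_significant_s": t_first},
        "ripple_centered_eeg": {"t": float(t_rs), "p": float(p_rs)},
    }, RESULTS / "coupling.json")
    print(f"wrote {RESULTS / 'coupling.json'}")


if __name__ == "__main__":
    main()
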
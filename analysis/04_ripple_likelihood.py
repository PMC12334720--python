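"""Stimulus-locked ripple likelihood R(t) and its behavioral correlates.

Builds each subject's 200 ms moving-window ripple-rate time course around
stimulus onsets (summed over the top-4 sensors, z-scored to the 200 ms
pre-stimulus baseline), locates the post-stimulus suppression and rebound,
correlates window means with hit rate across subjects, and tests the
per-subject scaling of ripple counts with N-back load in each session.
Writes results/likelihood.json.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import get_cohort  # noqa: E402

from wakeripples.behavior import score_behavior  # noqa: E402
from wakeripples.io import write_summary  # noqa: E402
from wakeripples.ripples import (  # noqa: E402
    compare_nback_scaling,
    detect_ripples,
    likelihood_performance_correlation,
    mean_likelihood_in_window,
    nback_scaling,
    sensor_likelihood_map,
    select_top_sensors,
    stimulus_locked_likelihood,
)

RESULTS = Path(__file__).parent.parent / "results"
EARLY, LATE = (0.0, 1.0), (1.5, 2.5)


def main():
    cohort = get_cohort()
    curves, late_means, hit_rates = [], [], []
    nback_rates = {"rest": [], "PA": []}
    for subj in cohort:
        subj_hits, subj_late = [], []
        for sess, data in subj.sessions.items():
            rec, gt = data.recording, data.ground_truth
            meg = rec.pick_modality("MEG")
            events = detect_ripples(meg)
            lmap = sensor_likelihood_map(events, gt.stim_onsets.size,
                                         meg.channel_labels)
            top = select_top_sensors(lmap, meg.channel_labels, 4)
            series = stimulus_locked_likelihood(
                events, gt.stim_onsets, top, rec.n_samples, rec.sample_rate)
            curves.append(series.rate)
            subj_late.append(mean_likelihood_in_window(series, LATE))
            scores = score_behavior(data.trials)
            subj_hits.append(scores.hit_rate.mean())
            # ripple counts per N-back level for the load-scaling analysis
            trial_n = data.trials.groupby("trial_index")["n_back"].first()
            onset_n = trial_n.to_numpy()
            counts = {2: 0, 3: 0, 4: 0}
            trials_per_n = {n: (onset_n == n).sum() for n in (2, 3, 4)}
            soa = np.diff(gt.stim_onsets).mean()
            for e in events:
                if e.channel not in top:
                    continue
                k = int((e.peak_time - gt.stim_onsets[0]) // soa)
                if 0 <= k < onset_n.size:
                    counts[onset_n[k]] += 1
            nback_rates[sess].append([counts[n] / max(trials_per_n[n], 1)
                                      for n in (2, 3, 4)])
        hit_rates.append(np.mean(subj_hits))
        late_means.append(np.mean(subj_late))

    mean_curve = np.mean(curves, axis=0)
    times = series.times
    t_min = times[np.argmin(np.where((times > 0.1) & (times < 1.4),
                                     mean_curve, np.inf))]
    t_max = times[np.argmax(np.where((times > 1.0) & (times < 2.52),
                                     mean_curve, -np.inf))]
    r_late, p_late = likelihood_performance_correlation(late_means,
                                                        hit_rates)
    scaling = {s: nback_scaling(np.asarray(v)) for s, v in
               nback_rates.items()}
    t_sc, p_sc = compare_nback_scaling(scaling["rest"], scaling["PA"])

    print(f"R(t): suppression trough at {t_min:.2f} s, rebound peak at "
          f"{t_max:.2f} s after stimulus onset")
    print(f"late-window likelihood vs hit rate: rank r={r_late:.2f} "
          f"(p={p_late:.3f}, n={len(hit_rates)})")
    for s in ("rest", "PA"):
        print(f"N-back scaling {s}: mean r="
              f"{np.tanh(scaling[s].subject_z.mean()):.2f} "
              f"(one-sided p={scaling[s].p_value:.3f})")
    print(f"PA vs rest scaling: t={t_sc:.2f} p={p_sc:.3f}")

    write_summary({
        "times": np.round(times, 3),
        "mean_curve": np.round(mean_curve, 4),
        "suppression_trough_s": t_min, "rebound_peak_s": t_max,
        "late_window_rank_r": r_late, "late_window_p": p_late,
        "nback_scaling": {
            s: {"mean_r": float(np.tanh(v.subject_z.mean())),
                "p_one_sided": v.p_value}
            for s, v in scaling.items()},
        "pa_vs_rest_scaling": {"t": t_sc, "p": p_sc},
    }, RESULTS / "likelihood.json")
    print(f"wrote {RESULTS / 'likelihood.json'}")


if __name__ == "__main__":
    main()
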
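"""Detect ripples across the cohort; topography and top-sensor selection.

Per-session detection on all magnetometers, sensor likelihood maps, the
pairwise between-subject topography consistency (Fisher-transformed and
compared PA vs rest), and the four most ripple-dense sensors per subject.
Writes scratch/ripple_events.tsv and results/topography.json.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import get_cohort  # noqa: E402

from wakeripples.io import write_summary, write_table  # noqa: E402
from wakeripples.ripples import (  # noqa: E402
    compare_topography_sessions,
    detect_ripples,
    events_to_frame,
    sensor_likelihood_map,
    select_top_sensors,
    topography_consistency,
)

RESULTS = Path(__file__).parent.parent / "results"
SCRATCH = Path(__file__).parent.parent / "scratch"


def main():
    cohort = get_cohort()
    frames, maps, tops = [], {"rest": [], "PA": []}, {}
    for subj in cohort:
        for sess, data in subj.sessions.items():
            meg = data.recording.pick_modality("MEG")
            events = detect_ripples(meg)
            frames.append(events_to_frame(events, subj.subject_id, sess))
            lmap = sensor_likelihood_map(
                events, data.ground_truth.stim_onsets.size,
                meg.channel_labels)
            maps[sess].append(lmap)
            tops[(subj.subject_id, sess)] = select_top_sensors(
                lmap, meg.channel_labels, 4)
    events = pd.concat(frames)
    # full event table is bulky; it goes to scratch, the summary to results
    write_table(events, SCRATCH / "ripple_events.tsv")

    res_rest = topography_consistency(np.asarray(maps["rest"]))
    res_pa = topography_consistency(np.asarray(maps["PA"]))
    t, p = compare_topography_sessions(res_rest, res_pa)

    print(f"{len(events)} ripple events across "
          f"{len(cohort)} subjects x 2 sessions")
    print(f"mean duration {events.duration_s.mean() * 1000:.1f} ms, "
          f"mean peak z {events.peak_z.mean():.2f}")
    print(f"topography pairs: {res_rest.pair_r.size} per session; "
          f"mean r rest={res_rest.pair_r.mean():.2f} "
          f"PA={res_pa.pair_r.mean():.2f} (paired t={t:.2f}, p={p:.3f})")
    designated = set(cohort[0].sessions["rest"]
                     .ground_truth.ripple_times.keys())
    hitrate = np.mean([len(designated & set(v)) / 4 for v in tops.values()])
    print(f"top-4 sensor selection recovers {100 * hitrate:.0f}% of the "
          f"designated ripple sensors")

    write_summary({
        "n_events": len(events),
        "mean_duration_ms": events.duration_s.mean() * 1000,
        "n_pairs": int(res_rest.pair_r.size),
        "mean_r_rest": res_rest.pair_r.mean(),
        "mean_r_pa": res_pa.pair_r.mean(),
        "session_t": t, "session_p": p,
        "top_sensors": {f"{k[0]}_{k[1]}": v for k, v in tops.items()},
        "top_sensor_recovery": hitrate,
    }, RESULTS / "topography.json")
    print(f"wrote {RESULTS / 'topography.json'}")


if __name__ == "__main__":
    main()
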
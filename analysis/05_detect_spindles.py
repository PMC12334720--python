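"""Wake-spindle amplitude time course and discrete spindle events.

The 14-18 Hz envelope around stimulus onsets (z-scored to the pre-stimulus
baseline) gives the task-locked spindle amplitude; its 1-2 s window mean is
contrasted PA vs rest across subjects. Discrete 13-20 Hz bouts are detected
per session. Writes scratch/spindle_events.tsv and
results/spindle_stats.json.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import get_cohort  # noqa: E402

from wakeripples.io import write_summary, write_table  # noqa: E402
from wakeripples.spindles import (  # noqa: E402
    detect_spindle_events,
    mean_in_window,
    spindle_amplitude_timecourse,
    spindle_session_contrast,
)

RESULTS = Path(__file__).parent.parent / "results"
SCRATCH = Path(__file__).parent.parent / "scratch"


def main():
    cohort = get_cohort()
    roi = ["Fz", "Cz", "FC1", "FC2"]
    window_means = {"rest": [], "PA": []}
    rows = []
    for subj in cohort:
        for sess, data in subj.sessions.items():
            rec, gt = data.recording, data.ground_truth
            times, course = spindle_amplitude_timecourse(
                rec, gt.stim_onsets, roi=roi)
            window_means[sess].append(mean_in_window(times, course,
                                                     (1.0, 2.0)))
            for e in detect_spindle_events(rec, roi=roi):
                rows.append({
                    "subject": subj.subject_id, "session": sess,
                    "channel": e.channel, "start_s": e.start_time,
                    "center_s": e.center_time, "end_s": e.end_time,
                    "duration_s": e.duration, "peak_z": e.peak_z})
    events = pd.DataFrame(rows)
    write_table(events, SCRATCH / "spindle_events.tsv")

    t, p = spindle_session_contrast(np.asarray(window_means["PA"]),
                                    np.asarray(window_means["rest"]))
    print(f"{len(events)} spindle events; mean duration "
          f"{events.duration_s.mean():.2f} s, mean peak z "
          f"{events.peak_z.mean():.1f}")
    print(f"1-2 s spindle amplitude, PA vs rest: t={t:.2f} p={p:.3f} "
          f"(PA mean {np.mean(window_means['PA']):.2f}, rest "
          f"{np.mean(window_means['rest']):.2f})")
    write_summary({
        "n_events": len(events),
        "mean_duration_s": events.duration_s.mean(),
        "window_mean_pa": float(np.mean(window_means["PA"])),
        "window_mean_rest": float(np.mean(window_means["rest"])),
        "contrast_t": t, "contrast_p": p,
    }, RESULTS / "spindle_stats.json")
    print(f"wrote {RESULTS / 'spindle_stats.json'}")


if __name__ == "__main__":
    main()
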
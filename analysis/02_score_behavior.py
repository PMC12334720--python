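"""Score N-back behavior and run the session/load statistics.

Hit and false-alarm rates per subject x session x N; two-way surrogate
ANOVA (motion x N-back) and Bonferroni-corrected paired PA-vs-rest
contrasts. Writes results/behavior_scores.tsv and results/behavior_stats.json.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import MASTER_SEED, get_cohort  # noqa: E402

from wakeripples.behavior import (  # noqa: E402
    paired_contrasts,
    rates_to_table,
    score_behavior,
    surrogate_anova,
)
from wakeripples.io import write_summary, write_table  # noqa: E402

RESULTS = Path(__file__).parent.parent / "results"


def main():
    cohort = get_cohort()
    trials = pd.concat([data.trials
                        for subj in cohort
                        for data in subj.sessions.values()])
    summary = score_behavior(trials)
    write_table(summary, RESULTS / "behavior_scores.tsv")

    table = rates_to_table(summary)
    by_n = table.mean(axis=(0, 1))
    anova = surrogate_anova(table, n_iter=1000, seed=MASTER_SEED)
    contrasts = paired_contrasts(table)

    print(f"hit rate by N: 2-back {by_n[0]:.1f}%  3-back {by_n[1]:.1f}%  "
          f"4-back {by_n[2]:.1f}%")
    print(f"PA {table[:, 1, :].mean():.1f}%  rest "
          f"{table[:, 0, :].mean():.1f}%")
    print(f"ANOVA: F_motion={anova.f_motion:.2f} (surrogate "
          f"p={anova.p_motion:.3f}), F_nback={anova.f_nback:.2f} "
          f"(p={anova.p_nback:.3f})")
    print(f"paired PA-rest: t={contrasts.t_overall:.2f} "
          f"p={contrasts.p_overall:.4f} (threshold "
          f"{contrasts.threshold:.4f})")

    write_summary({
        "hit_rate_by_n": by_n,
        "hit_rate_pa": table[:, 1, :].mean(),
        "hit_rate_rest": table[:, 0, :].mean(),
        "fa_rate_mean": float(np.nanmean(rates_to_table(summary,
                                                        "fa_rate"))),
        "anova": {"f_motion": anova.f_motion, "p_motion": anova.p_motion,
                  "f_nback": anova.f_nback, "p_nback": anova.p_nback,
                  "n_iter": anova.n_iter},
        "contrasts": {"t_overall": contrasts.t_overall,
                      "p_overall": contrasts.p_overall,
                      "per_n_p": contrasts.p_per_n,
                      "threshold": contrasts.threshold},
    }, RESULTS / "behavior_stats.json")
    print(f"wrote {RESULTS / 'behavior_stats.json'}")


if __name__ == "__main__":
    main()
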
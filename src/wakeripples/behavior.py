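"""N-back scoring and the surrogate-calibrated two-way ANOVA.

Hit rate H is the percentage of target responses on target trials; false
alarms FA the percentage of target responses on standards, per
subject x session x N. The two-way ANOVA (factors: motion PA/rest and
N-back level) is evaluated against a surrogate null built by jointly
shuffling the subject x condition cell values across participants and
conditions, which sidesteps sphericity/normality assumptions. Paired PA-rest
contrasts use a Bonferroni-corrected threshold of alpha / n_comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st


def score_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit and false-alarm rates (%) per subject x session x N.

    Cells without targets (or without standards) get NaN and are flagged in
    the `missing` column.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    rows = []
    grouped = trials.groupby(["subject", "session", "n_back"], sort=True)
    for (subj, sess, n), g in grouped:
        targets = g[g["is_target"]]
        standards = g[~g["is_target"]]
        h = (100.0 * (targets["response"] == "target").mean()
             if len(targets) else np.nan)
        fa = (100.0 * (standards["response"] == "target").mean()
              if len(standards) else np.nan)
        rows.append({"subject": subj, "session": sess, "n_back": int(n),
                     "hit_rate": h, "fa_rate": fa,
                     "n_targets": len(targets),
                     "n_standards": len(standards),
                     "missing": len(targets) == 0 or len(standards) == 0})
    return pd.DataFrame(rows)


def rates_to_table(summary: pd.DataFrame, value: str = "hit_rate"
                   ) -> np.ndarray:
    """Pivot a score table to (n_subjects, 2 sessions [rest, PA], 3 N-levels)."""
    subjects = sorted(summary["subject"].unique())
    table = np.full((len(subjects), 2, 3), np.nan)
    for si, subj in enumerate(subjects):
        for mi, sess in enumerate(["rest", "PA"]):
            for ni, n in enumerate([2, 3, 4]):
                cell = summary[(summary["subject"] == subj)
                               & (summary["session"] == sess)
                               & (summary["n_back"] == n)]
                if len(cell):
                    table[si, mi, ni] = cell[value].iloc[0]
    return table


# --------------------------------------------------------------------------
# balanced two-way ANOVA (closed form) and the surrogate null
# --------------------------------------------------------------------------

def twoway_f(table: np.ndarray) -> tuple[float, float]:
    """F statistics (motion, N-back) of a balanced two-way ANOVA.

    table is (n_subjects, n_motion, n_nback); subjects are the replicates,
    the model includes both main effects and their interaction, so the error
    degrees of freedom are N - a*b.
    """
    table = np.asarray(table, float)
    n, a, b = table.shape
    grand = table.mean()
    m_a = table.mean(axis=(0, 2))       # motion level means
    m_b = table.mean(axis=(0, 1))       # N-back level means
    m_ab = table.mean(axis=0)           # cell means
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_e = np.sum((table - m_ab[None]) ** 2)
    df_a, df_b, df_e = a - 1, b - 1, n * a * b - a * b
    ms_e = ss_e / df_e
    if ms_e == 0:
        return 0.0, 0.0
    return float((ss_a / df_a) / ms_e), float((ss_b / df_b) / ms_e)


@dataclass
class SurrogateAnovaResult:
    f_motion: float
    f_nback: float
    p_motion: float
    p_nback: float
    n_iter: int


def surrogate_anova(table: np.ndarray, n_iter: int = 1000,
                    seed: int | np.random.Generator = 0
                    ) -> SurrogateAnovaResult:
    """Two-way ANOVA with surrogate p-values from joint cell shuffling.

    The null distribution is built by randomly permuting the full set of
    subject x motion x N values across participants and both conditions in
    each of n_iter iterations; p is the fraction of surrogate F at or above
    the observed F.
    """
    if n_iter < 100:
        warnings.warn(f"only {n_iter} surrogate iterations; p is coarse",
                      stacklevel=2)
    table = np.asarray(table, float)
    if np.isnan(table).any():
        raise ValueError("table has missing cells")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    f_m, f_n = twoway_f(table)
    flat = table.ravel()
    count_m = count_n = 0
    for _ in range(n_iter):
        perm = rng.permutation(flat).reshape(table.shape)
        sm, sn = twoway_f(perm)
        count_m += sm >= f_m
        count_n += sn >= f_n
    return SurrogateAnovaResult(
        f_motion=f_m, f_nback=f_n,
        p_motion=count_m / n_iter, p_nback=count_n / n_iter,
        n_iter=n_iter)


# --------------------------------------------------------------------------
# paired PA-vs-rest contrasts
# --------------------------------------------------------------------------

@dataclass
class PairedContrasts:
    t_overall: float
    p_overall: float
    t_per_n: dict[int, float]
    p_per_n: dict[int, float]
    alpha: float
    threshold: float            # Bonferroni-corrected level
    significant: dict[int, bool]


def paired_contrasts(table: np.ndarray, alpha: float = 0.05,
                     n_comparisons: int = 3,
                     n_levels: tuple[int, ...] = (2, 3, 4)
                     ) -> PairedContrasts:
    """Paired t-tests PA vs rest, overall and per N, Bonferroni-corrected.

    table is (n_subjects, 2, 3) ordered [rest, PA] x [2, 3, 4].
    """
    table = np.asarray(table, float)
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    threshold = alpha / n_comparisons
    rest, pa = table[:, 0, :], table[:, 1, :]
    t_all, p_all = st.ttest_rel(pa.mean(axis=1), rest.mean(axis=1))
    t_n, p_n, sig = {}, {}, {}
    for ni, n in enumerate(n_levels):
        t, p = st.ttest_rel(pa[:, ni], rest[:, ni])
        t_n[n], p_n[n] = float(t), float(p)
        sig[n] = bool(p < threshold)
    return PairedContrasts(t_overall=float(t_all), p_overall=float(p_all),
                           t_per_n=t_n, p_per_n=p_n, alpha=alpha,
                           threshold=threshold, significant=sig)
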
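"""Shared desk-scale cohort definition for the analysis scripts.

One paired (rest / physical-activity) cohort, deterministic under the
master seed. Relative to a full recording session this is scaled down --
8 subjects, one 50-trial block, 6 magnetometers + 5 EEG channels -- so each
driver runs in seconds; the coupling parameters differ between sessions
(physical activity strengthens ripple-to-spindle phase locking), which is
the effect the downstream analyses should recover.
"""

from wakeripples.simulate import SimConfig, simulate_cohort

MASTER_SEED = 11
N_SUBJECTS = 8

COHORT_CONFIG = SimConfig(
    seed=MASTER_SEED,
    n_blocks=3,
    trials_per_block=50,
    targets_per_block=15,
    n_channels_meg=6,
    n_channels_eeg=5,
    spindle_rate=0.08,
    coupling_mu=3.14159,
    coupling_kappa=1.0,          # weak locking at rest
    p_ripple_in_spindle=0.5,
)

# physical activity: stronger phase locking and a small behavioral benefit
PA_OVERRIDES = {"coupling_kappa": 4.0, "p_ripple_in_spindle": 0.7}


def get_cohort():
    return simulate_cohort(N_SUBJECTS, COHORT_CONFIG,
                           pa_overrides=PA_OVERRIDES,
                           ability_rate_coupling=0.5)
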
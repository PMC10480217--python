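"""Shared settings for the numbered analysis scripts.

One synthetic cohort mirrors the study's group sizes (12 PD-like, 20
dystonia-like subjects); each script regenerates it deterministically from
COHORT_SEED, so the scripts can run independently and still describe the
same cohort. Nights are 30 min long — long enough for every stage-resolved
estimator to have dozens of epochs, short enough that each script runs in
well under a minute.
"""

from pathlib import Path

from pallidal_sleep import synthetic as syn

COHORT_SEED = 20230905
N_PD = 12
N_DYST = 20
NIGHT_SECONDS = 30 * 60.0

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_cohort() -> syn.CohortBundle:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return syn.generate_cohort(N_PD, N_DYST, seed=COHORT_SEED, total_time=NIGHT_SECONDS)
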
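"""Sleep-architecture comparison between the two synthetic groups.

Unlike the signal-heavy scripts, sleep parameters need only hypnograms and
chin EMG, so this script uses full-length nights (the generator profile
defaults: ~8 h, long sleep latency and dense wake intrusions for the
PD-like group). It computes the per-night parameter table (TTB, TST, WASO,
SL, RSL, stage percentages, SE, fragmentation count, RSWA%) on the
consensus hypnograms and compares groups with the two-sided Mann-Whitney U
test. Writes results/sleep_parameters.csv and
results/sleep_parameter_tests.csv.
"""

import numpy as np
import pandas as pd

from common import COHORT_SEED, N_DYST, N_PD, RESULTS
from pallidal_sleep import sleep_metrics as sm
from pallidal_sleep import staging
from pallidal_sleep import synthetic as syn
from pallidal_sleep.stats import mann_whitney_u, table_summary, tidy_results

EMG_RATE = 200.0  # Hz; enough for the 10-70 Hz chin-EMG band


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(COHORT_SEED)
    rows = []
    for diagnosis, n, hp_fn, emg_fn in (
        ("PD", N_PD, syn.pd_like_hypnogram_params, syn.pd_like_emg_profile),
        ("dystonia", N_DYST, syn.dystonia_like_hypnogram_params, syn.dystonia_like_emg_profile),
    ):
        for i in range(n):
            seed = int(rng.integers(2**31 - 1))
            h, _ = syn.generate_hypnogram(hp_fn(), seed)
            h2 = syn._relabel(h, 0.144, np.random.default_rng(seed + 1))
            ch = staging.consensus(h, h2)
            profile = emg_fn()
            profile.sample_rate = EMG_RATE
            emg, _ = syn.generate_emg(h, profile, seed + 2)
            # sleep parameters from the primary hypnogram; the consensus only
            # decides REM eligibility (enough agreeing REM epochs)
            h1 = staging.hypnogram_as_consensus(h)
            params = sm.parameters_with_extras(
                h1, emg, h1 if staging.rem_eligible(ch) else None
            )
            rows.append({
                "subject_id": f"{diagnosis}-{i + 1}", "diagnosis": diagnosis,
                **params.as_dict(),
            })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "sleep_parameters.csv", index=False)

    tests = {}
    print(f"{'parameter':<8} {'PD median (IQR)':>20} {'dystonia median (IQR)':>24} {'P':>8}")
    for col in ("TTB", "TST", "WASO", "SL", "RSL", "N1pct", "N2pct", "N3pct",
                "Rpct", "SE", "Sfrag", "RSWA"):
        x = table[table.diagnosis == "PD"][col].dropna()
        y = table[table.diagnosis == "dystonia"][col].dropna()
        mp, ip = table_summary(table, col, "PD")
        md, idq = table_summary(table, col, "dystonia")
        if len(x) > 1 and len(y) > 1 and (x.nunique() > 1 or y.nunique() > 1):
            tests[col] = mann_whitney_u(x, y)
            p = f"{tests[col].p_value:.3f}"
        else:
            p = "--"
        print(f"{col:<8} {mp:>12.1f} ({ip:.1f}) {md:>16.1f} ({idq:.1f}) {p:>8}")
    tidy_results(tests).to_csv(RESULTS / "sleep_parameter_tests.csv", index=False)
    print(f"\nwrote {RESULTS / 'sleep_parameters.csv'}")


if __name__ == "__main__":
    main()
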
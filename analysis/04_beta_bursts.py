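"""Per-Hz beta-burst analysis with a cohort-level threshold.

Pools the z-scored Morlet envelopes of every subject and stage to set the
per-frequency-bin 75th-percentile threshold, detects bursts (>= 0.1 s),
and compares mean burst duration between the groups per stage. Writes
results/burst_stats.csv and results/burst_tests.csv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, load_cohort
from pallidal_sleep import bursts, staging
from pallidal_sleep.stats import mann_whitney_u, tidy_results


def main() -> None:
    bundle = load_cohort()
    keyed, pool = [], []
    for s in bundle.subjects:
        ch = staging.consensus(s.hypnogram, s.hypnogram2)
        ep = staging.epoch_signal(s.lfp, ch)
        for stage in ("W", "NREM", "R"):
            parts = ep.epochs(stage)
            if not parts:
                continue
            x = np.concatenate(parts)
            if x.size < s.lfp.sample_rate * 60:
                continue
            env = bursts.envelope_bank(x, s.lfp.sample_rate)
            pool.append(env)
            keyed.append((s.subject_id, s.diagnosis, stage, env))

    thr = bursts.cohort_threshold(pool)
    rows = []
    for sid, diag, stage, env in keyed:
        per_bin = [
            bursts.burst_stats(
                bursts.detect_bursts(env[i], float(thr[i]), frequency_bin=f),
                env.shape[-1] / bursts.BURST_RATE,
            )
            for i, f in enumerate(bursts.BETA_BIN_FREQS)
        ]
        st = bursts.average_over_bins(per_bin)
        rows.append({
            "subject_id": sid, "diagnosis": diag, "stage": stage,
            "mean_duration": st.mean_duration, "mean_auc": st.mean_auc,
            "density": st.density,
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "burst_stats.csv", index=False)

    tests = {}
    for stage in ("W", "NREM", "R"):
        sub = table[table.stage == stage]
        for metric in ("mean_duration", "mean_auc", "density"):
            x = sub[sub.diagnosis == "PD"][metric].dropna()
            y = sub[sub.diagnosis == "dystonia"][metric].dropna()
            if len(x) > 1 and len(y) > 1:
                tests[f"{metric}_{stage}"] = mann_whitney_u(x, y)
    results = tidy_results(tests)
    results.to_csv(RESULTS / "burst_tests.csv", index=False)

    for stage in ("W", "NREM", "R"):
        sub = table[table.stage == stage]
        pd_d = sub[sub.diagnosis == "PD"]["mean_duration"].median()
        dy_d = sub[sub.diagnosis == "dystonia"]["mean_duration"].median()
        key = f"mean_duration_{stage}"
        p = results[results.comparison == key]["p"].squeeze() if key in tests else float("nan")
        print(f"{stage:<5} mean burst duration: PD {pd_d:.3f} s vs dystonia {dy_d:.3f} s (P = {p:.4f})")
    print(f"\nwrote {RESULTS / 'burst_stats.csv'}")


if __name__ == "__main__":
    main()
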
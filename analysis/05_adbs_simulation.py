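"""Adaptive-DBS controller simulation over every synthetic night.

For each subject: 5-s/0.5-s sliding normalized beta, Gaussian smoothing,
threshold at the median awake beta, the 0-3 V / 0.4 V/s ramp controller,
stimulation-on time per stage, and the Friedman comparison of NREM beta and
ON time across the four sleep quarters. Writes results/stim_on.csv and
results/quarter_tests.csv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, load_cohort
from pallidal_sleep import adbs, staging


def main() -> None:
    bundle = load_cohort()
    rows, beta_quarters, on_quarters = [], [], []
    for s in bundle.subjects:
        ch = staging.consensus(s.hypnogram, s.hypnogram2)
        series = adbs.sliding_beta(s.lfp.data[0], s.lfp.sample_rate)
        wake = adbs.stage_mask(series.times, ch, "W")
        if not wake.any():
            continue
        thr = adbs.awake_threshold(series.beta[wake])
        trace = adbs.simulate_controller(series, adbs.ControllerConfig(threshold=thr))
        row = {"subject_id": s.subject_id, "diagnosis": s.diagnosis, "threshold": thr}
        for stage in ("W", "NREM", "R"):
            row[f"stim_on_{stage}"] = adbs.stim_on_fraction(trace, ch, stage)
        rows.append(row)
        nrem = adbs.stage_mask(series.times, ch, "NREM")
        if nrem.sum() >= 4:
            beta_quarters.append(adbs.quarter_values(series.beta, nrem))
            on_quarters.append(adbs.quarter_values(trace.stim_on.astype(float), nrem))
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "stim_on.csv", index=False)

    qrows = []
    for name, mat in (("nrem_beta", beta_quarters), ("nrem_on_time", on_quarters)):
        res = adbs.quarter_analysis(np.array(mat))
        qrows.append({"measure": name, "statistic": res.statistic, "p": res.p_value})
        print(f"Friedman across NREM quarters, {name}: Q = {res.statistic:.2f}, P = {res.p_value:.3f}")
    pd.DataFrame(qrows).to_csv(RESULTS / "quarter_tests.csv", index=False)

    for grp in ("PD", "dystonia"):
        sub = table[table.diagnosis == grp]
        print(
            f"{grp}: median stimulation-on time "
            f"wake {sub['stim_on_W'].median():.1f}%, "
            f"NREM {sub['stim_on_NREM'].median():.1f}%, "
            f"REM {sub['stim_on_R'].median():.1f}%"
        )
    print(f"\nwrote {RESULTS / 'stim_on.csv'}")


if __name__ == "__main__":
    main()
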
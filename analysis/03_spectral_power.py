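"""Stage-resolved normalized spectra and theta/beta group comparisons.

For every subject: per-epoch Welch spectra on the consensus-kept epochs,
percent-power normalization, stage averages (wake, pooled NREM, REM), band
powers, and the 1/f-adjusted beta. Groups are compared per stage with the
Mann-Whitney U test. Writes results/band_powers.csv,
results/spectral_tests.csv and results/stage_spectra.csv.
"""

import pandas as pd

from common import RESULTS, load_cohort
from pallidal_sleep import spectral, staging
from pallidal_sleep.pipeline import RunConfig, run_subject
from pallidal_sleep.stats import mann_whitney_u, tidy_results


def main() -> None:
    bundle = load_cohort()
    cfg = RunConfig(run_bursts=False, run_adbs=False)
    rows, spec_rows = [], []
    for s in bundle.subjects:
        rep = run_subject(s, cfg)
        row = {"subject_id": s.subject_id, "diagnosis": s.diagnosis}
        for stage, powers in rep.band_powers.items():
            for band, v in powers.items():
                row[f"{band}_{stage}"] = v
        for stage, v in rep.adjusted_beta.items():
            row[f"adjbeta_{stage}"] = v
        rows.append(row)
        ch = staging.consensus(s.hypnogram, s.hypnogram2)
        ep = staging.epoch_signal(s.lfp, ch)
        for stage, spec in spectral.stage_spectra(ep).items():
            for f, p in zip(spec.freqs, spec.power):
                spec_rows.append(
                    {"subject_id": s.subject_id, "stage": stage, "frequency": f, "power": p}
                )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "band_powers.csv", index=False)
    pd.DataFrame(spec_rows).to_csv(RESULTS / "stage_spectra.csv", index=False)

    tests = {}
    for col in ("theta_W", "beta_W", "theta_NREM", "beta_NREM", "theta_R", "beta_R",
                "adjbeta_W", "adjbeta_NREM", "adjbeta_R"):
        if col not in table:
            continue
        x = table[table.diagnosis == "PD"][col].dropna()
        y = table[table.diagnosis == "dystonia"][col].dropna()
        if len(x) and len(y):
            tests[col] = mann_whitney_u(x, y)
    results = tidy_results(tests)
    results.to_csv(RESULTS / "spectral_tests.csv", index=False)

    for _, r in results.iterrows():
        direction = ""
        col = r["comparison"]
        pd_med = table[table.diagnosis == "PD"][col].median()
        dy_med = table[table.diagnosis == "dystonia"][col].median()
        direction = "PD > dystonia" if pd_med > dy_med else "PD < dystonia"
        print(f"{col:<14} {direction:<14} P = {r['p']:.4f}")
    print(f"\nwrote {RESULTS / 'band_powers.csv'}")


if __name__ == "__main__":
    main()
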
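"""Clinical-table statistics and the beta <-> sleep-quality correlations.

Part 1 reproduces the summary statistics of the bundled per-patient clinical
table (group medians; Spearman correlation between PSQI and RBDSQ in the PD
group). Part 2 computes, on the synthetic cohort, the correlation matrix
between stage-resolved beta power, the off-medication motor score, and the
PSQI — the injected monotone PSQI <-> NREM-beta link should surface as a
significant positive cell. Writes results/clinical_summary.csv and
results/correlation_matrix.csv.
"""

import pandas as pd

from common import RESULTS, load_cohort
from pallidal_sleep.clinical import clinical_summary, load_clinical_table
from pallidal_sleep.pipeline import cohort_band_table
from pallidal_sleep.stats import correlation_matrix, table_summary


def main() -> None:
    df = load_clinical_table()
    summary = clinical_summary(df)
    pd.DataFrame([summary]).to_csv(RESULTS / "clinical_summary.csv", index=False)
    print("bundled clinical table:")
    print(f"  disease duration median: PD {summary['pd_disease_duration_median']:.1f} y, "
          f"dystonia {summary['dystonia_disease_duration_median']:.1f} y")
    print(f"  PD RBDSQ median {summary['pd_rbdsq_median']:.1f}; "
          f"dystonia PSQI median {summary['dystonia_psqi_median']:.1f}")
    print(f"  PD motor score median off/on: {summary['pd_motor_off_median']:.1f} / "
          f"{summary['pd_motor_on_median']:.1f}")
    print(f"  Spearman PSQI~RBDSQ (PD): rho = {summary['psqi_rbdsq_rho']:.3f}, "
          f"P = {summary['psqi_rbdsq_p']:.3f}")

    bundle = load_cohort()
    tab = cohort_band_table(bundle)
    pd_rows = tab[tab.diagnosis == "PD"]
    cols = [c for c in ("beta_W", "beta_NREM", "beta_R", "psqi", "motor_off") if c in tab]
    rho, p, flags = correlation_matrix(pd_rows[cols])
    rho.to_csv(RESULTS / "correlation_matrix.csv")
    p.to_csv(RESULTS / "correlation_matrix_p.csv")
    print("\nsynthetic PD-like group, Spearman rho (PSQI column):")
    for c in cols:
        if c != "psqi":
            star = " *" if flags.loc[c, "psqi"] else ""
            print(f"  {c:<10} rho = {rho.loc[c, 'psqi']:+.2f} (P = {p.loc[c, 'psqi']:.3f}){star}")
    print(f"\nwrote {RESULTS / 'correlation_matrix.csv'}")


if __name__ == "__main__":
    main()
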
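"""The bundled per-patient clinical table and its summary statistics.

The fixture holds the published per-patient demographics of the two GPi-DBS
cohorts (12 Parkinson's disease, 20 dystonia): nights recorded, disease
duration (years), PSQI (0-21), RBDSQ (0-13, PD only), and pre-operative
motor scores (MDS-UPDRS-III off/on medication for PD; TWSTRS or BFMDRS for
cervical/oromandibular dystonia — score scales differ by subtype, so
dystonia motor scores are summarized per subtype only).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import spearman, table_summary


def load_clinical_table() -> pd.DataFrame:
    """The bundled clinical table as a DataFrame (one row per subject)."""
    with resources.files("pallidal_sleep.data").joinpath("clinical_table.csv").open() as fh:
        df = pd.read_csv(fh)
    bad = set(df["diagnosis"]) - {"PD", "dystonia"}
    if bad:
        raise ValueError(f"unexpected diagnosis labels {bad}")
    if not df["psqi"].between(0, 21).all():
        raise ValueError("PSQI outside its 0-21 range")
    return df


def clinical_summary(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Headline clinical statistics: group medians and the PSQI-RBDSQ link."""
    df = load_clinical_table() if df is None else df
    pd_rows = df[df["diagnosis"] == "PD"]
    link = spearman(pd_rows["psqi"], pd_rows["rbdsq"])
    out = {
        "pd_disease_duration_median": table_summary(df, "disease_duration", "PD")[0],
        "dystonia_disease_duration_median": table_summary(df, "disease_duration", "dystonia")[0],
        "pd_psqi_median": table_summary(df, "psqi", "PD")[0],
        "dystonia_psqi_median": table_summary(df, "psqi", "dystonia")[0],
        "pd_rbdsq_median": table_summary(df, "rbdsq", "PD")[0],
        "pd_motor_off_median": table_summary(df, "motor_off", "PD")[0],
        "pd_motor_on_median": table_summary(df, "motor_on", "PD")[0],
        "psqi_rbdsq_rho": link.rho,
        "psqi_rbdsq_p": link.p_value,
    }
    return out
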
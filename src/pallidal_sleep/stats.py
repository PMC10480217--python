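"""Nonparametric cohort statistics: Mann-Whitney, Kruskal-Wallis, Friedman,
Spearman with tie handling, Bonferroni correction, and median/IQR summaries.

All tests are two-sided. The Mann-Whitney test uses exact enumeration when
the combined sample is small (n1 + n2 <= 12) and tie-free, and the
tie-corrected normal approximation otherwise. Quantiles (median, IQR) use
linear interpolation (type-7), which matters for small-sample IQRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str
    rho: float | None = None


def _clean(x) -> np.ndarray:
    a = np.asarray(x, float).ravel()
    return a[~np.isnan(a)]


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for combined n <= 12 without ties; tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if x.size + y.size <= EXACT_MAX_N and no_ties:
        res = sst.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "mann-whitney-exact"
    else:
        res = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "mann-whitney-asymptotic"
    return TestResult(float(res.statistic), float(res.pvalue), (x.size, y.size), method)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties), two-sided t-based P."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("Spearman correlation needs >= 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = sst.spearmanr(x, y)
    return TestResult(float(rho), float(p), (x.size,), "spearman", rho=float(rho))


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test over >= 2 groups."""
    groups = [_clean(g) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if np.unique(np.concatenate(groups)).size == 1:
        # all values identical: no rank variation
        return TestResult(0.0, 1.0, tuple(g.size for g in groups), "kruskal-wallis")
    stat, p = sst.kruskal(*groups)
    return TestResult(float(stat), float(p), tuple(g.size for g in groups), "kruskal-wallis")


def friedman(block_matrix) -> TestResult:
    """Tie-corrected Friedman test; blocks are rows, treatments columns.

    A matrix with no within-block rank variation (e.g. constant) has
    statistic 0 and P = 1 by convention.
    """
    m = np.atleast_2d(np.asarray(block_matrix, float))
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test needs >= 2 blocks and >= 2 treatments")
    ranks = sst.rankdata(m, axis=1)
    if np.all(np.ptp(ranks, axis=1) == 0):
        return TestResult(0.0, 1.0, (n,) * k, "friedman")
    with np.errstate(invalid="ignore"):
        stat, p = sst.friedmanchisquare(*[m[:, j] for j in range(k)])
    if np.isnan(stat):
        return TestResult(0.0, 1.0, (n,) * k, "friedman")
    return TestResult(float(stat), float(p), (n,) * k, "friedman")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m*p)."""
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def table_summary(records: pd.DataFrame, column: str, group: str | None = None) -> tuple[float, float]:
    """Median and IQR (Q3 - Q1, type-7 quantiles) of one clinical column.

    *group*, if given, filters on the ``diagnosis`` column. All-missing
    input yields (nan, nan).
    """
    df = records if group is None else records[records["diagnosis"] == group]
    vals = _clean(df[column])
    if vals.size == 0:
        return (np.nan, np.nan)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(q3 - q1)


def correlation_matrix(df: pd.DataFrame, alpha: float = 0.05):
    """Pairwise Spearman rho/P over complete pairs of the DataFrame columns.

    Returns ``(rho, p, flagged)`` DataFrames; cells with fewer than 3
    complete pairs are NaN, and ``flagged`` marks P < alpha.
    """
    cols = list(df.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                rho[i, j] = 1.0
                pmat[i, j] = 0.0
                continue
            x, y = df[cols[i]].to_numpy(float), df[cols[j]].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.unique(x[ok]).size == 1 or np.unique(y[ok]).size == 1:
                continue
            r = spearman(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r.rho
            pmat[i, j] = pmat[j, i] = r.p_value
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols)
    return rho_df, p_df, p_df < alpha


def tidy_results(results: dict[str, TestResult], m_correction: int | None = None) -> pd.DataFrame:
    """Tidy (comparison, statistic, p, p_adjusted) table from named tests."""
    rows = []
    ps = np.array([r.p_value for r in results.values()])
    adj = bonferroni(ps, m_correction or len(ps)) if len(ps) else ps
    for (name, r), pa in zip(results.items(), adj):
        rows.append(
            {"comparison": name, "method": r.method, "statistic": r.statistic,
             "p": r.p_value, "p_adjusted": float(pa)}
        )
    return pd.DataFrame(rows)
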
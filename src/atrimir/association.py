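"""Pearson correlation of miRNA vs gene abundance, and linear age trends.

Correlations are computed on logCPM values across the 12 samples; the exact
two-sided p-value uses the t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2
degrees of freedom.  Age trends are ordinary least squares of logCPM on age
in years, with t-based 95% confidence bounds on the slope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix


def pearson_r(x, y) -> float:
    """Product-moment correlation; constant input is an error (undefined r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def pearson_p(r: float, n: int) -> float:
    """Exact two-sided p for a correlation coefficient at sample size n.

    p = 2 * P(T_{n-2} >= |r| sqrt(n-2) / sqrt(1-r^2)).  |r| = 1 returns 0.0
    (the t statistic is infinite).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def correlate_all(
    mirna_expr: ExpressionMatrix, gene_expr: ExpressionMatrix
) -> pd.DataFrame:
    """All (miRNA, gene) Pearson correlations with exact p-values.

    Both matrices must cover the identical samples; gene columns are aligned
    to the miRNA sample order before computing.  Output is ordered by miRNA
    id then gene id, one row per pair, with columns
    ``mirna, gene, r, n, p_cor``.  Constant features (zero variance) are an
    error: correlation against them is undefined.
    """
    if set(mirna_expr.sample_ids) != set(gene_expr.sample_ids):
        raise ValueError("miRNA and gene matrices cover different samples")
    samples = mirna_expr.sample_ids
    M = mirna_expr.values[samples].to_numpy(dtype=float)
    G = gene_expr.values[samples].to_numpy(dtype=float)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 shared samples")

    def standardize(A: np.ndarray, kind: str) -> np.ndarray:
        Ac = A - A.mean(axis=1, keepdims=True)
        norm = np.sqrt((Ac * Ac).sum(axis=1, keepdims=True))
        if np.any(norm == 0):
            bad = np.flatnonzero(norm[:, 0] == 0)[:5]
            raise ValueError(f"constant {kind} feature(s) at rows {bad.tolist()}")
        return Ac / norm

    R = np.clip(standardize(M, "miRNA") @ standardize(G, "gene").T, -1.0, 1.0)
    mirna_ids = np.array(mirna_expr.feature_ids)
    gene_ids = np.array(gene_expr.feature_ids)
    mi_order = np.argsort(mirna_ids, kind="stable")
    g_order = np.argsort(gene_ids, kind="stable")
    R = R[np.ix_(mi_order, g_order)]
    with np.errstate(divide="ignore"):
        t = np.abs(R) * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - R * R, 0.0))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[np.abs(R) == 1.0] = 0.0
    return pd.DataFrame(
        {
            "mirna": np.repeat(mirna_ids[mi_order], len(gene_ids)),
            "gene": np.tile(gene_ids[g_order], len(mirna_ids)),
            "r": R.ravel(),
            "n": n,
            "p_cor": p.ravel(),
        }
    )


def linear_trend(expr, ages) -> dict:
    """OLS of expression on age with a 95% CI on the slope (t, df = n-2)."""
    expr = np.asarray(expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if expr.size != ages.size or expr.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; trend undefined")
    fit = stats.linregress(ages, expr)
    tq = stats.t.ppf(0.975, df=expr.size - 2)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "ci_low": fit.slope - tq * fit.stderr,
        "ci_high": fit.slope + tq * fit.stderr,
        "p_trend": fit.pvalue,
    }


def trend_table(expr: ExpressionMatrix, sample_table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature linear age trend for every row of an expression matrix."""
    ages = sample_table.set_index("sample_id").loc[expr.sample_ids, "age"].to_numpy()
    rows = []
    for fid in expr.feature_ids:
        res = linear_trend(expr.values.loc[fid].to_numpy(), ages)
        rows.append({"feature": fid, **res})
    return pd.DataFrame(rows)
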
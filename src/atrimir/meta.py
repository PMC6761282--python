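"""Fisher's-method meta-analysis of the two contrasts, BH FDR and selection.

Each feature carries a p-value from each of the two reciprocal contrasts
(older vs younger).  Fisher's statistic -2 * sum(ln p) is referred to a
chi-square with 2k degrees of freedom (k = number of contrasts, here 2, so
df = 4), the combined p-values are adjusted by Benjamini-Hochberg, and
age-associated features are selected either on nominal per-contrast
significance (the miRNA path) or on the meta FDR (the gene path), requiring
direction consistency in both cases.  Direction-discordant features that pass
every other filter are reported separately, never silently merged or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds for calling a feature age-associated."""

    nominal_p: float = 0.05
    fdr_cut: float = 0.05
    require_consistency: bool = True

    def __post_init__(self) -> None:
        for name in ("nominal_p", "fdr_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def fisher_combine(pvalues) -> tuple[float, float]:
    """Combine independent p-values: stat = -2 * sum(ln p), p ~ chi2(2k).

    p-values of exactly 0 (underflow upstream) are floored at 1e-300 with a
    warning; p > 1 or p < 0 is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0.0):
        logger.warning("fisher_combine: zero p-value floored at %g", _P_FLOOR)
        p = np.maximum(p, _P_FLOOR)
    stat = float(-2.0 * np.sum(np.log(p)))
    return stat, float(stats.chi2.sf(stat, df=2 * p.size))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(p > 1.0) or np.any(p < 0.0) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


def _sign_char(x: float) -> str:
    if x == 0:
        logger.warning("zero logFC treated as '+' for direction")
    return "-" if x < 0 else "+"


def build_meta_table(de: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine the two contrast p-values of an aligned two-set DE table.

    Input must carry columns ``feature, logFC1, pvalue1, logFC2, pvalue2``
    (extra columns pass through).  Adds ``direction`` (two sign characters),
    ``fisher_stat``, ``p_fisher``, ``fdr`` (BH over all rows) and
    ``consistent``.  Rows with a missing (non-converged) p-value are dropped
    with a logged count before combining.
    """
    out = de.copy()
    bad = out["pvalue1"].isna() | out["pvalue2"].isna()
    if bad.any():
        logger.info("meta: dropping %d features with missing p-values", int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    p1 = out["pvalue1"].to_numpy()
    p2 = out["pvalue2"].to_numpy()
    p = np.maximum(np.column_stack([p1, p2]), _P_FLOOR)
    fisher_stat = -2.0 * np.log(p).sum(axis=1)
    out["direction"] = [
        _sign_char(a) + _sign_char(b) for a, b in zip(out["logFC1"], out["logFC2"])
    ]
    out["fisher_stat"] = fisher_stat
    out["p_fisher"] = stats.chi2.sf(fisher_stat, df=4)
    out["fdr"] = bh_adjust(out["p_fisher"].to_numpy())
    out["consistent"] = out["direction"].isin(["++", "--"])
    return out


def select_aa_features(
    records: pd.DataFrame,
    rule: SelectionRule = SelectionRule(),
    mode: str = "nominal_both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select age-associated features from a meta table.

    mode ``nominal_both`` (the miRNA path) keeps rows with both per-contrast
    p-values below ``rule.nominal_p``; mode ``fdr_meta`` (the gene path) keeps
    rows with meta ``fdr`` below ``rule.fdr_cut``.  With
    ``rule.require_consistency`` the main list keeps direction-consistent rows
    only, and rows passing every other filter with discordant directions are
    returned as the second ("discordant") table.

    Returns ``(selected, discordant)``.
    """
    if mode == "nominal_both":
        passing = (records["pvalue1"] < rule.nominal_p) & (records["pvalue2"] < rule.nominal_p)
    elif mode == "fdr_meta":
        passing = records["fdr"] < rule.fdr_cut
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    hits = records[passing]
    if rule.require_consistency:
        selected = hits[hits["consistent"]].reset_index(drop=True)
        discordant = hits[~hits["consistent"]].reset_index(drop=True)
    else:
        selected = hits.reset_index(drop=True)
        discordant = hits.iloc[0:0].reset_index(drop=True)
    logger.info(
        "selection (%s): %d in, %d selected, %d discordant",
        mode, len(records), len(selected), len(discordant),
    )
    return selected, discordant
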
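"""Chromosome-level expression aggregation.

Pools the unified matrix's log2 ratios by chromosome, splits them into
positive and negative parts before averaging (activation vs.
deactivation relative to control), and correlates gene counts per
chromosome with the signed mean expression across the early (4 h) and
late (72 h) treatment scopes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chromosome_means", "chromosome_profile_table", "correlate_counts_expression"]

SCOPE_EXPERIMENTS = {"all": ("1", "2", "3", "4", "5"), "4h": ("1", "2", "3"), "72h": ("4", "5")}


def chromosome_means(
    matrix: pd.DataFrame,
    chromosome_map: dict,
    scope: str = "all",
) -> pd.DataFrame:
    """Per-chromosome gene count and signed mean expression.

    M values are pooled over the scope's experiment columns for all
    genes on each chromosome; means of the strictly positive and
    strictly negative values are reported separately (zeros count in
    neither).  Chromosomes with no positive (negative) values get NaN
    for that mean.  Unmapped genes are dropped with a logged count.
    """
    if scope not in SCOPE_EXPERIMENTS:
        raise ValueError(f"scope must be one of {sorted(SCOPE_EXPERIMENTS)}")
    cols = [c for c in matrix.columns if str(c) in SCOPE_EXPERIMENTS[scope]]
    if not cols:
        raise ValueError(f"no experiment columns in scope {scope!r}")
    mapped = matrix.index.isin(chromosome_map.keys())
    n_drop = int((~mapped).sum())
    if n_drop:
        logging.getLogger(__name__).info(
            "chromosome_means: %d genes without chromosome dropped", n_drop
        )
    sub = matrix.loc[mapped, cols]
    chrom = pd.Series({g: chromosome_map[g] for g in sub.index}, name="chromosome")
    rows = []
    for c in sorted(chrom.unique(), key=str):
        vals = sub.loc[chrom[chrom == c].index].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        pos = vals[vals > 0]
        neg = vals[vals < 0]
        rows.append(
            {
                "chromosome": c,
                "gene_count": int((chrom == c).sum()),
                "m_pos": float(pos.mean()) if pos.size else np.nan,
                "m_neg": float(neg.mean()) if neg.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("chromosome")


def chromosome_profile_table(
    matrix: pd.DataFrame, chromosome_map: dict
) -> pd.DataFrame:
    """Wide per-chromosome table over all three scopes, ready for the
    correlation analysis: gene_count, m_pos/all, m_neg/all, m_pos/4h,
    m_neg/4h, m_pos/72h, m_neg/72h."""
    base = chromosome_means(matrix, chromosome_map, "all")
    out = base[["gene_count"]].copy()
    for scope in ("all", "4h", "72h"):
        prof = chromosome_means(matrix, chromosome_map, scope)
        out[f"m_pos/{scope}"] = prof["m_pos"]
        out[f"m_neg/{scope}"] = prof["m_neg"]
    return out


def correlate_counts_expression(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation (r and two-sided p) of the
    per-chromosome columns, pairwise-complete over NaN means.

    Columns with fewer than 3 paired finite values, or zero variance,
    yield NaN for the affected pairs.
    """
    cols = list(profiles.columns)
    n_def = profiles.notna().sum()
    if int((n_def >= 3).sum()) < 1 or len(profiles) < 3:
        raise ValueError("at least 3 chromosomes with defined values required")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x = profiles[a].to_numpy(dtype=float)
            y = profiles[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rv, pv = np.nan, np.nan
            else:
                res = stats.pearsonr(x[ok], y[ok])
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p
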
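"""Gene-level covariates and covariate-controlled comparisons.

Nearest-gene essentiality (from knockout-phenotype vocabularies), nearest-gene
expression (mean — or maximum — signal over a 61-tissue compendium, binned at
<200, 200-400, >=400), and the contrasts that control enhancer-rate comparisons
for these covariates: tissue-specific enhancers only, compared within each
expression bin.
"""

from __future__ import annotations

import logging
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .gbgc import compare_groups

logger = logging.getLogger(__name__)

ESSENTIAL_TERMS = frozenset({"premature_death", "infertility"})
EXPRESSION_BIN_EDGES = (200.0, 400.0)
EXPRESSION_BIN_LABELS = ("<200", "200-400", ">=400")

_EXACT_PERM_MAX_N = 10
_T_APPROX_MIN_N = 30


def classify_essentiality(phenotype_terms) -> str:
    """'essential' if any knockout phenotype is premature death or infertility;
    'non-essential' if the gene has at least one other documented null
    phenotype; 'unknown' when no null phenotype is documented."""
    terms = set(phenotype_terms)
    if terms & ESSENTIAL_TERMS:
        return "essential"
    if terms:
        return "non-essential"
    return "unknown"


def expression_bin(value: float) -> str:
    """Bin edges [0,200), [200,400), [400,inf); 400 belongs to the top bin."""
    if value < EXPRESSION_BIN_EDGES[0]:
        return EXPRESSION_BIN_LABELS[0]
    if value < EXPRESSION_BIN_EDGES[1]:
        return EXPRESSION_BIN_LABELS[1]
    return EXPRESSION_BIN_LABELS[2]


def expression_summary(signals, mode: str = "mean") -> tuple[float, str]:
    """Summarize a gene's per-tissue expression signals and bin the summary.

    ``mode='mean'`` averages over all tissues (the default definition);
    ``mode='max'`` takes the maximum signal (the robustness variant). Missing
    signals (NaN) are ignored; all-missing input raises ValueError.
    """
    x = np.asarray(signals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no non-missing expression signal")
    if mode == "mean":
        value = float(x.mean())
    elif mode == "max":
        value = float(x.max())
    else:
        raise ValueError("mode must be 'mean' or 'max'")
    return value, expression_bin(value)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value: exact permutation enumeration for n <= 10, scipy's exact/
    t-approximation policy in between, t-approximation for n > 30. Constant
    input is undefined and raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= _EXACT_PERM_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def _exact_spearman_p(x, y, rho_obs) -> float:
    """Two-sided exact p by full enumeration of pairings of y against x."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    sx, sy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    count = total = 0
    obs = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        r = float(sx @ sy[list(perm)]) / denom
        total += 1
        if abs(r) >= obs:
            count += 1
    return count / total


def covariate_table(
    regions_df: pd.DataFrame,
    gene_covariates: pd.DataFrame,
    expression_mode: str = "mean",
) -> pd.DataFrame:
    """Join each region to its *adjacent* (nearest) gene's covariates.

    ``gene_covariates`` needs gene_id, essentiality in {essential,
    non-essential, unknown}, and expr_* signal columns. Adds columns
    essentiality, expression, expression_bin to the region table.
    """
    expr_cols = [c for c in gene_covariates.columns if c.startswith("expr_")]
    summaries = {}
    for row in gene_covariates.itertuples(index=False):
        signals = [getattr(row, c) for c in expr_cols]
        try:
            value, bin_ = expression_summary(signals, mode=expression_mode)
        except ValueError:
            value, bin_ = np.nan, None
        summaries[row.gene_id] = (row.essentiality, value, bin_)
    out = regions_df.copy()
    joined = out["nearest_gene_id"].map(
        lambda g: summaries.get(g, ("unknown", np.nan, None))
    )
    out["essentiality"] = [j[0] for j in joined]
    out["expression"] = [j[1] for j in joined]
    out["expression_bin"] = [j[2] for j in joined]
    return out


def _first_tissue(label: str) -> str:
    return str(label).split(",")[0]


def controlled_comparison(
    covariates_df: pd.DataFrame,
    rate_columns: tuple = ("D", "ratio"),
    specific_only: bool = True,
) -> pd.DataFrame:
    """Pairwise tissue contrasts of enhancer rates within each expression bin.

    Controls both confounders at once: pleiotropy, by keeping only specific
    enhancers (whose tissue set is a single label), and adjacent-gene
    expression, by stratifying into the three bins before every contrast.
    Returns one row per (metric, bin, tissue pair), plus per-group medians.
    Empty bin x tissue cells are skipped and logged.
    """
    df = covariates_df
    if specific_only:
        df = df[df["pleiotropy"] == "specific"]
    df = df[df["expression_bin"].notna()]
    rows = []
    for metric in rate_columns:
        if metric not in df.columns:
            continue
        for bin_label, sub in df.groupby("expression_bin"):
            groups = {
                _first_tissue(t): g[metric].dropna().to_numpy()
                for t, g in sub.groupby(sub["tissues"].map(_first_tissue))
            }
            groups = {k: v for k, v in groups.items() if len(v) > 0}
            if len(groups) < 2:
                logger.info("bin %s: fewer than two tissues with data, skipped", bin_label)
                continue
            table = compare_groups(groups)
            table.insert(0, "metric", metric)
            table.insert(1, "expression_bin", bin_label)
            rows.append(table)
    if not rows:
        return pd.DataFrame(
            columns=["metric", "expression_bin", "group_a", "group_b", "p_value"]
        )
    return pd.concat(rows, ignore_index=True)


def bin_medians(covariates_df: pd.DataFrame, metric: str = "ratio", specific_only: bool = True) -> pd.DataFrame:
    """Median of ``metric`` per (expression bin, tissue) — the grid the
    controlled comparison summarizes."""
    df = covariates_df
    if specific_only:
        df = df[df["pleiotropy"] == "specific"]
    df = df[df["expression_bin"].notna()]
    rows = []
    for (bin_label, tissue), grp in df.groupby(
        ["expression_bin", df["tissues"].map(_first_tissue)]
    ):
        vals = grp[metric].dropna()
        rows.append(
            {
                "expression_bin": bin_label,
                "tissue": tissue,
                "n": len(vals),
                "median": float(vals.median()) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def contingency_chi2(counts: pd.DataFrame) -> tuple[float, float]:
    """Generic 2xk (or rxk) contingency chi-square for composition contrasts."""
    res = stats.chi2_contingency(np.asarray(counts))
    return float(res.statistic), float(res.pvalue)
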
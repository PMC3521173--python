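"""Neutral-reference normalization (D/d4, D/di) and per-enhancer Fisher's-exact
selection classification.

Each testable enhancer contributes a 2x2 table: rows are the enhancer and its
neutral reference (fourfold or intronic sites of the nearest orthologous gene),
columns are substituted vs unsubstituted sites. A two-sided exact test at
alpha = 0.05 classifies the enhancer: significant excess of substitutions
relative to neutral -> positive selection; significant deficit -> purifying
selection; otherwise neutrality cannot be rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
#: relative gate for "as or less probable" when summing point probabilities,
#: guarding against ties lost to floating-point rounding
_REL_GATE = 1.0 + 1e-7


@dataclass
class NormalizedRate:
    region_id: str
    D: float
    d_neutral: float
    reference_kind: str  # 'd4' | 'di'

    @property
    def ratio(self) -> float:
        return self.D / self.d_neutral


@dataclass
class SelectionCall:
    region_id: str
    neutral_reference: str  # 'fourfold' | 'intron'
    table: tuple  # (enh_diff, enh_same, neut_diff, neut_same)
    p_value: float
    direction: str  # 'enhancer_enriched' | 'enhancer_depleted' | 'none'
    call: str  # 'positive' | 'purifying' | 'neutral'


def normalize_divergence(D_est, d_est, kind: str) -> NormalizedRate | None:
    """D divided by the local neutral rate; None (logged) when unusable.

    A ratio below 1 indicates purifying constraint on the enhancer; above 1,
    acceleration relative to the neutral reference.
    """
    if kind not in ("d4", "di"):
        raise ValueError("kind must be 'd4' or 'di'")
    region_id = getattr(D_est, "region_id", "?")
    if not (D_est.converged and d_est.converged):
        logger.info("region %s: unconverged estimate, ratio skipped", region_id)
        return None
    if d_est.t <= 0:
        logger.info("region %s: neutral rate is zero, ratio undefined", region_id)
        return None
    return NormalizedRate(region_id, float(D_est.t), float(d_est.t), kind)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration.

    The p-value is the total probability, under fixed margins, of all tables
    as or less probable than the observed one (point probabilities compared
    with a tiny relative tolerance so exact ties are included).
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table counts must be nonnegative")
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or k == n:
        return 1.0
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = hypergeom.pmf(support, n, n1, k)
    p_obs = pmf[support.searchsorted(a)]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_GATE].sum()))


def fisher_classify(
    enh: tuple, neut: tuple, alpha: float = ALPHA_DEFAULT,
    region_id: str = "?", neutral_reference: str = "fourfold",
) -> SelectionCall:
    """Classify one enhancer from (n_diff, n_sites) of itself and its reference.

    positive  : p <= alpha and enhancer substitution proportion > neutral's
    purifying : p <= alpha and enhancer substitution proportion < neutral's
    neutral   : otherwise (the neutral model cannot be rejected)
    """
    enh_diff, enh_sites = (int(x) for x in enh)
    neut_diff, neut_sites = (int(x) for x in neut)
    if enh_sites <= 0 or neut_sites <= 0:
        raise ValueError("both rows need at least one site")
    if not (0 <= enh_diff <= enh_sites and 0 <= neut_diff <= neut_sites):
        raise ValueError("substituted-site counts exceed site counts or are negative")
    table = (enh_diff, enh_sites - enh_diff, neut_diff, neut_sites - neut_diff)
    p = fisher_exact_p(table)
    enh_prop = enh_diff / enh_sites
    neut_prop = neut_diff / neut_sites
    if p <= alpha and enh_prop > neut_prop:
        direction, call = "enhancer_enriched", "positive"
    elif p <= alpha and enh_prop < neut_prop:
        direction, call = "enhancer_depleted", "purifying"
    else:
        direction = (
            "enhancer_enriched" if enh_prop > neut_prop
            else "enhancer_depleted" if enh_prop < neut_prop
            else "none"
        )
        call = "neutral"
    return SelectionCall(region_id, neutral_reference, table, p, direction, call)


def run_selection_scan(
    regions_df: pd.DataFrame,
    divergence_df: pd.DataFrame,
    reference: str = "fourfold",
    alpha: float = ALPHA_DEFAULT,
    specific_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every testable enhancer and summarize per tissue.

    ``regions_df`` is the consolidated-region table; ``divergence_df`` holds one
    row per (unit_id, class) with columns unit_id, class in
    {enhancer, fourfold, intron}, t, n_sites, n_diff, converged. Enhancers are
    testable when (after the optional specific-only filter) their neutral
    reference gene has a converged divergence row with at least one usable
    site. A Benjamini-Hochberg q-value column is emitted for transparency but
    never drives the calls.

    Returns (per-enhancer calls frame, per-tissue summary frame).
    """
    if reference not in ("fourfold", "intron"):
        raise ValueError("reference must be 'fourfold' or 'intron'")
    div = divergence_df.set_index(["unit_id", "class"])
    rows = []
    regions = regions_df
    if specific_only:
        regions = regions[regions["pleiotropy"] == "specific"]
    for r in regions.itertuples(index=False):
        gene = r.neutral_reference_gene_id
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        try:
            enh_row = div.loc[(r.region_id, "enhancer")]
            neut_row = div.loc[(gene, reference)]
        except KeyError:
            continue
        if not (bool(enh_row.converged) and bool(neut_row.converged)):
            continue
        if enh_row.n_sites <= 0 or neut_row.n_sites <= 0:
            continue
        call = fisher_classify(
            (enh_row.n_diff, enh_row.n_sites),
            (neut_row.n_diff, neut_row.n_sites),
            alpha=alpha,
            region_id=r.region_id,
            neutral_reference=reference,
        )
        ratio = float(enh_row.t / neut_row.t) if neut_row.t > 0 else np.nan
        rows.append(
            {
                "region_id": r.region_id,
                "tissues": r.tissues,
                "reference": reference,
                "enh_diff": int(enh_row.n_diff),
                "enh_sites": int(enh_row.n_sites),
                "neut_diff": int(neut_row.n_diff),
                "neut_sites": int(neut_row.n_sites),
                "p_value": call.p_value,
                "call": call.call,
                "direction": call.direction,
                "D": float(enh_row.t),
                "d_neutral": float(neut_row.t),
                "ratio": ratio,
            }
        )
    calls = pd.DataFrame(rows)
    if len(calls):
        calls["q_value"] = multipletests(calls["p_value"], method="fdr_bh")[1]
    else:
        calls["q_value"] = pd.Series(dtype=float)
    return calls, summarize_calls(calls)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue counts and ratios: total testable, under selection, positive.

    A region consolidated from several tissues contributes to each of its
    tissues' rows (relevant only when pleiotropic regions are scanned).
    """
    rows = []
    tissues = sorted({t for lbl in calls.get("tissues", pd.Series(dtype=str)) for t in str(lbl).split(",")})
    for tissue in tissues:
        sub = calls[calls["tissues"].astype(str).str.split(",").apply(lambda ts: tissue in ts)]
        total = len(sub)
        under = int((sub["call"] != "neutral").sum())
        positive = int((sub["call"] == "positive").sum())
        rows.append(
            {
                "tissue": tissue,
                "total": total,
                "under_selection": under,
                "positive": positive,
                "under_over_total": under / total if total else np.nan,
                "positive_over_under": positive / under if under else np.nan,
                "positive_over_total": positive / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
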
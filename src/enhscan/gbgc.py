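"""GC-biased gene conversion diagnostics.

Mouse-lineage substitutions are polarized by outgroup parsimony on
mouse/rat/human columns: a site is "ancestrally A/T" when rat and human agree
on an A or a T; a mouse base differing from that ancestor is a mouse-lineage
substitution, split into A/T->G/C versus A/T->A/T. Regions enriched for
A/T->G/C substitutions and located in high-recombination windows are the
signature gBGC would leave; comparing these quantities across tissues tests
whether conversion bias, rather than selection, drives rate differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .divergence import collect_columns

logger = logging.getLogger(__name__)

NOT_ANCESTRAL_AT = "not_ancestral_AT"
NO_SUBSTITUTION = "no_substitution"
AT_TO_GC = "AT_to_GC"
AT_TO_AT = "AT_to_AT"
EXCLUDED = "excluded"

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class PolarityCounts:
    region_id: str
    n_substituted_AT: int
    n_AT_to_GC: int

    @property
    def ratio(self) -> float:
        """N_A/T->G/C over N_substituted A/T; NaN when no A/T substitution."""
        if self.n_substituted_AT == 0:
            return float("nan")
        return self.n_AT_to_GC / self.n_substituted_AT


def polarize_site(mouse: str, rat: str, human: str, strict: bool = True) -> str:
    """Category of one aligned mouse/rat/human column (case-insensitive).

    Strict reading (default): the ancestor is A/T only when rat and human carry
    the *same* A or T. The looser reading (``strict=False``) accepts any
    rat, human in {A, T} and takes the rat allele as the ancestor.
    """
    m, r, h = mouse.upper(), rat.upper(), human.upper()
    if any(b not in "ACGT" for b in (m, r, h)):
        return EXCLUDED
    if strict:
        if r != h or r not in "AT":
            return NOT_ANCESTRAL_AT
        ancestor = r
    else:
        if r not in "AT" or h not in "AT":
            return NOT_ANCESTRAL_AT
        ancestor = r
    if m == ancestor:
        return NO_SUBSTITUTION
    return AT_TO_GC if m in "GC" else AT_TO_AT


def polarize_columns(codes: np.ndarray, strict: bool = True) -> dict:
    """Vectorized polarization; ``codes`` is (3, n) mouse/rat/human base codes."""
    m, r, h = codes[0], codes[1], codes[2]
    valid = (codes < 4).all(axis=0)
    is_at = (r == _A) | (r == _T)
    if strict:
        anc_ok = valid & (r == h) & is_at
    else:
        anc_ok = valid & is_at & ((h == _A) | (h == _T))
    sub = anc_ok & (m != r)
    to_gc = sub & ((m == _G) | (m == _C))
    return {
        EXCLUDED: int((~valid).sum()),
        NOT_ANCESTRAL_AT: int((valid & ~anc_ok).sum()),
        NO_SUBSTITUTION: int((anc_ok & ~sub).sum()),
        AT_TO_GC: int(to_gc.sum()),
        AT_TO_AT: int((sub & ~to_gc).sum()),
    }


def polarity_for_region(region, alignments, strict: bool = True) -> PolarityCounts | None:
    """Sum site polarization over a region's three-species columns."""
    codes = collect_columns(
        alignments, region.chrom,
        np.arange(region.start, region.end, dtype=np.int64),
        ("mouse", "rat", "human"),
    )
    if codes.shape[1] == 0:
        logger.info("region %s: no three-species columns, skipped", region.region_id)
        return None
    cats = polarize_columns(codes, strict=strict)
    n_sub = cats[AT_TO_GC] + cats[AT_TO_AT]
    return PolarityCounts(region.region_id, n_sub, cats[AT_TO_GC])


def polarity_table(regions, alignments, strict: bool = True) -> pd.DataFrame:
    rows = []
    for r in regions:
        pc = polarity_for_region(r, alignments, strict=strict)
        if pc is None:
            continue
        rows.append(
            {
                "region_id": r.region_id,
                "tissues": r.tissue_label,
                "n_substituted_AT": pc.n_substituted_AT,
                "n_AT_to_GC": pc.n_AT_to_GC,
                "ratio": pc.ratio,
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Stars at the conventional thresholds: * 0.01<p<=0.05, ** 0.001<p<=0.01,
    *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_groups(values_by_group: dict, min_n: int = 1) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test for every pair of groups.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy). Pairs with an empty
    group are skipped. Returns one row per pair with medians, U, p and stars.
    """
    groups = {k: np.asarray([v for v in vals if np.isfinite(v)]) for k, vals in values_by_group.items()}
    rows = []
    for a, b in combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < min_n or len(xb) < min_n:
            logger.info("pair (%s, %s) skipped: empty group", a, b)
            continue
        res = mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "U": float(res.statistic),
                "p_value": float(res.pvalue),
                "stars": significance_stars(float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def group_quartiles(values_by_group: dict) -> pd.DataFrame:
    """Median and quartiles per group (the box-plot summary the figures use)."""
    rows = []
    for name in sorted(values_by_group):
        x = np.asarray([v for v in values_by_group[name] if np.isfinite(v)])
        if len(x) == 0:
            rows.append({"group": name, "n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan})
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append({"group": name, "n": len(x), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows)
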
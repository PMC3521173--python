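"""Maximum-likelihood substitution distances under GTR + discrete gamma.

``fit_pairwise`` estimates the expected number of substitutions per site t
between two aligned sequences; ``fit_triple`` estimates the three branch
lengths of the unrooted mouse/rat/human tree by Felsenstein pruning over the
rate categories. Applied to an enhancer span the distance is D; applied to a
gene's fourfold-degenerate or intronic site mask it is d4 or di.

Base frequencies are fixed to the empirical means of the aligned sequences
(never ML-optimized); exchangeabilities and the gamma shape are ML-fit when a
unit has enough usable sites, otherwise they are frozen at values fit on
pooled neutral data and only t is optimized (threshold configurable, default
200 sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import GTRModel
from .sites import SiteMask, project_mask_to_alignment

logger = logging.getLogger(__name__)

#: below this many usable sites, fall back to a pooled model and fit t only
FULL_FIT_MIN_SITES = 200

_T_BOUNDS = (1e-9, 10.0)
_ALPHA_BOUNDS = (0.05, 50.0)
_EXCH_BOUNDS = (1e-4, 1e4)
_T_STARTS = (0.05, 0.2, 1.0)  # fixed multi-start grid
_LL_TOL = 1e-8


class NoUsableSitesError(ValueError):
    """All alignment columns were gapped/ambiguous or the selection was empty."""


@dataclass
class PatternCounts:
    """Site-pattern sufficient statistics for 2 or 3 aligned sequences."""

    counts: np.ndarray  # (4,4) pairwise or (4,4,4) three-taxon
    n_sites: int
    n_diff: int
    n_excluded: int

    @property
    def n_species(self) -> int:
        return self.counts.ndim

    def empirical_frequencies(self) -> np.ndarray:
        """Base frequencies averaged over all aligned sequences."""
        c = self.counts
        axes = list(range(c.ndim))
        freq = np.zeros(4)
        for keep in axes:
            other = tuple(a for a in axes if a != keep)
            freq += c.sum(axis=other)
        freq /= freq.sum()
        return np.clip(freq, 1e-6, None) / np.clip(freq, 1e-6, None).sum()

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        if self.counts.shape != other.counts.shape:
            raise ValueError("cannot pool pattern counts of different arity")
        return PatternCounts(
            self.counts + other.counts,
            self.n_sites + other.n_sites,
            self.n_diff + other.n_diff,
            self.n_excluded + other.n_excluded,
        )


def count_site_patterns(column_codes: np.ndarray) -> PatternCounts:
    """Tally nucleotide site patterns from stacked base codes.

    ``column_codes`` has shape (n_species, n_columns) with A,C,G,T as 0..3 and
    anything else (ambiguity, gap) > 3. Columns containing any non-ACGT code
    are excluded and counted in ``n_excluded``.
    """
    codes = np.asarray(column_codes)
    if codes.ndim != 2 or codes.shape[0] not in (2, 3):
        raise ValueError("expected (n_species in {2,3}, n_columns) array")
    ok = (codes < 4).all(axis=0)
    kept = codes[:, ok]
    n_excluded = int(codes.shape[1] - kept.shape[1])
    n_species = codes.shape[0]
    flat = np.zeros(kept.shape[1], dtype=np.int64)
    for row in kept:
        flat = flat * 4 + row
    counts = np.bincount(flat, minlength=4**n_species).reshape((4,) * n_species)
    n_sites = int(kept.shape[1])
    same = kept == kept[0]
    n_diff = int(n_sites - same.all(axis=0).sum())
    return PatternCounts(counts.astype(np.float64), n_sites, n_diff, n_excluded)


@dataclass
class DivergenceEstimate:
    t: float
    model: GTRModel
    n_sites: int
    n_diff: int
    converged: bool
    log_likelihood: float

    def standard_error(self) -> float:
        """SE of t from the likelihood curvature at the optimum, conditional
        on the fitted substitution model.

        Caveat: when the gamma shape is estimated jointly from the same single
        pairwise alignment, t and the shape trade off along a nearly flat
        likelihood ridge, and the marginal uncertainty of t can be much larger
        than this conditional value. Distances used for D/d ratios in the
        pipeline are fit with a shared (pooled) model, where this SE applies.
        """
        if self.n_sites == 0 or self.t <= _T_BOUNDS[0]:
            return float("nan")
        if getattr(self, "_ll", None) is None:
            return float("nan")
        h = max(1e-5, 1e-3 * self.t)
        ll = self._ll
        d2 = (ll(self.t + h) - 2.0 * ll(self.t) + ll(self.t - h)) / h**2
        return float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")


@dataclass
class TripleEstimate:
    branch_lengths: dict  # species -> substitutions/site
    model: GTRModel
    n_sites: int
    n_diff: int
    converged: bool
    log_likelihood: float

    @property
    def mouse_rat_distance(self) -> float:
        return self.branch_lengths["mouse"] + self.branch_lengths["rat"]


# ------------------------------------------------------------ likelihoods --

def _pairwise_loglik(counts: np.ndarray, model: GTRModel, t: float) -> float:
    pmats = model.transition_matrices(t)  # (K,4,4)
    mix = pmats.mean(axis=0)
    joint = model.base_frequencies[:, None] * mix
    return float(np.sum(counts * np.log(joint)))


def _triple_loglik(counts: np.ndarray, model: GTRModel, tm: float, tr: float, th: float) -> float:
    pi = model.base_frequencies
    pm = model.transition_matrices(tm)
    pr = model.transition_matrices(tr)
    ph = model.transition_matrices(th)
    mix = np.einsum("a,kax,kay,kaz->xyz", pi, pm, pr, ph) / model.n_categories
    return float(np.sum(counts * np.log(np.clip(mix, 1e-300, None))))


# ------------------------------------------------------------------ fits ---

def _t_only_fit(counts, model, loglik):
    res = optimize.minimize_scalar(
        lambda t: -loglik(counts, model, t),
        bounds=_T_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun), bool(res.success)


def fit_pairwise(
    patterns: PatternCounts,
    n_categories: int = 5,
    model: GTRModel | None = None,
    full_fit_min_sites: int = FULL_FIT_MIN_SITES,
    fallback_model: GTRModel | None = None,
) -> DivergenceEstimate:
    """ML pairwise distance under GTR+Gamma.

    With ``model`` given, only t is optimized under that fixed model. Otherwise
    exchangeabilities and the gamma shape are ML-fit jointly with t (empirical
    base frequencies), unless the unit has fewer than ``full_fit_min_sites``
    usable sites and a ``fallback_model`` is supplied, in which case the
    fallback's parameters are frozen and only t is optimized.
    """
    if patterns.n_species != 2:
        raise ValueError("fit_pairwise needs two-sequence patterns")
    if patterns.n_sites == 0:
        raise NoUsableSitesError("no usable alignment columns")
    if patterns.n_diff == 0:
        base = model or fallback_model or GTRModel(
            np.ones(6), patterns.empirical_frequencies(), 1.0, n_categories
        )
        ll = _pairwise_loglik(patterns.counts, base, _T_BOUNDS[0])
        est = DivergenceEstimate(0.0, base, patterns.n_sites, 0, True, ll)
        est._ll = None
        return est

    if model is None and patterns.n_sites < full_fit_min_sites and fallback_model is not None:
        model = fallback_model

    if model is not None:
        t, ll, ok = _t_only_fit(patterns.counts, model, _pairwise_loglik)
        est = DivergenceEstimate(t, model, patterns.n_sites, patterns.n_diff, ok, ll)
        est._ll = lambda tt: _pairwise_loglik(patterns.counts, model, tt)
        return est

    freqs = patterns.empirical_frequencies()

    def build(theta):
        t = np.exp(theta[0])
        exch = np.concatenate([np.exp(theta[1:6]), [1.0]])
        alpha = np.exp(theta[6])
        return t, GTRModel(exch, freqs, alpha, n_categories)

    def neg_ll(theta):
        t, m = build(theta)
        return -_pairwise_loglik(patterns.counts, m, t)

    bounds = (
        [np.log(_T_BOUNDS)]
        + [np.log(_EXCH_BOUNDS)] * 5
        + [np.log(_ALPHA_BOUNDS)]
    )
    best = None
    for t0 in _T_STARTS:
        theta0 = np.concatenate([[np.log(t0)], np.zeros(5), [0.0]])
        res = optimize.minimize(
            neg_ll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": _LL_TOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    t, fitted = build(best.x)
    est = DivergenceEstimate(
        float(t), fitted, patterns.n_sites, patterns.n_diff, bool(best.success), -float(best.fun)
    )
    est._ll = lambda tt: _pairwise_loglik(patterns.counts, fitted, tt)
    if not best.success:
        logger.warning("pairwise fit did not converge (n_sites=%d)", patterns.n_sites)
    return est


def fit_triple(
    patterns: PatternCounts,
    n_categories: int = 5,
    model: GTRModel | None = None,
    full_fit_min_sites: int = FULL_FIT_MIN_SITES,
    fallback_model: GTRModel | None = None,
    species_order: tuple = ("mouse", "rat", "human"),
) -> TripleEstimate:
    """ML branch lengths on the unrooted three-taxon tree with a shared model."""
    if patterns.n_species != 3:
        raise ValueError("fit_triple needs three-sequence patterns")
    if patterns.n_sites == 0:
        raise NoUsableSitesError("no usable alignment columns")
    if patterns.n_diff == 0:
        base = model or fallback_model or GTRModel(
            np.ones(6), patterns.empirical_frequencies(), 1.0, n_categories
        )
        ll = _triple_loglik(patterns.counts, base, *([_T_BOUNDS[0]] * 3))
        return TripleEstimate(dict.fromkeys(species_order, 0.0), base, patterns.n_sites, 0, True, ll)

    if model is None and patterns.n_sites < full_fit_min_sites and fallback_model is not None:
        model = fallback_model

    fit_model = model is None
    freqs = patterns.empirical_frequencies()

    def build(theta):
        ts = np.exp(theta[:3])
        if fit_model:
            exch = np.concatenate([np.exp(theta[3:8]), [1.0]])
            alpha = np.exp(theta[8])
            return ts, GTRModel(exch, freqs, alpha, n_categories)
        return ts, model

    def neg_ll(theta):
        ts, m = build(theta)
        return -_triple_loglik(patterns.counts, m, *ts)

    bounds = [np.log(_T_BOUNDS)] * 3
    if fit_model:
        bounds += [np.log(_EXCH_BOUNDS)] * 5 + [np.log(_ALPHA_BOUNDS)]
    best = None
    for t0 in _T_STARTS:
        theta0 = np.full(3, np.log(t0))
        if fit_model:
            theta0 = np.concatenate([theta0, np.zeros(5), [0.0]])
        res = optimize.minimize(
            neg_ll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": _LL_TOL, "maxiter": 800},
        )
        if best is None or res.fun < best.fun:
            best = res
    ts, fitted = build(best.x)
    branches = {sp: float(t) for sp, t in zip(species_order, ts)}
    if not best.success:
        logger.warning("triple fit did not converge (n_sites=%d)", patterns.n_sites)
    return TripleEstimate(
        branches, fitted, patterns.n_sites, patterns.n_diff, bool(best.success), -float(best.fun)
    )


# ------------------------------------------------------- region assembly ---

def collect_columns(
    alignments,
    chrom: str,
    positions: np.ndarray,
    species: tuple,
) -> np.ndarray:
    """Concatenate base codes for all mask positions across overlapping blocks.

    Returns stacked codes, shape (n_species, n_selected_columns); columns are
    ordered by genomic position (blocks are scanned left to right).
    """
    if positions.size == 0:
        return np.empty((len(species), 0), dtype=np.uint8)
    mask = SiteMask("_query", chrom, "fourfold", positions)
    chunks = []
    for block in alignments.overlapping(chrom, int(positions[0]), int(positions[-1]) + 1):
        cols, _ = project_mask_to_alignment(mask, block)
        if cols.size:
            chunks.append(block.column_codes(cols, list(species)))
    if not chunks:
        return np.empty((len(species), 0), dtype=np.uint8)
    return np.concatenate(chunks, axis=1)


def patterns_for_span(alignments, chrom, start, end, species) -> PatternCounts:
    codes = collect_columns(alignments, chrom, np.arange(start, end, dtype=np.int64), species)
    return count_site_patterns(codes)


def patterns_for_mask(alignments, mask: SiteMask, species) -> PatternCounts:
    codes = collect_columns(alignments, mask.chrom, mask.positions, species)
    return count_site_patterns(codes)


def divergence_for_region(
    alignments,
    chrom: str,
    positions: np.ndarray,
    species: tuple = ("mouse", "rat"),
    mode: str = "pairwise",
    **fit_kwargs,
):
    """Concatenate all projected columns for a region/mask and fit once.

    Returns a DivergenceEstimate (pairwise) or TripleEstimate (triple);
    raises NoUsableSitesError when the region projects to no usable column.
    """
    codes = collect_columns(alignments, chrom, np.asarray(positions, dtype=np.int64), species)
    patterns = count_site_patterns(codes)
    if mode == "pairwise":
        return fit_pairwise(patterns, **fit_kwargs)
    if mode == "triple":
        return fit_triple(patterns, species_order=species, **fit_kwargs)
    raise ValueError("mode must be 'pairwise' or 'triple'")
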
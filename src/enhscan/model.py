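"""General time-reversible (GTR) nucleotide substitution model with discrete-gamma
rate heterogeneity.

The model is parameterized by six exchangeabilities (order AC, AG, AT, CG, CT, GT),
four base frequencies, a gamma shape alpha, and the number of equal-probability
rate categories K. The generator is scaled so that the expected substitution rate
at stationarity is one per unit branch length, i.e. branch lengths are expected
substitutions per site. Category rates are the means of K equal-probability slices
of a Gamma(alpha, 1/alpha) distribution (mean 1), renormalized to average exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: row/col index pairs for the exchangeability vector (AC, AG, AT, CG, CT, GT)
PAIR_INDEX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability gamma categories.

    Rates follow Gamma(alpha, scale=1/alpha) (mean 1). Category k spans the
    (k/K, (k+1)/K) quantile slice; its rate is the conditional mean of the
    slice, K * (F_{alpha+1}(b_{k+1}) - F_{alpha+1}(b_k)), renormalized so the
    average over categories is exactly 1.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    if k == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    # E[X; X<b] for Gamma(a, 1/a) equals F_{a+1, 1/a}(b) since a*(1/a) = 1
    upper_cdf = _gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], upper_cdf, [1.0]])
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass
class GTRModel:
    """GTR+Gamma substitution model with cached spectral decomposition.

    Parameters
    ----------
    exchangeabilities : array-like of 6 nonnegative floats (AC, AG, AT, CG, CT, GT)
    base_frequencies : array-like of 4 probabilities summing to 1 (A, C, G, T)
    gamma_shape : shape alpha of the rate-heterogeneity gamma (ignored if
        ``n_categories`` is 1)
    n_categories : number of discrete equal-probability rate categories
    """

    exchangeabilities: np.ndarray
    base_frequencies: np.ndarray
    gamma_shape: float = 1.0
    n_categories: int = 5
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be 6 nonnegative rates")
        if self.base_frequencies.shape != (4,):
            raise ValueError("base_frequencies must have 4 entries")
        if abs(self.base_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1")
        if np.any(self.base_frequencies <= 0):
            raise ValueError("base_frequencies must be strictly positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    # -- generator ---------------------------------------------------------

    def rate_matrix(self, gc_factor: float = 1.0) -> np.ndarray:
        """Scaled GTR generator Q (rows sum to 0, mean rate 1 at stationarity).

        ``gc_factor`` multiplies every off-diagonal rate into G or C before
        rescaling; 1.0 gives the plain GTR generator. The matrix is rescaled
        after applying the factor so total substitution rate stays 1 — the
        factor changes the *direction* composition of substitutions, not the
        overall pace.
        """
        pi = self.base_frequencies
        q = np.zeros((4, 4))
        for (i, j), s in zip(PAIR_INDEX, self.exchangeabilities):
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        if gc_factor != 1.0:
            q[:, 1] *= gc_factor  # -> C
            q[:, 2] *= gc_factor  # -> G
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
        return q / scale

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def _decomposition(self):
        """Eigendecomposition of the reversible generator, cached.

        Q = D^{-1/2} U diag(w) U^T D^{1/2} with D = diag(pi); P(t) follows by
        exponentiating the eigenvalues. Only valid for gc_factor == 1 (the
        biased generator is not reversible w.r.t. pi and is only used by the
        simulator, which exponentiates directly).
        """
        if self._eig is None:
            pi = self.base_frequencies
            q = self.rate_matrix()
            d = np.sqrt(pi)
            sym = (q * d[:, None]) / d[None, :]
            sym = 0.5 * (sym + sym.T)
            w, u = np.linalg.eigh(sym)
            left = u.T * d[None, :]      # U^T D^{1/2}
            right = u / d[:, None]       # D^{-1/2} U
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for a single rate-1 branch of length ``t``."""
        w, right, left = self._decomposition()
        p = (right * np.exp(w * t)) @ left
        np.clip(p, 1e-300, None, out=p)
        return p

    def transition_matrices(self, t: float) -> np.ndarray:
        """Per-category transition matrices, shape (K, 4, 4)."""
        w, right, left = self._decomposition()
        rates = self.category_rates()
        ew = np.exp(np.outer(rates, w) * t)          # (K, 4)
        p = np.einsum("ij,kj,jl->kil", right, ew, left)
        np.clip(p, 1e-300, None, out=p)
        return p

    def replace(self, **kw) -> "GTRModel":
        args = dict(
            exchangeabilities=self.exchangeabilities,
            base_frequencies=self.base_frequencies,
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
        )
        args.update(kw)
        return GTRModel(**args)


def jukes_cantor_distance(p: float) -> float:
    """Closed-form JC69 distance for a mismatch fraction ``p`` (< 0.75)."""
    if not 0 <= p < 0.75:
        raise ValueError("mismatch fraction must lie in [0, 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jukes_cantor_p(t: float) -> float:
    """Expected mismatch fraction at JC69 distance ``t``."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
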
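import numpy as np
import pytest

from enhscan.divergence import (
    NoUsableSitesError,
    PatternCounts,
    count_site_patterns,
    divergence_for_region,
    fit_pairwise,
    fit_triple,
    patterns_for_span,
)
from enhscan.io import AlignmentBlock, AlignmentSet, encode_sequence
from enhscan.model import GTRModel, jukes_cantor_distance

JC_MODEL = GTRModel(np.ones(6), np.full(4, 0.25), gamma_shape=1.0, n_categories=1)
MAMMAL = GTRModel((1, 4, 0.8, 1.2, 4.5, 1.0), (0.29, 0.21, 0.21, 0.29), 1.0, 5)


def simulate_pair(model, t, n, rng):
    """Two sequences separated by distance t under the model (stationary start)."""
    rates = model.category_rates()
    cat = rng.integers(0, model.n_categories, n)
    a = rng.choice(4, n, p=model.base_frequencies)
    b = np.empty(n, dtype=np.int64)
    for k in range(model.n_categories):
        p = model.transition_matrix(t * rates[k])
        m = cat == k
        u = rng.random(m.sum())
        b[m] = (u[:, None] > np.cumsum(p, axis=1)[a[m]]).sum(1)
    return np.stack([a, b]), cat


def simulate_triple(model, ts, n, rng):
    rates = model.category_rates()
    cat = rng.integers(0, model.n_categories, n)
    anc = rng.choice(4, n, p=model.base_frequencies)
    leaves = []
    for t in ts:
        leaf = np.empty(n, dtype=np.int64)
        for k in range(model.n_categories):
            p = model.transition_matrix(t * rates[k])
            m = cat == k
            u = rng.random(m.sum())
            leaf[m] = (u[:, None] > np.cumsum(p, axis=1)[anc[m]]).sum(1)
        leaves.append(leaf)
    return np.stack(leaves)


class TestPatternCounts:
    def test_identical_pair(self):
        codes = np.tile(np.array([[0], [0]]), (1, 100))
        pat = count_site_patterns(codes)
        assert (pat.n_sites, pat.n_diff) == (100, 0)

    def test_seven_of_hundred_differ(self):
        a = np.zeros(100, dtype=int)
        b = a.copy()
        b[:7] = 2
        pat = count_site_patterns(np.stack([a, b]))
        assert (pat.n_sites, pat.n_diff) == (100, 7)

    def test_gapped_columns_match_naive_oracle(self, rng):
        a = rng.integers(0, 6, 500)  # includes ambiguity (4) and gap (5)
        b = rng.integers(0, 6, 500)
        pat = count_site_patterns(np.stack([a, b]))
        keep = (a < 4) & (b < 4)
        assert pat.n_sites == int(keep.sum())
        assert pat.n_excluded == 500 - int(keep.sum())
        assert pat.n_diff == int((a[keep] != b[keep]).sum())
        for x in range(4):
            for y in range(4):
                assert pat.counts[x, y] == int(((a == x) & (b == y)).sum())

    def test_column_order_irrelevant(self, rng):
        codes, _ = simulate_pair(MAMMAL, 0.2, 2000, rng)
        perm = rng.permutation(2000)
        t1 = fit_pairwise(count_site_patterns(codes), model=MAMMAL).t
        t2 = fit_pairwise(count_site_patterns(codes[:, perm]), model=MAMMAL).t
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestPairwiseFit:
    def test_identical_sequences_give_zero(self):
        codes = np.tile(np.array([[1], [1]]), (1, 300))
        est = fit_pairwise(count_site_patterns(codes))
        assert est.t == 0.0 and est.n_diff == 0 and est.converged

    def test_jukes_cantor_closed_form(self):
        """Equal frequencies/exchangeabilities, one rate class, p = 0.10:
        the ML distance equals -(3/4)ln(1-4p/3)."""
        counts = np.full((4, 4), 1000 / 12)
        np.fill_diagonal(counts, 2250.0)
        pat = PatternCounts(counts, 10_000, 1000, 0)
        est = fit_pairwise(pat, model=JC_MODEL)
        assert est.t == pytest.approx(jukes_cantor_distance(0.10), abs=1e-3)
        assert est.converged

    def test_distance_increases_with_mismatch_fraction(self):
        prev = -1.0
        for p in (0.05, 0.15, 0.30, 0.50, 0.70):
            counts = np.full((4, 4), 10_000 * p / 12)
            np.fill_diagonal(counts, 10_000 * (1 - p) / 4)
            est = fit_pairwise(PatternCounts(counts, 10_000, int(10_000 * p), 0), model=JC_MODEL)
            assert est.t > prev
            prev = est.t

    def test_recovers_simulated_distance_under_known_model(self, rng):
        codes, _ = simulate_pair(MAMMAL, 0.2, 30_000, rng)
        est = fit_pairwise(count_site_patterns(codes), model=MAMMAL)
        assert est.converged
        assert abs(est.t - 0.2) < 3 * est.standard_error()

    def test_free_fit_dominates_true_parameters(self, rng):
        """The joint ML fit never does worse than the generating parameters."""
        from enhscan.divergence import _pairwise_loglik

        codes, _ = simulate_pair(MAMMAL, 0.2, 30_000, rng)
        pat = count_site_patterns(codes)
        free = fit_pairwise(pat)
        assert free.converged
        assert free.log_likelihood >= _pairwise_loglik(pat.counts, MAMMAL, 0.2) - 1e-6

    def test_optimum_beats_fixed_start(self, rng):
        codes, _ = simulate_pair(MAMMAL, 0.35, 5_000, rng)
        pat = count_site_patterns(codes)
        est = fit_pairwise(pat, model=MAMMAL)
        from enhscan.divergence import _pairwise_loglik

        assert est.log_likelihood >= _pairwise_loglik(pat.counts, MAMMAL, 0.1)

    def test_small_unit_uses_fallback_model(self, rng):
        codes, _ = simulate_pair(MAMMAL, 0.2, 120, rng)
        pat = count_site_patterns(codes)
        est = fit_pairwise(pat, fallback_model=MAMMAL, full_fit_min_sites=200)
        assert est.model is MAMMAL  # frozen pooled model, only t optimized

    def test_empty_input_raises(self):
        with pytest.raises(NoUsableSitesError):
            fit_pairwise(count_site_patterns(np.full((2, 10), 5)))


class TestTripleFit:
    def test_identical_sequences_give_zero_branches(self):
        codes = np.tile(np.array([[2], [2], [2]]), (1, 200))
        est = fit_triple(count_site_patterns(codes))
        assert all(v == 0.0 for v in est.branch_lengths.values())

    def test_recovers_simulated_branches(self, rng):
        codes = simulate_triple(MAMMAL, (0.1, 0.1, 0.3), 50_000, rng)
        est = fit_triple(count_site_patterns(codes), model=MAMMAL)
        for sp, true_t in zip(("mouse", "rat", "human"), (0.1, 0.1, 0.3)):
            se = np.sqrt(true_t / 50_000) * 2  # crude binomial-scale SE
            assert est.branch_lengths[sp] == pytest.approx(true_t, abs=3 * max(se, 0.004))

    def test_zero_outgroup_limit_matches_pairwise(self, rng):
        """Collapsing the human branch to 0 reduces the triple fit to the
        pairwise mouse-rat distance."""
        codes = simulate_triple(MAMMAL, (0.1, 0.1, 0.0), 50_000, rng)
        triple = fit_triple(count_site_patterns(codes))
        pair = fit_pairwise(count_site_patterns(codes[:2]))
        assert triple.mouse_rat_distance == pytest.approx(pair.t, abs=1e-2)


class TestRegionAssembly:
    def make_alignments(self, rng, n=600, block_len=200):
        codes, _ = simulate_pair(MAMMAL, 0.25, n, rng)
        blocks = []
        for s in range(0, n, block_len):
            blocks.append(
                AlignmentBlock(
                    "chr1", s,
                    {
                        "mouse": "".join("ACGT"[c] for c in codes[0, s : s + block_len]),
                        "rat": "".join("ACGT"[c] for c in codes[1, s : s + block_len]),
                    },
                )
            )
        return AlignmentSet(blocks), codes

    def test_span_inside_one_block_equals_direct_fit(self, rng):
        aln, codes = self.make_alignments(rng)
        est = divergence_for_region(aln, "chr1", np.arange(20, 180), model=MAMMAL)
        direct = fit_pairwise(count_site_patterns(codes[:, 20:180]), model=MAMMAL)
        assert est.t == pytest.approx(direct.t, abs=1e-12)

    def test_span_across_blocks_equals_concatenation(self, rng):
        aln, codes = self.make_alignments(rng)
        est = divergence_for_region(aln, "chr1", np.arange(150, 450), model=MAMMAL)
        direct = fit_pairwise(count_site_patterns(codes[:, 150:450]), model=MAMMAL)
        assert est.t == pytest.approx(direct.t, abs=1e-12)
        assert est.n_sites == 300

    def test_empty_projection_raises(self, rng):
        aln, _ = self.make_alignments(rng)
        with pytest.raises(NoUsableSitesError):
            divergence_for_region(aln, "chr1", np.arange(5000, 5100))

    def test_patterns_for_span_counts(self, rng):
        aln, codes = self.make_alignments(rng)
        pat = patterns_for_span(aln, "chr1", 0, 600, ("mouse", "rat"))
        assert pat.n_sites == 600
        assert pat.n_diff == int((codes[0] != codes[1]).sum())
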
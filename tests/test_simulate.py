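import numpy as np
import pandas as pd
import pytest

from enhscan import (
    SimulationConfig,
    consolidate,
    evolve_alignments,
    fourfold_sites,
    simulate_annotation,
    simulate_dataset,
)
from enhscan.io import decode_sequence
from enhscan.simulate import (
    PlacementError,
    expected_at_to_gc_ratio,
    expected_mismatch_fraction,
    truth_classes_for_regions,
)
from enhscan.sites import InvalidCdsError
from tests.conftest import ALL_TISSUES, small_config


class TestConfig:
    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(base_frequencies=(0.3, 0.3, 0.3, 0.3))

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            SimulationConfig(tree_branch_lengths={"mouse": -0.1, "rat": 0.1, "human": 0.3})

    def test_zero_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multiplier"):
            SimulationConfig(
                selection_multiplier_by_class={"neutral": 1.0, "purifying": 0.0, "positive": 2.0}
            )

    def test_json_round_trip(self, tmp_path):
        cfg = small_config(seed=5)
        cfg.to_json(tmp_path / "c.json")
        back = SimulationConfig.from_json(tmp_path / "c.json")
        assert back == cfg


class TestAnnotation:
    def test_empty_enhancer_set_still_yields_genes(self):
        cfg = small_config(n_enhancers_per_tissue={t: 0 for t in ALL_TISSUES}, n_genes=8)
        ann = simulate_annotation(cfg)
        assert len(ann.enhancer_records) == 0
        assert len(ann.genes) == 8
        assert all(len(g.longest_isoform.exons) >= 1 for g in ann.genes)

    def test_every_truth_enhancer_has_one_emitted_record(self, dataset):
        _, annotation, _, truth = dataset
        emitted = sorted((r.start, r.end, r.tissue) for r in annotation.enhancer_records)
        in_truth = sorted(
            (int(r.start), int(r.end), r.tissue) for r in truth.enhancers.itertuples()
        )
        assert emitted == in_truth

    def test_forced_duplicate_becomes_one_pleiotropic_region(self):
        cfg = small_config(
            n_genes=6,
            n_enhancers_per_tissue={"HT": 3, "FB": 0, "MB": 0, "LB": 0},
            pleiotropic_fraction=1.0,
        )
        ann = simulate_annotation(cfg)
        regions = consolidate(ann.enhancer_records)
        assert len(regions) == 3
        assert all(r.pleiotropy == "pleiotropic" for r in regions)

    def test_placement_error_names_the_constraint(self):
        with pytest.raises(PlacementError, match="chrom_length"):
            simulate_annotation(small_config(chrom_length=10_000))

    def test_deterministic_given_seed(self):
        a1 = simulate_annotation(small_config(n_genes=10))
        a2 = simulate_annotation(small_config(n_genes=10))
        assert a1.truth.enhancers.equals(a2.truth.enhancers)
        assert a1.covariates.equals(a2.covariates)
        assert [(g.gene_id, g.strand, g.start, g.end) for g in a1.genes] == [
            (g.gene_id, g.strand, g.start, g.end) for g in a2.genes
        ]

    def test_gene_structure_fractions_exercised(self, dataset):
        _, annotation, _, _ = dataset
        n_exons = [len(g.longest_isoform.exons) for g in annotation.genes]
        assert min(n_exons) >= 1
        assert any(n <= 2 for n in n_exons)  # intronless/single-intron present
        assert any(n >= 4 for n in n_exons)

    def test_covariates_have_essentiality_and_61_signals(self, dataset):
        _, annotation, _, _ = dataset
        cov = annotation.covariates
        expr_cols = [c for c in cov.columns if c.startswith("expr_")]
        assert len(expr_cols) == 61
        assert set(cov["essentiality"]) <= {"essential", "non-essential", "unknown"}


class TestEvolution:
    def test_zero_branch_lengths_give_identical_sequences(self):
        cfg = small_config(
            n_genes=5,
            n_enhancers_per_tissue={t: 2 for t in ALL_TISSUES},
            tree_branch_lengths={"mouse": 0.0, "rat": 0.0, "human": 0.0},
        )
        _, _, truth = simulate_dataset(cfg)
        assert np.array_equal(truth.sequences["mouse"], truth.ancestral)
        assert np.array_equal(truth.sequences["rat"], truth.ancestral)
        assert truth.mouse_substituted.sum() == 0

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        from enhscan.simulate import write_dataset

        for sub in ("a", "b"):
            cfg = small_config(n_genes=6, n_enhancers_per_tissue={t: 3 for t in ALL_TISSUES})
            ann, aln, truth = simulate_dataset(cfg)
            write_dataset(tmp_path / sub, cfg, ann, aln, truth)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_mismatch_fraction_matches_jukes_cantor_expectation(self):
        """Equal frequencies and exchangeabilities, one rate class, neutral
        sites: the realized mouse-rat difference fraction must sit within
        3 Monte-Carlo SE of the closed-form JC expectation."""
        cfg = small_config(
            seed=3,
            n_genes=2,
            n_enhancers_per_tissue={"HT": 0, "FB": 0, "MB": 0, "LB": 0},
            gtr_exchangeabilities=(1.0,) * 6,
            base_frequencies=(0.25,) * 4,
            n_gamma_categories=1,
            chrom_length=60_000,
        )
        ann, _, truth = simulate_dataset(cfg)
        # restrict to sites outside genes (everything neutral, rate 1)
        neutral = np.ones(ann.chrom_length, dtype=bool)
        for g in ann.genes:
            neutral[g.start : g.end] = False
        m, r = truth.sequences["mouse"][neutral], truth.sequences["rat"][neutral]
        p_hat = float((m != r).mean())
        t = cfg.tree_branch_lengths["mouse"] + cfg.tree_branch_lengths["rat"]
        p_exp = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / neutral.sum())
        assert abs(p_hat - p_exp) < 3 * se

    def test_positive_class_doubles_difference_rate(self):
        """Enhancers with multiplier 2 vs neutral flanks: the realized
        difference-rate ratio matches the analytic expectation within
        sampling error (>= 20 kb of enhancer sites)."""
        cfg = small_config(
            seed=4,
            n_genes=20,
            n_enhancers_per_tissue={"HT": 20, "FB": 0, "MB": 0, "LB": 0},
            class_probabilities={"neutral": 0.0, "purifying": 0.0, "positive": 1.0},
            pleiotropic_fraction=0.0,
        )
        ann, _, truth = simulate_dataset(cfg)
        enh = np.zeros(ann.chrom_length, dtype=bool)
        for row in ann.truth.enhancers.itertuples():
            enh[row.start : row.end] = True
        assert enh.sum() >= 20_000
        genic = np.zeros(ann.chrom_length, dtype=bool)
        for g in ann.genes:
            genic[g.start : g.end] = True
        m, r = truth.sequences["mouse"], truth.sequences["rat"]
        diff = m != r
        p_enh = float(diff[enh].mean())
        p_neu = float(diff[~enh & ~genic].mean())
        expected_ratio = expected_mismatch_fraction(cfg, multiplier=2.0) / (
            expected_mismatch_fraction(cfg, multiplier=1.0)
        )
        se_ratio = expected_ratio * np.sqrt(
            1 / diff[enh].sum() + 1 / diff[~enh & ~genic].sum()
        )
        assert p_enh / p_neu == pytest.approx(expected_ratio, abs=3.5 * se_ratio)

    def test_gene_cds_mostly_survives_drift(self, dataset):
        """Coding constraint keeps most reading frames intact in the mouse."""
        _, annotation, _, truth = dataset
        genome = {annotation.chrom: decode_sequence(truth.sequences["mouse"])}
        ok = 0
        for g in annotation.genes:
            try:
                fourfold_sites(g, genome)
                ok += 1
            except InvalidCdsError:
                pass
        assert ok / len(annotation.genes) > 0.6

    def test_truth_class_mapping(self, dataset):
        _, annotation, _, truth = dataset
        regions = consolidate(annotation.enhancer_records)
        mapped = truth_classes_for_regions(regions, truth.enhancers)
        assert len(mapped) == len(regions)
        assert set(mapped["sel_class"]) <= {"neutral", "purifying", "positive"}


class TestGcBias:
    def test_bias_raises_expected_at_to_gc_ratio(self):
        cfg0 = small_config(gc_fixation_bias=0.0)
        cfg1 = small_config(gc_fixation_bias=1.5)
        assert expected_at_to_gc_ratio(cfg1) > expected_at_to_gc_ratio(cfg0)

    def test_neutral_ratio_matches_analytic_expectation(self):
        """With no bias, the simulated A/T->G/C share of polarized mouse events
        sits within 3 SE of the value implied by the generator's rate matrix."""
        from enhscan.gbgc import polarize_columns

        cfg = small_config(
            seed=9,
            n_genes=2,
            n_enhancers_per_tissue={t: 0 for t in ALL_TISSUES},
            chrom_length=120_000,
        )
        _, _, truth = simulate_dataset(cfg)
        codes = np.stack([truth.sequences[s] for s in ("mouse", "rat", "human")])
        cats = polarize_columns(codes)
        n_sub = cats["AT_to_GC"] + cats["AT_to_AT"]
        ratio = cats["AT_to_GC"] / n_sub
        expected = expected_at_to_gc_ratio(cfg)
        se = np.sqrt(expected * (1 - expected) / n_sub)
        assert abs(ratio - expected) < 3 * se
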
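import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from enhscan.io import AlignmentBlock
from enhscan.sites import (
    GeneModel,
    InvalidCdsError,
    Isoform,
    SiteMask,
    FOURFOLD_PREFIXES,
    fourfold_sites,
    intron_sites,
    project_mask_to_alignment,
)

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def single_exon_gene(cds: str, strand="+", offset=10, gene_id="g1"):
    """Gene whose single exon is exactly the CDS, placed at ``offset``."""
    seq = cds if strand == "+" else reverse_complement(cds)
    genome = {"chr1": "A" * offset + seq + "A" * 10}
    span = [(offset, offset + len(cds))]
    gene = GeneModel(gene_id, "chr1", strand, [Isoform("t1", span, span)])
    return gene, genome


def oracle_fourfold_indices(cds: str):
    """Per-codon brute force: all four third-base variants must be synonymous
    sense codons."""
    out = []
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if str(Seq(codons[-1]).translate()) == "*":
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        variants = [codon[:2] + b for b in "ACGT"]
        aas = {str(Seq(v).translate()) for v in variants}
        if len(aas) == 1 and "*" not in aas:
            out.append(3 * i + 2)
    return out


class TestFourfoldSites:
    def test_known_example_met_gly_ala_stop(self):
        """ATG GGA GCT TAA: GGA and GCT are fourfold at their third position."""
        gene, genome = single_exon_gene("ATGGGAGCTTAA")
        mask = fourfold_sites(gene, genome)
        assert list(mask.positions) == [10 + 5, 10 + 8]

    def test_all_met_codons_yield_empty_mask(self):
        gene, genome = single_exon_gene("ATG" * 6 + "TAA")
        assert len(fourfold_sites(gene, genome)) == 0

    def test_minus_strand_mirrors_plus_strand(self):
        cds = "ATGGGAGCTCCGGTATAA"
        plus, genome_p = single_exon_gene(cds, "+")
        minus, genome_m = single_exon_gene(cds, "-")
        mp = fourfold_sites(plus, genome_p)
        mm = fourfold_sites(minus, genome_m)
        assert len(mp) == len(mm)
        start, end = 10, 10 + len(cds)
        mirrored = sorted(start + end - 1 - p for p in mp.positions)
        assert list(mm.positions) == mirrored

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_synonymy_oracle(self, rng, strand):
        """Exact agreement with per-codon genetic-code enumeration on 100 CDS."""
        for _ in range(100):
            n_codons = int(rng.integers(4, 60))
            body = rng.choice(SENSE_CODONS, size=n_codons)
            cds = "ATG" + "".join(body) + "TAA"
            gene, genome = single_exon_gene(cds, strand)
            mask = fourfold_sites(gene, genome)
            expected_tx = oracle_fourfold_indices(cds)
            if strand == "+":
                expected = [10 + i for i in expected_tx]
            else:
                end = 10 + len(cds)
                expected = sorted(end - 1 - i for i in expected_tx)
            assert list(mask.positions) == expected
            assert len(mask) <= len(cds) // 3

    def test_spliced_cds_maps_through_introns(self):
        # ATG GGA | GCT TAA split across two exons with a 100 bp intron
        genome = {"chr1": "T" * 10 + "ATGGGA" + "C" * 100 + "GCTTAA" + "T" * 5}
        iso = Isoform("t1", [(10, 16), (116, 122)], [(10, 16), (116, 122)])
        gene = GeneModel("g1", "chr1", "+", [iso])
        mask = fourfold_sites(gene, genome)
        assert list(mask.positions) == [15, 118]  # GGA third, GCT third

    def test_premature_stop_and_bad_length_excluded(self):
        gene, genome = single_exon_gene("ATGTAAGCTTAA")
        with pytest.raises(InvalidCdsError, match="premature stop"):
            fourfold_sites(gene, genome)
        gene, genome = single_exon_gene("ATGGGAGC")
        with pytest.raises(InvalidCdsError, match="multiple of 3"):
            fourfold_sites(gene, genome)

    def test_ambiguous_codon_skipped(self):
        gene, genome = single_exon_gene("ATGGNAGCTTAA")
        mask = fourfold_sites(gene, genome)
        assert list(mask.positions) == [10 + 8]  # only GCT remains

    def test_fourfold_prefix_table_is_the_eight_families(self):
        assert FOURFOLD_PREFIXES == {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}


def gene_with_introns(exon_lens, intron_lens, strand="+", start=100):
    exons = []
    cursor = start
    for i, el in enumerate(exon_lens):
        exons.append((cursor, cursor + el))
        cursor += el
        if i < len(intron_lens):
            cursor += intron_lens[i]
    return GeneModel("gI", "chr1", strand, [Isoform("t1", exons, exons)])


class TestIntronSites:
    def test_first_intron_removed(self):
        gene = gene_with_introns([50, 50, 50, 50], [500, 300, 200])
        mask = intron_sites(gene)
        assert len(mask) == 300 + 200
        first_intron = set(range(150, 650))
        assert not first_intron & set(mask.positions)

    def test_single_intron_gene_has_empty_mask(self):
        assert len(intron_sites(gene_with_introns([50, 50], [400]))) == 0

    def test_intronless_gene_has_empty_mask(self):
        assert len(intron_sites(gene_with_introns([150], []))) == 0

    def test_minus_strand_first_intron_is_rightmost(self):
        gene = gene_with_introns([50, 50, 50], [500, 200], strand="-")
        mask = intron_sites(gene)
        assert len(mask) == 500  # the rightmost (200 bp) intron is removed
        assert mask.positions.min() == 150 and mask.positions.max() == 649

    def test_mask_disjoint_from_exons_and_first_intron(self):
        gene = gene_with_introns([30, 40, 50, 60], [100, 200, 300])
        mask = intron_sites(gene)
        exonic = {p for s, e in gene.longest_isoform.exons for p in range(s, e)}
        assert not exonic & set(mask.positions)


class TestLongestIsoform:
    def test_greatest_summed_exon_length_wins(self):
        short = Isoform("a", [(0, 100)], [(0, 99)])
        long_ = Isoform("b", [(0, 80), (200, 280)], [(0, 80), (200, 278)])
        gene = GeneModel("g", "chr1", "+", [short, long_])
        assert gene.longest_isoform.isoform_id == "b"

    def test_ties_broken_by_cds_then_id(self):
        a = Isoform("b_iso", [(0, 100)], [(0, 60)])
        b = Isoform("a_iso", [(0, 100)], [(0, 60)])
        gene = GeneModel("g", "chr1", "+", [a, b])
        assert gene.longest_isoform.isoform_id == "a_iso"
        c = Isoform("c_iso", [(0, 100)], [(0, 90)])
        gene = GeneModel("g", "chr1", "+", [a, c])
        assert gene.longest_isoform.isoform_id == "c_iso"


class TestProjection:
    def block(self, seqs, start=1000):
        return AlignmentBlock("chr1", start, seqs)

    def test_disjoint_mask_projects_to_nothing(self):
        b = self.block({"mouse": "ACGT", "rat": "ACGT"})
        mask = SiteMask("g", "chr1", "fourfold", np.array([10, 20]))
        cols, outside = project_mask_to_alignment(mask, b)
        assert cols.size == 0 and outside == 2

    def test_gapless_block_projects_all_columns(self):
        b = self.block({"mouse": "ACGTAC", "rat": "ACGAAC"})
        mask = SiteMask("g", "chr1", "intron", np.arange(1000, 1006))
        cols, outside = project_mask_to_alignment(mask, b)
        assert list(cols) == list(range(6)) and outside == 0

    def test_gap_columns_dropped_and_coordinates_shift(self):
        # mouse has a gap at column 2: columns 3.. map to coordinates 1002..
        b = self.block({"mouse": "AC-GTA", "rat": "ACCGTA"})
        mask = SiteMask("g", "chr1", "fourfold", np.array([1002, 1004]))
        cols, _ = project_mask_to_alignment(mask, b)
        assert list(cols) == [3, 5]
        # rat gap removes a column even when mouse coordinate exists
        b2 = self.block({"mouse": "ACGTA", "rat": "AC-TA"})
        cols2, _ = project_mask_to_alignment(
            SiteMask("g", "chr1", "fourfold", np.array([1002, 1003])), b2
        )
        assert list(cols2) == [3]

    def test_matches_per_position_linear_scan(self, rng):
        for _ in range(20):
            n = 80
            mouse = "".join(rng.choice(list("ACGT-"), n, p=[0.23] * 4 + [0.08]))
            rat = "".join(rng.choice(list("ACGT-"), n, p=[0.23] * 4 + [0.08]))
            b = self.block({"mouse": mouse, "rat": rat}, start=500)
            positions = np.sort(
                rng.choice(np.arange(480, 620), size=40, replace=False)
            )
            mask = SiteMask("g", "chr1", "fourfold", positions)
            cols, outside = project_mask_to_alignment(mask, b)
            # oracle: walk columns, tracking the mouse coordinate
            expected, coord = [], 500
            ref_end = 500 + sum(c != "-" for c in mouse)
            for i in range(n):
                if mouse[i] != "-":
                    if coord in positions and rat[i] != "-":
                        expected.append(i)
                    coord += 1
            assert list(cols) == expected
            n_outside_oracle = int(((positions < 500) | (positions >= ref_end)).sum())
            assert outside == n_outside_oracle
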
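"""Gene models and neutral-reference site masks.

Two site classes serve as local neutral references for enhancer divergence:
fourfold-degenerate third codon positions (d4) and intronic positions with the
first intron removed (di), both taken from the longest annotated isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def fourfold_prefixes(table=standard_dna_table) -> frozenset[str]:
    """Dinucleotide codon prefixes whose four third-base completions are synonymous.

    Under the standard code these are the 8 fourfold families
    (GC, CG, GG, CT, CC, TC, AC, GT → Ala, Arg, Gly, Leu, Pro, Ser, Thr, Val).
    """
    prefixes = []
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = set()
            ok = True
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    ok = False
                    break
                aas.add(table.forward_table[codon])
            if ok and len(aas) == 1:
                prefixes.append(b1 + b2)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = fourfold_prefixes()
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class InvalidCdsError(ValueError):
    """Raised when a gene's longest-isoform CDS cannot be scanned for degeneracy."""

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}")


@dataclass
class Isoform:
    isoform_id: str
    exons: list  # [(start, end)] genomic, 0-based half-open, sorted, non-overlapping
    cds: list    # [(start, end)] genomic CDS sub-ranges, sorted

    def __post_init__(self):
        for name, ranges in (("exons", self.exons), ("cds", self.cds)):
            prev_end = -1
            for s, e in ranges:
                if e <= s:
                    raise ValueError(f"{self.isoform_id}: empty {name} range ({s},{e})")
                if s < prev_end:
                    raise ValueError(f"{self.isoform_id}: overlapping/unsorted {name}")
                prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list:
        """Genomic intron intervals between consecutive exons (left to right)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    isoforms: list
    has_one2one_ortholog: dict = field(default_factory=dict)  # species -> bool
    essential: bool | None = None
    expression: np.ndarray | None = None  # per-tissue signal vector

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.isoforms:
            raise ValueError(f"{self.gene_id}: at least one isoform required")

    @property
    def start(self) -> int:
        return min(iso.exons[0][0] for iso in self.isoforms)

    @property
    def end(self) -> int:
        return max(iso.exons[-1][1] for iso in self.isoforms)

    @property
    def longest_isoform(self) -> Isoform:
        """Isoform with the greatest summed exon length.

        Ties broken by longer CDS, then lexicographically smaller isoform id.
        """
        return min(
            self.isoforms,
            key=lambda iso: (-iso.exonic_length, -iso.cds_length, iso.isoform_id),
        )

    def orthologous_in(self, species: str) -> bool:
        return bool(self.has_one2one_ortholog.get(species, False))


@dataclass
class SiteMask:
    """Sorted genomic positions of one neutral-reference site class for one gene."""

    gene_id: str
    chrom: str
    site_class: str  # 'fourfold' | 'intron'
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("mask positions must be strictly increasing")

    def __len__(self):
        return self.positions.size

    def to_bed_intervals(self) -> list:
        """Collapse consecutive positions into (start, end) half-open runs."""
        if self.positions.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.positions) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [self.positions.size - 1]])
        return [
            (int(self.positions[i]), int(self.positions[j]) + 1)
            for i, j in zip(starts, ends)
        ]


def _cds_genomic_positions(iso: Isoform, strand: str) -> np.ndarray:
    """Genomic position of every CDS base in transcription (5'→3') order."""
    parts = [np.arange(s, e, dtype=np.int64) for s, e in iso.cds]
    pos = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    return pos[::-1] if strand == "-" else pos


def extract_cds_sequence(gene: GeneModel, genome: dict) -> str:
    """Spliced CDS of the longest isoform, reading strand, uppercase."""
    iso = gene.longest_isoform
    chrom_seq = genome[gene.chrom]
    raw = "".join(str(chrom_seq[s:e]) for s, e in iso.cds).upper()
    return reverse_complement(raw) if gene.strand == "-" else raw


def fourfold_sites(gene: GeneModel, genome: dict) -> SiteMask:
    """Genomic positions of fourfold-degenerate third codon positions.

    The codon is classified from the reference (mouse) sequence alone: the
    third position of a codon is fourfold degenerate when all four third-base
    choices encode the same amino acid. A terminal stop codon is excluded from
    scanning; codons containing non-ACGT symbols are skipped.

    Raises
    ------
    InvalidCdsError
        if the longest isoform has no CDS, its length is not a multiple of 3,
        or it contains a premature (internal) stop codon.
    """
    iso = gene.longest_isoform
    cds = extract_cds_sequence(gene, genome)
    if len(cds) == 0:
        raise InvalidCdsError(gene.gene_id, "no annotated CDS")
    if len(cds) % 3 != 0:
        raise InvalidCdsError(gene.gene_id, "CDS length not a multiple of 3")

    n_codons = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    scan = codons[:-1] if codons[-1] in STOP_CODONS else codons
    for i, codon in enumerate(scan):
        if codon in STOP_CODONS:
            raise InvalidCdsError(gene.gene_id, f"premature stop codon at codon {i}")

    pos_tx_order = _cds_genomic_positions(iso, gene.strand)
    third_positions = []
    for i, codon in enumerate(scan):
        if any(b not in "ACGT" for b in codon):
            continue  # ambiguity codes: skip codon
        if codon[:2] in FOURFOLD_PREFIXES:
            third_positions.append(pos_tx_order[3 * i + 2])
    return SiteMask(
        gene.gene_id, gene.chrom, "fourfold", np.sort(np.array(third_positions, dtype=np.int64))
    )


def intron_sites(gene: GeneModel) -> SiteMask:
    """Genomic positions of all introns of the longest isoform except the first.

    "First" is the 5'-most intron in transcription order (strand-aware): the
    leftmost intron for plus-strand genes, the rightmost for minus-strand
    genes. Intronless and single-intron genes yield an empty mask — such genes
    carry only the fourfold neutral reference.
    """
    iso = gene.longest_isoform
    introns = iso.introns()
    if len(introns) <= 1:
        return SiteMask(gene.gene_id, gene.chrom, "intron", np.empty(0, dtype=np.int64))
    kept = introns[1:] if gene.strand == "+" else introns[:-1]
    pos = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in kept])
    return SiteMask(gene.gene_id, gene.chrom, "intron", np.sort(pos))


def first_intron_span(gene: GeneModel) -> tuple | None:
    """The removed first intron's (start, end), or None if <2 introns."""
    introns = gene.longest_isoform.introns()
    if len(introns) <= 1:
        return introns[0] if (introns and gene.strand == "+") else (introns[0] if introns else None)
    return introns[0] if gene.strand == "+" else introns[-1]


def project_mask_to_alignment(mask: SiteMask, block) -> tuple:
    """Alignment columns of ``block`` whose reference coordinate is in ``mask``.

    Columns where any aligned species carries a gap are dropped. Mask positions
    outside the block are ignored but counted.

    Returns
    -------
    (columns, n_outside) : (np.ndarray of column indices, int)
    """
    if block.chrom != mask.chrom:
        return np.empty(0, dtype=np.int64), mask.positions.size
    ref_coords = block.reference_coordinates()  # -1 at ref-gap columns
    inside = (mask.positions >= block.start) & (mask.positions < block.ref_end)
    n_outside = int(mask.positions.size - inside.sum())
    wanted = mask.positions[inside]
    # map ref coordinate -> column index
    valid = ref_coords >= 0
    col_of = np.full(block.ref_end - block.start, -1, dtype=np.int64)
    col_of[ref_coords[valid] - block.start] = np.flatnonzero(valid)
    cols = col_of[wanted - block.start]
    cols = cols[cols >= 0]
    gapless = ~block.any_gap_columns()
    cols = cols[gapless[cols]]
    return np.sort(cols), n_outside
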
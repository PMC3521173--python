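"""Synthetic genomes with known selection ground truth.

The generator lays out gene models and tissue-labelled enhancers on one
chromosome, draws an ancestral sequence, rewrites gene CDS spans as valid open
reading frames, and evolves three descendant sequences (mouse, rat, human)
along the unrooted three-taxon tree under GTR + discrete gamma. Every enhancer
carries a hidden selection class — neutral, purifying, or positive — realized
as a rate multiplier on its sites; an optional GC-fixation bias multiplies all
substitution rates into G or C (the generator's stand-in for GC-biased gene
conversion). The true class, multiplier and per-site mouse-lineage
substitution events are recorded so downstream estimates can be checked
against ground truth.

Defaults emulate a rodent-primate comparison: mouse and rat lineage lengths of
0.09 and 0.11 substitutions/site (neutral mouse-rat distance 0.20), a human
lineage of 0.30, mildly GC-poor base composition, transition-rich
exchangeabilities, gamma shape 1.0 with 5 categories, enhancers of 0.8-2 kb
near multi-exon genes, and purifying/positive multipliers of 0.5 and 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import io as eio
from .covariates import classify_essentiality
from .intervals import TISSUES, EnhancerRecord
from .model import GTRModel, BASE_INDEX
from .sites import GeneModel, Isoform

logger = logging.getLogger(__name__)

SELECTION_CLASSES = ("neutral", "purifying", "positive")

# sub-stream domains (entropy = [seed, domain, index]) so adding features
# never reshuffles existing ones
_D_GENE, _D_ENH, _D_COV, _D_ANC, _D_BRANCH, _D_CAT, _D_RECOMB, _D_NOISE = range(1, 9)


class PlacementError(RuntimeError):
    """Features do not fit on the configured chromosome."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 60
    n_enhancers_per_tissue: dict = field(
        default_factory=lambda: {t: 50 for t in TISSUES}
    )
    chrom_name: str = "chr1"
    chrom_length: int | None = None  # None: sized to fit the layout
    tree_branch_lengths: dict = field(
        default_factory=lambda: {"mouse": 0.09, "rat": 0.11, "human": 0.30}
    )
    gtr_exchangeabilities: tuple = (1.0, 4.0, 0.8, 1.2, 4.5, 1.0)  # AC AG AT CG CT GT
    base_frequencies: tuple = (0.29, 0.21, 0.21, 0.29)  # A C G T
    gamma_shape: float = 1.0
    n_gamma_categories: int = 5
    selection_multiplier_by_class: dict = field(
        default_factory=lambda: {"neutral": 1.0, "purifying": 0.5, "positive": 2.0}
    )
    #: class mix per enhancer; may also be a {tissue: {class: prob}} mapping
    class_probabilities: dict = field(
        default_factory=lambda: {"neutral": 0.6, "purifying": 0.25, "positive": 0.15}
    )
    gc_fixation_bias: float = 0.0
    #: rate multiplier on CDS positions other than fourfold-degenerate third
    #: positions (purifying selection on coding sequence, so reading frames
    #: rarely acquire premature stops); fourfold sites always evolve at rate 1
    cds_constraint_multiplier: float = 0.05
    #: lognormal (mu, sigma) of a gene's per-tissue expression signal level
    expression_distribution: tuple = (5.6, 0.9)
    n_expression_tissues: int = 61
    essential_fraction: float = 0.35
    phenotype_documented_fraction: float = 0.8
    #: fraction of enhancers duplicated at identical coordinates into a second
    #: tissue, so consolidation and pleiotropy are exercised
    pleiotropic_fraction: float = 0.10
    ortholog_fraction: float = 0.9
    enhancer_length_range: tuple = (800, 2000)
    exon_count_range: tuple = (5, 10)
    exon_length_range: tuple = (130, 280)
    intron_length_range: tuple = (250, 1200)
    utr_length_range: tuple = (20, 60)
    intergenic_gap_range: tuple = (500, 3000)
    intronless_fraction: float = 0.08
    single_intron_fraction: float = 0.10
    second_isoform_fraction: float = 0.2
    recomb_window_size: int = 50_000
    maf_block_length: int = 100_000
    gap_fraction: float = 0.0
    ambiguity_fraction: float = 0.0

    def __post_init__(self):
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1 (tolerance 1e-9)")
        if any(t < 0 for t in self.tree_branch_lengths.values()):
            raise ValueError("branch lengths must be nonnegative")
        if any(m <= 0 for m in self.selection_multiplier_by_class.values()):
            raise ValueError("selection multipliers must be positive")
        if self.gc_fixation_bias < 0:
            raise ValueError("gc_fixation_bias must be >= 0")
        if self.n_gamma_categories < 1:
            raise ValueError("n_gamma_categories must be >= 1")
        if not 0 <= self.essential_fraction <= 1:
            raise ValueError("essential_fraction must lie in [0, 1]")
        unknown = set(self.n_enhancers_per_tissue) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissue labels {sorted(unknown)}")

    def model(self) -> GTRModel:
        return GTRModel(
            np.asarray(self.gtr_exchangeabilities, dtype=float),
            np.asarray(self.base_frequencies, dtype=float),
            self.gamma_shape,
            self.n_gamma_categories,
        )

    def class_probs_for(self, tissue: str) -> dict:
        cp = self.class_probabilities
        if cp and isinstance(next(iter(cp.values())), dict):
            return cp[tissue]
        return cp

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in (
            "gtr_exchangeabilities", "base_frequencies", "expression_distribution",
            "enhancer_length_range", "exon_count_range", "exon_length_range",
            "intron_length_range", "utr_length_range", "intergenic_gap_range",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data."""

    enhancers: pd.DataFrame  # enh_id, chrom, start, end, tissue, sel_class, multiplier
    gene_covariates: pd.DataFrame
    ancestral: np.ndarray | None = None  # base codes over the chromosome
    sequences: dict | None = None        # species -> base codes
    mouse_substituted: np.ndarray | None = None  # bool per site (vs ancestor)


@dataclass
class Annotation:
    genes: list
    enhancer_records: list
    covariates: pd.DataFrame
    recombination: pd.DataFrame
    truth: SyntheticTruth
    chrom: str
    chrom_length: int


def _rng(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, domain, index]))


# ----------------------------------------------------------- annotation ----

def _make_gene(config: SimulationConfig, index: int, start: int, rng) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    u = rng.random()
    if u < config.intronless_fraction:
        n_exons = 1
    elif u < config.intronless_fraction + config.single_intron_fraction:
        n_exons = 2
    else:
        n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
    exon_lens = rng.integers(*config.exon_length_range, endpoint=True, size=n_exons)
    if n_exons <= 2:
        # intronless/single-intron genes still carry a full-length ORF: scale
        # exons so total coding length matches multi-exon architectures
        scale = int(round(np.mean(config.exon_count_range) / n_exons))
        exon_lens = exon_lens * max(1, scale)
    intron_lens = rng.integers(*config.intron_length_range, endpoint=True, size=max(0, n_exons - 1))
    utr5, utr3 = rng.integers(*config.utr_length_range, endpoint=True, size=2)

    # transcription-order CDS chunks: exon lengths minus the UTR ends, trimmed
    # so the total is a multiple of 3 (trim goes to the 3' UTR)
    cds_lens = exon_lens.copy()
    cds_lens[0] -= utr5
    cds_lens[-1] -= utr3
    if np.any(cds_lens <= 0):
        cds_lens = np.maximum(cds_lens, 9)
    excess = int(cds_lens.sum()) % 3
    cds_lens[-1] -= excess
    utr3 += excess
    exon_lens = cds_lens.copy()
    exon_lens[0] += utr5
    exon_lens[-1] += utr3

    # genomic layout left to right; transcription order depends on strand
    tx_exons = list(exon_lens)
    tx_introns = list(intron_lens)
    if strand == "-":
        tx_exons = tx_exons[::-1]
        tx_introns = tx_introns[::-1]
    exons, cds = [], []
    cursor = start
    for i, ex_len in enumerate(tx_exons):
        exons.append((cursor, cursor + int(ex_len)))
        cursor += int(ex_len)
        if i < len(tx_introns):
            cursor += int(tx_introns[i])
    # CDS: trim UTR5 at the transcription start, UTR3 at the transcription end
    first_i, last_i = (0, len(exons) - 1) if strand == "+" else (len(exons) - 1, 0)
    for i, (s, e) in enumerate(exons):
        cs, ce = s, e
        if i == first_i:
            cs, ce = (s + int(utr5), e) if strand == "+" else (s, e - int(utr5))
        if i == last_i:
            cs, ce = (cs, ce - int(utr3)) if strand == "+" else (cs + int(utr3), ce)
        if ce > cs:
            cds.append((cs, ce))

    isoforms = [Isoform(f"g{index:04d}.t1", exons, sorted(cds))]
    if len(exons) >= 3 and rng.random() < config.second_isoform_fraction:
        # exon-skipping isoform: shorter by construction, never the longest
        kept = exons[:1] + exons[2:]
        kept_cds = [c for c in cds if not (exons[1][0] <= c[0] < exons[1][1])]
        isoforms.append(Isoform(f"g{index:04d}.t2", kept, sorted(kept_cds)))

    orth = rng.random() < config.ortholog_fraction
    return GeneModel(
        gene_id=f"g{index:04d}",
        chrom=config.chrom_name,
        strand=strand,
        isoforms=isoforms,
        has_one2one_ortholog={"rat": orth, "human": orth},
    )


def _gene_covariates(config: SimulationConfig, gene_ids: list) -> pd.DataFrame:
    non_essential_vocab = ("coat_color", "behavioral", "skeletal", "metabolic")
    mu, sigma = config.expression_distribution
    rows = []
    for i, gid in enumerate(gene_ids):
        rng = _rng(config.seed, _D_COV, i)
        if rng.random() < config.phenotype_documented_fraction:
            if rng.random() < config.essential_fraction:
                terms = [str(rng.choice(["premature_death", "infertility"]))]
            else:
                terms = [str(rng.choice(non_essential_vocab))]
        else:
            terms = []
        level = rng.lognormal(mu, sigma)
        signals = level * rng.lognormal(0.0, 0.25, size=config.n_expression_tissues)
        row = {
            "gene_id": gid,
            "phenotypes": ",".join(terms),
            "essentiality": classify_essentiality(terms),
        }
        row.update({f"expr_{k + 1}": signals[k] for k in range(config.n_expression_tissues)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out genes, enhancers, covariates and recombination windows.

    Genes and enhancers are interleaved left to right with random intergenic
    gaps, so features never overlap except deliberately duplicated enhancers
    (identical coordinates in a second tissue, exercising consolidation).
    Raises PlacementError when a fixed ``chrom_length`` cannot hold the layout.
    """
    tissue_quota = [
        t for t in TISSUES for _ in range(config.n_enhancers_per_tissue.get(t, 0))
    ]
    layout_rng = _rng(config.seed, _D_ENH, 0)
    layout_rng.shuffle(tissue_quota)
    n_enh = len(tissue_quota)
    per_slot = int(np.ceil(n_enh / max(1, config.n_genes)))

    genes, records = [], []
    truth_rows = []
    cursor = 1000
    enh_i = 0
    for gi in range(config.n_genes):
        g_rng = _rng(config.seed, _D_GENE, gi)
        gene = _make_gene(config, gi, cursor, g_rng)
        genes.append(gene)
        cursor = gene.end + int(g_rng.integers(*config.intergenic_gap_range, endpoint=True))
        for _ in range(per_slot):
            if enh_i >= n_enh:
                break
            e_rng = _rng(config.seed, _D_ENH, enh_i + 1)
            length = int(e_rng.integers(*config.enhancer_length_range, endpoint=True))
            start = cursor
            end = start + length
            tissue = tissue_quota[enh_i]
            probs = config.class_probs_for(tissue)
            classes = list(probs)
            sel_class = str(e_rng.choice(classes, p=np.array([probs[c] for c in classes])))
            records.append(EnhancerRecord(config.chrom_name, start, end, tissue))
            truth_rows.append(
                {
                    "enh_id": f"e{enh_i:05d}",
                    "chrom": config.chrom_name,
                    "start": start,
                    "end": end,
                    "tissue": tissue,
                    "sel_class": sel_class,
                    "multiplier": config.selection_multiplier_by_class[sel_class],
                }
            )
            if e_rng.random() < config.pleiotropic_fraction:
                others = [t for t in TISSUES if t != tissue]
                twin = str(e_rng.choice(others))
                records.append(EnhancerRecord(config.chrom_name, start, end, twin))
                truth_rows.append(
                    {**truth_rows[-1], "enh_id": f"e{enh_i:05d}p", "tissue": twin}
                )
            cursor = end + int(e_rng.integers(*config.intergenic_gap_range, endpoint=True))
            enh_i += 1

    if enh_i < n_enh:
        raise PlacementError(
            f"could not place all enhancers: {n_enh - enh_i} left after {config.n_genes} gene slots"
        )
    chrom_length = cursor + 1000
    if config.chrom_length is not None:
        if config.chrom_length < chrom_length:
            raise PlacementError(
                f"chrom_length={config.chrom_length} too short for layout needing {chrom_length} bp"
            )
        chrom_length = config.chrom_length

    covariates = _gene_covariates(config, [g.gene_id for g in genes])

    recomb_rng = _rng(config.seed, _D_RECOMB, 0)
    starts = np.arange(0, chrom_length, config.recomb_window_size)
    recomb = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "start": starts,
            "end": np.minimum(starts + config.recomb_window_size, chrom_length),
            "rate": recomb_rng.gamma(2.0, 0.3, size=starts.size),
        }
    )

    truth = SyntheticTruth(
        enhancers=pd.DataFrame(
            truth_rows,
            columns=["enh_id", "chrom", "start", "end", "tissue", "sel_class", "multiplier"],
        ),
        gene_covariates=covariates,
    )
    return Annotation(genes, records, covariates, recomb, truth, config.chrom_name, chrom_length)


# ------------------------------------------------------------ evolution ----

_SENSE_CODONS = None


def _sense_codon_sampler(freqs: np.ndarray):
    """Codons excluding stops, weighted by the product of base frequencies."""
    from .sites import STOP_CODONS

    codons, weights = [], []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                c = b1 + b2 + b3
                if c in STOP_CODONS:
                    continue
                codons.append(c)
                weights.append(
                    freqs[BASE_INDEX[b1]] * freqs[BASE_INDEX[b2]] * freqs[BASE_INDEX[b3]]
                )
    w = np.array(weights)
    return codons, w / w.sum()


def _write_orf(seq: np.ndarray, gene: GeneModel, config: SimulationConfig, rng) -> None:
    """Overwrite the gene's longest-isoform CDS with a valid reading frame."""
    from .sites import _cds_genomic_positions

    iso = gene.longest_isoform
    pos = _cds_genomic_positions(iso, gene.strand)  # transcription order
    n = pos.size
    if n < 9 or n % 3:
        raise ValueError(f"{gene.gene_id}: CDS length {n} unusable")
    codons, probs = _sense_codon_sampler(np.asarray(config.base_frequencies))
    n_codons = n // 3
    body = rng.choice(len(codons), size=n_codons - 2, p=probs)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    cds = "ATG" + "".join(codons[i] for i in body) + stop
    coding = np.array([BASE_INDEX[b] for b in cds], dtype=np.uint8)
    if gene.strand == "-":
        coding = 3 - coding  # complement; pos already runs 3'->5' genomically
    seq[pos] = coding


def _site_annotations(config, annotation, ancestral):
    """Per-site (multiplier id, multiplier values) over the chromosome.

    Enhancer spans carry their class multiplier; CDS positions of each gene's
    longest isoform carry the coding-constraint multiplier except the third
    positions of fourfold-degenerate codons (classified on the ancestral
    sequence), which stay neutral so d4 is a valid neutral reference.
    """
    from .sites import FOURFOLD_PREFIXES, _cds_genomic_positions

    mults = [1.0]
    mult_index = {1.0: 0}
    mult_id = np.zeros(annotation.chrom_length, dtype=np.uint8)

    def idx_for(m: float) -> int:
        if m not in mult_index:
            mult_index[m] = len(mults)
            mults.append(m)
        return mult_index[m]

    for row in annotation.truth.enhancers.itertuples(index=False):
        mult_id[row.start : row.end] = idx_for(float(row.multiplier))

    cm = config.cds_constraint_multiplier
    if cm != 1.0:
        cidx = idx_for(cm)
        bases = "ACGT"
        for gene in annotation.genes:
            pos = _cds_genomic_positions(gene.longest_isoform, gene.strand)
            tx = ancestral[pos]
            if gene.strand == "-":
                tx = 3 - tx
            for i in range(pos.size // 3):
                prefix = bases[tx[3 * i]] + bases[tx[3 * i + 1]]
                codon_pos = pos[3 * i : 3 * i + 3]
                if prefix in FOURFOLD_PREFIXES:
                    mult_id[codon_pos[:2]] = cidx
                else:
                    mult_id[codon_pos] = cidx
    return mult_id, np.array(mults)


def _transition_tables(model: GTRModel, t: float, mults: np.ndarray, gc_factor: float) -> np.ndarray:
    """Cumulative transition probabilities, shape (n_mult * K * 4, 4)."""
    q = model.rate_matrix(gc_factor=gc_factor)
    rates = model.category_rates()
    tables = []
    for m in mults:
        for r in rates:
            p = expm(q * (t * m * r))
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            tables.append(np.cumsum(p, axis=1))
    flat = np.concatenate(tables, axis=0)  # (n_mult*K*4, 4)
    flat[:, -1] = 1.0 + 1e-12
    return flat


def _evolve_branch(parent: np.ndarray, key_base: np.ndarray, cum_flat: np.ndarray, rng) -> np.ndarray:
    key = key_base + parent
    u = rng.random(parent.size)
    child = np.empty_like(parent)
    for k in np.unique(key):
        m = key == k
        child[m] = np.searchsorted(cum_flat[k], u[m], side="left").astype(np.uint8)
    return child


def evolve_alignments(config: SimulationConfig, annotation: Annotation):
    """Evolve mouse/rat/human sequences and assemble alignment blocks.

    The ancestral sequence sits at the mouse-rat ancestor node of the unrooted
    three-taxon tree; each lineage evolves independently under the scaled GTR
    generator with per-site discrete-gamma rates, per-site enhancer-class
    multipliers, and (when ``gc_fixation_bias`` > 0) off-diagonal rates into
    G/C multiplied by (1 + bias) before rescaling. True mouse-lineage events
    (mouse base != ancestral base) are recorded in the truth object.

    Returns (AlignmentSet, SyntheticTruth).
    """
    L = annotation.chrom_length
    model = config.model()
    freqs = np.asarray(config.base_frequencies)

    anc_rng = _rng(config.seed, _D_ANC, 0)
    ancestral = anc_rng.choice(4, size=L, p=freqs).astype(np.uint8)
    for gi, gene in enumerate(annotation.genes):
        _write_orf(ancestral, gene, config, _rng(config.seed, _D_ANC, gi + 1))

    cat_rng = _rng(config.seed, _D_CAT, 0)
    K = config.n_gamma_categories
    cat = cat_rng.integers(0, K, size=L).astype(np.uint8)
    mult_id, mults = _site_annotations(config, annotation, ancestral)
    key_base = (mult_id.astype(np.int64) * K + cat) * 4
    gc_factor = 1.0 + config.gc_fixation_bias

    sequences = {}
    for bi, (sp, t) in enumerate(sorted(config.tree_branch_lengths.items())):
        if t == 0:
            sequences[sp] = ancestral.copy()
            continue
        cum = _transition_tables(model, t, mults, gc_factor)
        sequences[sp] = _evolve_branch(
            ancestral, key_base, cum, _rng(config.seed, _D_BRANCH, bi)
        )

    noise_rng = _rng(config.seed, _D_NOISE, 0)
    for sp in ("rat", "human"):
        if config.gap_fraction > 0:
            hit = noise_rng.random(L) < config.gap_fraction
            sequences[sp][hit] = 5
        if config.ambiguity_fraction > 0:
            hit = noise_rng.random(L) < config.ambiguity_fraction
            sequences[sp][hit] = 4

    truth = annotation.truth
    truth.ancestral = ancestral
    truth.sequences = sequences
    truth.mouse_substituted = sequences["mouse"] != ancestral

    blocks = []
    for start in range(0, L, config.maf_block_length):
        end = min(start + config.maf_block_length, L)
        blocks.append(
            eio.AlignmentBlock(
                annotation.chrom,
                start,
                {sp: eio.decode_sequence(seq[start:end]) for sp, seq in sequences.items()},
            )
        )
    return eio.AlignmentSet(blocks), truth


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: annotation + evolved alignments + truth."""
    annotation = simulate_annotation(config)
    alignments, truth = evolve_alignments(config, annotation)
    return annotation, alignments, truth


def truth_classes_for_regions(regions, truth_enhancers: pd.DataFrame) -> pd.DataFrame:
    """Map consolidated regions to their true selection class by overlap.

    The generator never overlaps enhancers of different classes, so every
    region's member enhancers share one class; a mixed region raises.
    """
    rows = []
    for r in regions:
        members = truth_enhancers[
            (truth_enhancers["chrom"] == r.chrom)
            & (truth_enhancers["start"] < r.end)
            & (truth_enhancers["end"] > r.start)
        ]
        classes = set(members["sel_class"])
        if len(classes) != 1:
            raise ValueError(f"region {r.region_id}: ambiguous truth classes {classes}")
        rows.append(
            {
                "region_id": r.region_id,
                "sel_class": classes.pop(),
                "multiplier": float(members["multiplier"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------- analytic expectations ---

def pairwise_joint(config: SimulationConfig, species=("mouse", "rat"), multiplier: float = 1.0) -> np.ndarray:
    """Expected joint base distribution of two extant species (4x4)."""
    model = config.model()
    pi = np.asarray(config.base_frequencies)
    q = model.rate_matrix(gc_factor=1.0 + config.gc_fixation_bias)
    rates = model.category_rates()
    ta = config.tree_branch_lengths[species[0]] * multiplier
    tb = config.tree_branch_lengths[species[1]] * multiplier
    joint = np.zeros((4, 4))
    for r in rates:
        pa = expm(q * ta * r)
        pb = expm(q * tb * r)
        joint += (pa.T * pi) @ pb / len(rates)
    return joint


def expected_mismatch_fraction(config: SimulationConfig, species=("mouse", "rat"), multiplier: float = 1.0) -> float:
    joint = pairwise_joint(config, species, multiplier)
    return float(1.0 - np.trace(joint))


def expected_at_to_gc_ratio(config: SimulationConfig, multiplier: float = 1.0) -> float:
    """Expected N_AT->GC / N_substituted_AT under the generator's own rates,
    for sites polarized by strict rat==human agreement."""
    model = config.model()
    pi = np.asarray(config.base_frequencies)
    q = model.rate_matrix(gc_factor=1.0 + config.gc_fixation_bias)
    rates = model.category_rates()
    tm = config.tree_branch_lengths["mouse"] * multiplier
    tr = config.tree_branch_lengths["rat"] * multiplier
    th = config.tree_branch_lengths["human"] * multiplier
    num = den = 0.0
    for r in rates:
        pm, pr, ph = expm(q * tm * r), expm(q * tr * r), expm(q * th * r)
        for a in (0, 3):  # ancestrally A or T
            w = pi[a] * pr[a, a] * ph[a, a] / len(rates)
            num += w * (pm[a, 1] + pm[a, 2])
            den += w * (1.0 - pm[a, a])
    return num / den


# ------------------------------------------------------------- writers -----

def write_dataset(outdir, config: SimulationConfig, annotation: Annotation, alignments, truth: SyntheticTruth) -> dict:
    """Write the full synthetic dataset as plain-text files; returns paths."""
    out = eio.ensure_dir(outdir)
    paths = {}
    by_tissue = {}
    for rec in annotation.enhancer_records:
        by_tissue.setdefault(rec.tissue, []).append(rec)
    for tissue, recs in sorted(by_tissue.items()):
        p = out / f"enhancers_{tissue}.bed"
        eio.write_enhancer_bed(recs, p)
        paths[f"bed_{tissue}"] = p
    paths["genes"] = out / "genes.gtf"
    eio.write_gene_models_gtf(annotation.genes, paths["genes"])
    paths["covariates"] = out / "covariates.tsv"
    eio.write_tsv(annotation.covariates, paths["covariates"])
    paths["recombination"] = out / "recombination.tsv"
    eio.write_tsv(annotation.recombination, paths["recombination"])
    paths["truth"] = out / "truth_enhancers.tsv"
    eio.write_tsv(truth.enhancers, paths["truth"])
    paths["genome"] = out / "mouse_genome.fa"
    eio.write_fasta(
        {annotation.chrom: eio.decode_sequence(truth.sequences["mouse"])}, paths["genome"]
    )
    paths["maf"] = out / "alignment.maf"
    eio.write_maf(alignments, paths["maf"], {annotation.chrom: annotation.chrom_length})
    paths["config"] = out / "config.json"
    config.to_json(paths["config"])
    return paths
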
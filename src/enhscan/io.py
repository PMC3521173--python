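"""File formats and in-memory alignment containers.

Everything is plain text: BED for enhancers and masks, GTF-like gene models,
TSV covariate/recombination/truth tables, MAF and per-region aligned FASTA for
alignments. Coordinates are 0-based half-open throughout (BED convention); the
GTF-like writer converts to the format's 1-based inclusive coordinates on
output and back on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sites import GeneModel, Isoform

REF_SPECIES = "mouse"

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_GAP = 5
_ENC[ord("-")] = _GAP

_DEC = np.frombuffer(b"ACGTN-", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; ambiguity codes -> 4; gap '-' -> 5 (uint8)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


@dataclass
class AlignmentBlock:
    """One gapped alignment block anchored on reference (mouse) coordinates."""

    chrom: str
    start: int  # reference coordinate of the first non-gap reference base
    seqs: dict  # species -> aligned string (may contain '-')
    _codes: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if REF_SPECIES not in self.seqs:
            raise ValueError(f"block must include the reference species {REF_SPECIES!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values())))

    @property
    def species(self) -> list:
        return sorted(self.seqs)

    def codes(self, species: str) -> np.ndarray:
        if self._codes is None:
            self._codes = {}
        if species not in self._codes:
            self._codes[species] = encode_sequence(self.seqs[species])
        return self._codes[species]

    def reference_coordinates(self) -> np.ndarray:
        """Reference genomic coordinate per column; -1 where the reference is gapped."""
        ref = self.codes(REF_SPECIES)
        nongap = ref != _GAP
        coords = np.full(ref.size, -1, dtype=np.int64)
        coords[nongap] = self.start + np.arange(nongap.sum())
        return coords

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the reference span covered by this block."""
        return self.start + int((self.codes(REF_SPECIES) != _GAP).sum())

    def any_gap_columns(self) -> np.ndarray:
        out = np.zeros(self.n_columns, dtype=bool)
        for sp in self.seqs:
            out |= self.codes(sp) == _GAP
        return out

    def column_codes(self, columns: np.ndarray, species: list) -> np.ndarray:
        """Stacked base codes, shape (n_species, n_columns_selected)."""
        return np.stack([self.codes(sp)[columns] for sp in species])


class AlignmentSet:
    """Blocks of one alignment, sorted by reference position, binary-searchable."""

    def __init__(self, blocks):
        self.blocks = sorted(blocks, key=lambda b: (b.chrom, b.start))
        self._starts = {}
        for b in self.blocks:
            self._starts.setdefault(b.chrom, ([], []))
            self._starts[b.chrom][0].append(b.start)
            self._starts[b.chrom][1].append(b)

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """Blocks whose reference span intersects [start, end)."""
        if chrom not in self._starts:
            return []
        starts, blocks = self._starts[chrom]
        i = np.searchsorted(starts, start, side="right")
        out = []
        if i > 0 and blocks[i - 1].ref_end > start:
            out.append(blocks[i - 1])
        j = i
        while j < len(blocks) and blocks[j].start < end:
            out.append(blocks[j])
            j += 1
        return out

    def __len__(self):
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


# ---------------------------------------------------------------- MAF ------

def write_maf(blocks, path, chrom_sizes: dict | None = None) -> None:
    """Write blocks as MAF; non-reference rows reuse the reference coordinates
    (the simulator produces colinear, indel-free genomes)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for b in blocks:
            fh.write("a score=0.0\n")
            for sp in [REF_SPECIES] + [s for s in b.species if s != REF_SPECIES]:
                seq = b.seqs[sp]
                size = sum(c != "-" for c in seq)
                src_size = (chrom_sizes or {}).get(b.chrom, b.start + size)
                fh.write(
                    f"s {sp}.{b.chrom} {b.start} {size} + {src_size} {seq}\n"
                )
            fh.write("\n")


def read_maf(path) -> AlignmentSet:
    blocks = []
    seqs, chrom, start = {}, None, None
    with open(path) as fh:
        for line in fh:
            if line.startswith("a"):
                if seqs:
                    blocks.append(AlignmentBlock(chrom, start, seqs))
                seqs = {}
            elif line.startswith("s "):
                _, src, st, _size, strand, _src_size, text = line.split()
                sp, _, chr_ = src.partition(".")
                if sp == REF_SPECIES:
                    chrom, start = chr_, int(st)
                seqs[sp] = text
    if seqs:
        blocks.append(AlignmentBlock(chrom, start, seqs))
    return AlignmentSet(blocks)


def write_region_fasta(block: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for sp in block.species:
            fh.write(f">{sp} {block.chrom}:{block.start}\n{block.seqs[sp]}\n")


# ---------------------------------------------------------------- BED ------

def read_enhancer_bed(path, tissue: str | None = None):
    """Read a 4+-column BED of enhancer peaks; column 4 is the tissue label
    unless ``tissue`` overrides it."""
    from .intervals import EnhancerRecord

    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = tissue if tissue is not None else parts[3]
            records.append(EnhancerRecord(parts[0], int(parts[1]), int(parts[2]), label))
    return records


def write_enhancer_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.tissue}\n")


def write_mask_bed(mask, path) -> None:
    with open(path, "w") as fh:
        for s, e in mask.to_bed_intervals():
            fh.write(f"{mask.chrom}\t{s}\t{e}\t{mask.gene_id}:{mask.site_class}\n")


# ----------------------------------------------------- GTF-like models -----

def write_gene_models_gtf(genes, path) -> None:
    """Emit gene/exon/CDS lines, 1-based inclusive, with gene_id/transcript_id
    attributes and an ortholog flag per comparison species on the gene line."""
    with open(path, "w") as fh:
        for g in genes:
            orth = ";".join(
                f" ortholog_{sp} \"{int(v)}\"" for sp, v in sorted(g.has_one2one_ortholog.items())
            )
            fh.write(
                f"{g.chrom}\tenhscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";{orth}\n'
            )
            for iso in g.isoforms:
                for s, e in iso.exons:
                    fh.write(
                        f"{g.chrom}\tenhscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{iso.isoform_id}";\n'
                    )
                for s, e in iso.cds:
                    fh.write(
                        f"{g.chrom}\tenhscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{iso.isoform_id}";\n'
                    )


def _attrs(field8: str) -> dict:
    out = {}
    for part in field8.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gene_models_gtf(path) -> list:
    genes: dict[str, dict] = {}
    order = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, s1, e1, _score, strand, _frame, rest = line.rstrip("\n").split("\t")
            attrs = _attrs(rest)
            gid = attrs["gene_id"]
            if gid not in genes:
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "orth": {},
                    "iso": {},
                }
                order.append(gid)
            entry = genes[gid]
            if feat == "gene":
                for k, v in attrs.items():
                    if k.startswith("ortholog_"):
                        entry["orth"][k[len("ortholog_"):]] = bool(int(v))
            elif feat in ("exon", "CDS"):
                tid = attrs["transcript_id"]
                iso = entry["iso"].setdefault(tid, {"exon": [], "CDS": []})
                iso[feat].append((int(s1) - 1, int(e1)))
    out = []
    for gid in order:
        entry = genes[gid]
        isoforms = [
            Isoform(tid, sorted(v["exon"]), sorted(v["CDS"]))
            for tid, v in sorted(entry["iso"].items())
        ]
        out.append(
            GeneModel(gid, entry["chrom"], entry["strand"], isoforms, entry["orth"])
        )
    return out


# ---------------------------------------------------------------- FASTA ----

def write_fasta(seqs: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- TSVs -----

def write_tsv(df: pd.DataFrame, path, float_format="%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_recombination_tsv(path) -> pd.DataFrame:
    """Windows of per-region recombination rate: chrom, start, end, rate (cM/Mb)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "start", "end", "rate"}
    if not expected.issubset(df.columns):
        raise ValueError(f"recombination TSV needs columns {sorted(expected)}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
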
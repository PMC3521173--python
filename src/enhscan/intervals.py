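"""Enhancer interval consolidation, pleiotropy classification, nearest-gene
assignment and recombination-rate lookup.

Tissue-labelled enhancer peaks (forebrain FB, midbrain MB, limb LB, heart HT)
that overlap by at least one base pair are consolidated into a single region;
regions built from a single tissue's peaks are "specific", the rest
"pleiotropic". Each region is annotated with its closest gene (any gene) and,
separately, the closest gene carrying a one-to-one ortholog in the comparison
species — the gene whose neutral sites normalize the region's divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("FB", "MB", "LB", "HT")


@dataclass(frozen=True)
class EnhancerRecord:
    chrom: str
    start: int
    end: int
    tissue: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"enhancer record {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue label {self.tissue!r}; expected one of {TISSUES}")


@dataclass
class EnhancerRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    tissues: frozenset
    nearest_gene_id: str | None = None
    neutral_reference_gene_id: str | None = None
    recombination_rate: float | None = None
    member_indices: tuple = field(default_factory=tuple)

    @property
    def pleiotropy(self) -> str:
        return classify_pleiotropy(self)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def tissue_label(self) -> str:
        return ",".join(sorted(self.tissues))


def classify_pleiotropy(region) -> str:
    """'specific' iff the region derives from exactly one tissue's peaks."""
    if not region.tissues:
        raise ValueError("region has no tissue labels")
    return "specific" if len(region.tissues) == 1 else "pleiotropic"


def consolidate(records) -> list:
    """Merge overlapping peaks into non-overlapping regions (sweep line).

    Overlap means at least one shared base pair under half-open arithmetic;
    bookended peaks ([100,200) and [200,300)) are NOT merged. Output regions
    are the connected components of the overlap graph, each spanning the union
    of its members, carrying the union of member tissues, sorted by
    (chrom, start), with ids r0000, r0001, ... in that order.
    """
    records = list(records)
    for i, r in enumerate(records):
        if not isinstance(r, EnhancerRecord):
            raise TypeError(f"record {i} is not an EnhancerRecord")
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].start, records[i].end))
    regions = []
    cur = None  # [chrom, start, end, tissues, members]
    for i in order:
        r = records[i]
        if cur is not None and r.chrom == cur[0] and r.start < cur[2]:
            cur[2] = max(cur[2], r.end)
            cur[3].add(r.tissue)
            cur[4].append(i)
        else:
            if cur is not None:
                regions.append(cur)
            cur = [r.chrom, r.start, r.end, {r.tissue}, [i]]
    if cur is not None:
        regions.append(cur)
    return [
        EnhancerRegion(
            region_id=f"r{k:04d}",
            chrom=chrom,
            start=start,
            end=end,
            tissues=frozenset(tissues),
            member_indices=tuple(sorted(members)),
        )
        for k, (chrom, start, end, tissues, members) in enumerate(regions)
    ]


def _boundary_distance(a_start, a_end, b_start, b_end) -> int:
    """Gap between two half-open intervals; 0 if they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def assign_nearest_gene(region, genes, require_ortholog: str | None = None) -> str | None:
    """Gene id minimizing boundary-to-boundary distance to the region.

    ``require_ortholog`` restricts candidates to genes with a one-to-one
    ortholog in that species (e.g. 'rat'). Ties broken by smaller distance,
    then lower gene start, then lexicographic gene id. Returns None (logged)
    when no candidate exists on the region's chromosome.
    """
    best = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        if require_ortholog is not None and not g.orthologous_in(require_ortholog):
            continue
        d = _boundary_distance(region.start, region.end, g.start, g.end)
        key = (d, g.start, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    if best is None:
        logger.info("region %s: no candidate gene (ortholog filter: %s)", region.region_id, require_ortholog)
        return None
    return best[1]


def annotate_regions(regions, genes, ortholog_species: str = "rat") -> list:
    """Populate nearest_gene_id (any gene) and neutral_reference_gene_id
    (nearest gene with a one-to-one ortholog) on every region, in place."""
    for r in regions:
        r.nearest_gene_id = assign_nearest_gene(r, genes)
        r.neutral_reference_gene_id = assign_nearest_gene(r, genes, require_ortholog=ortholog_species)
    return regions


def attach_recombination(regions, rate_windows: pd.DataFrame) -> list:
    """Attach to each region the cM/Mb rate of the window containing its midpoint.

    Windows must tile each chromosome without overlap; overlapping windows are
    an error. Regions whose midpoint falls in no window keep rate None.
    """
    for chrom, grp in rate_windows.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].values[1:] < g["end"].values[:-1]).any():
            raise ValueError(f"overlapping recombination windows on {chrom}")
    by_chrom = {
        chrom: grp.sort_values("start")[["start", "end", "rate"]].to_numpy()
        for chrom, grp in rate_windows.groupby("chrom")
    }
    for r in regions:
        r.recombination_rate = None
        win = by_chrom.get(r.chrom)
        if win is None:
            continue
        mid = r.midpoint
        i = np.searchsorted(win[:, 0], mid, side="right") - 1
        if i >= 0 and win[i, 0] <= mid < win[i, 1]:
            r.recombination_rate = float(win[i, 2])
    return regions


def regions_to_frame(regions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "tissues": [r.tissue_label for r in regions],
            "pleiotropy": [r.pleiotropy for r in regions],
            "nearest_gene_id": [r.nearest_gene_id for r in regions],
            "neutral_reference_gene_id": [r.neutral_reference_gene_id for r in regions],
            "recombination_rate": [r.recombination_rate for r in regions],
        }
    )


def frame_to_regions(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EnhancerRegion(
                region_id=row.region_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                tissues=frozenset(str(row.tissues).split(",")),
                nearest_gene_id=None if pd.isna(row.nearest_gene_id) else row.nearest_gene_id,
                neutral_reference_gene_id=(
                    None if pd.isna(row.neutral_reference_gene_id) else row.neutral_reference_gene_id
                ),
                recombination_rate=(
                    None if pd.isna(row.recombination_rate) else float(row.recombination_rate)
                ),
            )
        )
    return out
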
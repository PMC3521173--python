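"""End-to-end orchestration: simulate -> consolidate -> sites -> divergence ->
classify -> gbgc -> covariates -> report, with a machine-readable manifest.

Every stage is a plain function over in-memory objects; ``run_all`` chains
them, writes each stage's TSV outputs under one directory, and reconciles
per-stage counts (in = out + excluded) in the manifest. Re-running with the
same config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .covariates import bin_medians, controlled_comparison, covariate_table, spearman
from .divergence import (
    NoUsableSitesError,
    fit_pairwise,
    patterns_for_mask,
    patterns_for_span,
)
from .gbgc import compare_groups, group_quartiles, polarity_table
from .intervals import annotate_regions, attach_recombination, consolidate, regions_to_frame
from .selection import run_selection_scan
from .sites import InvalidCdsError, fourfold_sites, intron_sites

logger = logging.getLogger(__name__)

PAIR_SPECIES = ("mouse", "rat")


@dataclass
class PipelineOptions:
    alpha: float = 0.05
    specific_only: bool = True
    ortholog_species: str = "rat"
    #: 'pooled' freezes the genome-wide neutral GTR+Gamma fit for every unit
    #: (only t optimized per unit); 'per-unit' ML-fits the model wherever a
    #: unit clears the usable-site threshold
    model_scope: str = "pooled"
    full_fit_min_sites: int = 200
    n_gamma_categories: int = 5


# ----------------------------------------------------------- stages --------

def build_regions(records, genes, recomb=None, ortholog_species="rat"):
    """Consolidate peaks, classify pleiotropy, assign genes and recombination."""
    regions = consolidate(records)
    annotate_regions(regions, genes, ortholog_species=ortholog_species)
    if recomb is not None:
        attach_recombination(regions, recomb)
    return regions


def build_masks(genes, genome, ortholog_species="rat"):
    """Fourfold and intron masks for every orthologous gene.

    Returns (masks, exclusions): masks maps gene_id -> {'fourfold': SiteMask,
    'intron': SiteMask}; exclusions is a list of (gene_id, reason code) for
    genes dropped from the fourfold reference.
    """
    masks, exclusions = {}, []
    for g in genes:
        if not g.orthologous_in(ortholog_species):
            exclusions.append((g.gene_id, "no_one2one_ortholog"))
            continue
        entry = {}
        try:
            entry["fourfold"] = fourfold_sites(g, genome)
        except InvalidCdsError as err:
            exclusions.append((g.gene_id, f"invalid_cds:{err.reason}"))
        entry["intron"] = intron_sites(g)
        if entry:
            masks[g.gene_id] = entry
    return masks, exclusions


def fit_pooled_model(alignments, masks, species=PAIR_SPECIES, n_categories=5):
    """Full GTR+Gamma ML fit on the pooled neutral (fourfold + intron) sites."""
    pooled = None
    for entry in masks.values():
        for mask in entry.values():
            if len(mask) == 0:
                continue
            pat = patterns_for_mask(alignments, mask, species)
            pooled = pat if pooled is None else pooled + pat
    if pooled is None or pooled.n_sites == 0:
        raise NoUsableSitesError("no neutral sites available for the pooled fit")
    est = fit_pairwise(pooled, n_categories=n_categories)
    return est.model, est


def compute_divergence(
    alignments, regions, masks, options: PipelineOptions | None = None
) -> tuple[pd.DataFrame, list]:
    """Per-unit divergence rows for enhancers and neutral references.

    One row per (unit_id, class): class 'enhancer' rows use the region span,
    'fourfold'/'intron' rows the gene masks. Unusable units are excluded with
    a reason code. Returns (divergence frame, exclusion list).
    """
    options = options or PipelineOptions()
    pooled_model, _ = fit_pooled_model(
        alignments, masks, PAIR_SPECIES, options.n_gamma_categories
    )
    per_unit_kwargs = (
        {"model": pooled_model}
        if options.model_scope == "pooled"
        else {"fallback_model": pooled_model, "full_fit_min_sites": options.full_fit_min_sites}
    )
    rows, exclusions = [], []

    def fit_unit(unit_id, klass, patterns):
        if patterns.n_sites == 0:
            exclusions.append((unit_id, klass, "no_usable_sites"))
            return
        est = fit_pairwise(patterns, n_categories=options.n_gamma_categories, **per_unit_kwargs)
        rows.append(
            {
                "unit_id": unit_id,
                "class": klass,
                "t": est.t,
                "n_sites": est.n_sites,
                "n_diff": est.n_diff,
                "alpha": est.model.gamma_shape,
                "converged": est.converged,
                "log_likelihood": est.log_likelihood,
            }
        )

    for r in regions:
        fit_unit(
            r.region_id, "enhancer",
            patterns_for_span(alignments, r.chrom, r.start, r.end, PAIR_SPECIES),
        )
    for gene_id, entry in masks.items():
        for klass, mask in entry.items():
            if len(mask) == 0:
                exclusions.append((gene_id, klass, "empty_mask"))
                continue
            fit_unit(gene_id, klass, patterns_for_mask(alignments, mask, PAIR_SPECIES))
    return pd.DataFrame(rows), exclusions


def gbgc_stage(regions, alignments, strict=True):
    """Per-region polarity counts plus per-tissue comparisons of the
    A/T->G/C ratio and of recombination rates."""
    pol = polarity_table(regions, alignments, strict=strict)
    ratio_by_tissue, recomb_by_tissue = {}, {}
    pol_idx = pol.set_index("region_id") if len(pol) else pol
    for r in regions:
        for tissue in r.tissues:
            if len(pol) and r.region_id in pol_idx.index:
                ratio_by_tissue.setdefault(tissue, []).append(
                    float(pol_idx.loc[r.region_id, "ratio"])
                )
            if r.recombination_rate is not None:
                recomb_by_tissue.setdefault(tissue, []).append(r.recombination_rate)
    comparisons = {
        "at_to_gc_ratio": (group_quartiles(ratio_by_tissue), compare_groups(ratio_by_tissue)),
        "recombination_rate": (group_quartiles(recomb_by_tissue), compare_groups(recomb_by_tissue)),
    }
    return pol, comparisons


def covariates_stage(regions_df, calls, gene_covariates, expression_mode="mean"):
    """Join covariates, run the pleiotropy/essentiality/expression contrasts
    and the bin-controlled tissue comparison."""
    cov = covariate_table(regions_df, gene_covariates, expression_mode=expression_mode)
    rates = calls[["region_id", "D", "ratio"]].drop_duplicates("region_id")
    cov = cov.merge(rates, on="region_id", how="left")

    results = {}
    usable = cov.dropna(subset=["D"])
    for metric in ("D", "ratio"):
        by_pleio = {
            k: g[metric].dropna().to_numpy() for k, g in usable.groupby("pleiotropy")
        }
        results[f"{metric}_by_pleiotropy"] = compare_groups(by_pleio)
        by_ess = {
            k: g[metric].dropna().to_numpy()
            for k, g in usable[usable["essentiality"] != "unknown"].groupby("essentiality")
        }
        results[f"{metric}_by_essentiality"] = compare_groups(by_ess)
    expr = usable.dropna(subset=["expression", "D"])
    if len(expr) >= 3 and expr["expression"].nunique() > 1 and expr["D"].nunique() > 1:
        rho, p = spearman(expr["expression"].to_numpy(), expr["D"].to_numpy())
        results["spearman_D_vs_expression"] = pd.DataFrame(
            [{"contrast": "D_vs_expression", "spearman_rho": rho, "p_value": p, "n": len(expr)}]
        )
    results["controlled_pairs"] = controlled_comparison(cov)
    results["bin_medians_ratio"] = bin_medians(cov, metric="ratio")
    results["bin_medians_D"] = bin_medians(cov, metric="D")
    return cov, results


# ----------------------------------------------------------- reporting -----

def truncate_percent(numerator: int, denominator: int) -> str:
    """Percentage truncated (not rounded) to two decimals, e.g. 875/2554 ->
    '34.25%'; integer arithmetic, so never off by float rounding."""
    if denominator == 0:
        return "-"
    basis = (10000 * int(numerator)) // int(denominator)
    return f"{basis // 100}.{basis % 100:02d}%"


def report(summary: pd.DataFrame) -> str:
    """Human-readable per-tissue summary with the three selection ratios."""
    header = (
        f"{'tissue':<8}{'total':>8}{'under_sel':>11}{'positive':>10}"
        f"{'under/total':>14}{'pos/under':>12}{'pos/total':>12}"
    )
    lines = [header]
    for row in summary.itertuples(index=False):
        total, under, pos = int(row.total), int(row.under_selection), int(row.positive)
        lines.append(
            f"{row.tissue:<8}{total:>8}{under:>11}{pos:>10}"
            f"{truncate_percent(under, total) if total else '-':>14}"
            f"{truncate_percent(pos, under) if under else '-':>12}"
            f"{truncate_percent(pos, total) if total else '-':>12}"
        )
    return "\n".join(lines)


# ----------------------------------------------------------- analyze -------

@dataclass
class AnalysisResult:
    """Everything the pipeline computes, in memory."""

    annotation: object
    alignments: object
    truth: object
    regions: list
    regions_df: pd.DataFrame
    masks: dict
    mask_exclusions: list
    divergence: pd.DataFrame
    divergence_exclusions: list
    calls: dict          # reference kind -> per-enhancer calls frame
    summaries: dict      # reference kind -> per-tissue summary frame
    polarity: pd.DataFrame
    gbgc_comparisons: dict
    covariates: pd.DataFrame
    associations: dict


def analyze(config, options: PipelineOptions | None = None) -> AnalysisResult:
    """Simulate a dataset and run every downstream stage, no files written."""
    from .simulate import evolve_alignments, simulate_annotation

    options = options or PipelineOptions()
    annotation = simulate_annotation(config)
    alignments, truth = evolve_alignments(config, annotation)

    regions = build_regions(
        annotation.enhancer_records, annotation.genes, annotation.recombination,
        ortholog_species=options.ortholog_species,
    )
    regions_df = regions_to_frame(regions)

    genome = {annotation.chrom: eio.decode_sequence(truth.sequences["mouse"])}
    masks, mask_exclusions = build_masks(
        annotation.genes, genome, ortholog_species=options.ortholog_species
    )
    div, div_exclusions = compute_divergence(alignments, regions, masks, options)

    calls, summaries = {}, {}
    for reference in ("fourfold", "intron"):
        calls[reference], summaries[reference] = run_selection_scan(
            regions_df, div, reference=reference,
            alpha=options.alpha, specific_only=options.specific_only,
        )

    polarity, gbgc_comparisons = gbgc_stage(regions, alignments)
    cov, associations = covariates_stage(regions_df, calls["fourfold"], annotation.covariates)

    return AnalysisResult(
        annotation, alignments, truth, regions, regions_df, masks, mask_exclusions,
        div, div_exclusions, calls, summaries, polarity, gbgc_comparisons, cov, associations,
    )


# ----------------------------------------------------------- run_all -------

def _config_hash(config) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config, out_dir, options: PipelineOptions | None = None) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest dict.

    All outputs are TSV/BED/MAF/FASTA text under ``out_dir``; the manifest
    (also written as manifest.json) records the config hash, seed, per-stage
    outputs and count reconciliation.
    """
    from .simulate import write_dataset

    options = options or PipelineOptions()
    out = eio.ensure_dir(out_dir)
    res = analyze(config, options)
    manifest = {
        "tool": "enhscan",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    paths = write_dataset(out / "simulated", config, res.annotation, res.alignments, res.truth)
    manifest["stages"]["simulate"] = {
        "outputs": {k: str(v) for k, v in paths.items()},
        "n_genes": len(res.annotation.genes),
        "n_enhancer_records": len(res.annotation.enhancer_records),
    }

    eio.write_tsv(res.regions_df, out / "regions.tsv")
    manifest["stages"]["consolidate"] = {
        "outputs": {"regions": str(out / "regions.tsv")},
        "records_in": len(res.annotation.enhancer_records),
        "regions_out": len(res.regions),
        "specific": int((res.regions_df["pleiotropy"] == "specific").sum()),
        "pleiotropic": int((res.regions_df["pleiotropy"] == "pleiotropic").sum()),
    }

    masks_dir = eio.ensure_dir(out / "masks")
    summary_rows = []
    for gid, entry in res.masks.items():
        for klass, mask in entry.items():
            eio.write_mask_bed(mask, masks_dir / f"{gid}_{klass}.bed")
        summary_rows.append(
            {
                "gene_id": gid,
                "n_fourfold": len(entry["fourfold"]) if "fourfold" in entry else 0,
                "n_intron_sites": len(entry.get("intron", [])),
            }
        )
    eio.write_tsv(pd.DataFrame(summary_rows), out / "masks_summary.tsv")
    eio.write_tsv(
        pd.DataFrame(res.mask_exclusions, columns=["gene_id", "reason"]),
        out / "mask_exclusions.tsv",
    )
    manifest["stages"]["sites"] = {
        "outputs": {"summary": str(out / "masks_summary.tsv")},
        "genes_in": len(res.annotation.genes),
        "genes_with_masks": len(res.masks),
        "genes_excluded": len(res.mask_exclusions),
    }

    eio.write_tsv(res.divergence, out / "divergence.tsv")
    eio.write_tsv(
        pd.DataFrame(res.divergence_exclusions, columns=["unit_id", "class", "reason"]),
        out / "divergence_exclusions.tsv",
    )
    manifest["stages"]["divergence"] = {
        "outputs": {"divergence": str(out / "divergence.tsv")},
        "units_out": len(res.divergence),
        "units_excluded": len(res.divergence_exclusions),
    }

    for reference in ("fourfold", "intron"):
        eio.write_tsv(res.calls[reference], out / f"calls_{reference}.tsv")
        eio.write_tsv(res.summaries[reference], out / f"summary_{reference}.tsv")
        manifest["stages"][f"selection_{reference}"] = {
            "outputs": {"calls": str(out / f"calls_{reference}.tsv")},
            "testable": len(res.calls[reference]),
        }

    eio.write_tsv(res.polarity, out / "gbgc_polarity.tsv")
    for name, (quart, pairs) in res.gbgc_comparisons.items():
        eio.write_tsv(quart, out / f"gbgc_{name}_quartiles.tsv")
        eio.write_tsv(pairs, out / f"gbgc_{name}_pairs.tsv")
    manifest["stages"]["gbgc"] = {
        "outputs": {"polarity": str(out / "gbgc_polarity.tsv")},
        "regions_polarized": len(res.polarity),
    }

    eio.write_tsv(res.covariates, out / "covariates_joined.tsv")
    assoc_dir = eio.ensure_dir(out / "assoc")
    for name, frame in res.associations.items():
        eio.write_tsv(frame, assoc_dir / f"{name}.tsv")
    manifest["stages"]["covariates"] = {
        "outputs": {"covariates": str(out / "covariates_joined.tsv")},
        "tables": sorted(res.associations),
    }

    report_text = "\n\n".join(
        f"neutral reference: {ref}\n{report(res.summaries[ref])}" for ref in res.summaries
    )
    (out / "report.txt").write_text(report_text + "\n")
    manifest["stages"]["report"] = {"outputs": {"report": str(out / "report.txt")}}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
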
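"""End-to-end orchestration: genotyping -> TPM -> cohorts -> gene filter
-> ratio matrices -> clustering -> contrast statistics.

`run_from_files` reads the four input tables from disk and hands them to
`run_analysis`, which does all the work in memory and returns a result
bundle; `write_results` materializes every intermediate table so later
stages can be re-run independently.  The analysis path itself contains no
randomness, so re-running with the same inputs is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, cohorts_ratios, expression, genotyping, reference_data, stats
from .exceptions import InputError, P53ccError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's defaults."""

    variants_path: str = ""
    expression_path: str = ""
    sample_sheet_path: str = ""
    transactivation_path: str = ""
    pathway_map_path: str = ""
    expression_unit: str = "FPKM"
    af_threshold: float = genotyping.DEFAULT_AF_THRESHOLD
    p21_loss_threshold: float = reference_data.DEFAULT_P21_LOSS_THRESHOLD
    tpm_floor: float = expression.DEFAULT_TPM_FLOOR
    ratio_floor: float = cohorts_ratios.DEFAULT_RATIO_FLOOR
    min_group: int = cohorts_ratios.DEFAULT_MIN_GROUP
    alpha: float = stats.DEFAULT_ALPHA
    k: int = 2
    wilcoxon_mode: str = "exact"
    missing_missense: str = "error"
    other_class_policy: str = "excluded"
    hotspot_residues: tuple[int, ...] = tuple(sorted(reference_data.DEFAULT_HOTSPOT_RESIDUES))
    proliferation_gene: str = "MKI67"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys {sorted(unknown)}")
        if "hotspot_residues" in raw:
            raw["hotspot_residues"] = tuple(raw["hotspot_residues"])
        return cls(**raw)


@dataclass
class PipelineResult:
    genotypes: list
    cohort_table: pd.DataFrame
    kept_genes: list[str]
    excluded_genes: list[str]
    ratio_a: cohorts_ratios.RatioMatrix
    ratio_b: cohorts_ratios.RatioMatrix | None
    dendrogram_a: clustering.Dendrogram
    clusters_a: clustering.ClusterAssignment
    dendrogram_b: clustering.Dendrogram | None
    sibling_count: int | None
    sibling_list: list
    discriminant: pd.DataFrame
    tally: pd.DataFrame
    per_type_counts: pd.DataFrame
    count_contrast: stats.TestResult
    mki67: dict
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except P53ccError as exc:
            raise P53ccError(f"stage {name!r}: {exc}") from exc

    return wrap


def run_analysis(
    variants: list,
    sample_sheet: pd.DataFrame,
    expr: expression.ExpressionMatrix,
    ta_records: list,
    pathway_map: reference_data.PathwayGeneMap,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full in-memory analysis on pre-loaded inputs."""
    cfg = cfg or PipelineConfig()
    gcfg = genotyping.GenotypingConfig(
        af_threshold=cfg.af_threshold,
        missing_missense=cfg.missing_missense,
        other_class_policy=cfg.other_class_policy,
        hotspot_residues=frozenset(cfg.hotspot_residues),
    )
    ref = reference_data.transactivation_lookup(ta_records)
    catalog = reference_data.gof_catalog(ta_records)

    genotypes = _stage("genotyping")(
        genotyping.genotype_samples, variants, sample_sheet, ref, catalog, gcfg
    )
    tpm = (
        _stage("tpm_conversion")(expression.fpkm_to_tpm, expr)
        if expr.unit == "FPKM"
        else expr
    )
    cohort_table = _stage("cohorts")(
        cohorts_ratios.build_cohorts, genotypes, cfg.min_group
    )
    a_types = [t for t in cohort_table.index if cohort_table.loc[t, "in_cohort_A"]]

    analyzed = {
        g.sample_id: g.cancer_type
        for g in genotypes
        if g.genotype != "excluded" and g.cancer_type in a_types
    }
    medians = _stage("group_median")(expression.group_median, tpm, analyzed)
    kept, excluded, missing = _stage("gene_filter")(
        expression.filter_low_expression_genes,
        medians,
        pathway_map.genes,
        cfg.tpm_floor,
        len(a_types),
    )
    if missing:
        raise P53ccError(f"stage 'gene_filter': pathway genes missing from "
                         f"expression matrix: {missing}")
    logger.info("gene filter: %d kept, %d excluded (%s)", len(kept), len(excluded), excluded)

    ratio_a = _stage("ratio_A")(
        cohorts_ratios.log2_ratio_matrix,
        tpm, genotypes, cohort_table, "A", kept, cfg.ratio_floor,
    )
    dist_a = _stage("clustering_A")(clustering.pearson_distance_matrix, ratio_a)
    dg_a = clustering.complete_linkage(dist_a)
    clusters_a = clustering.cut_k(dg_a, cfg.k)

    ratio_b = dg_b = None
    sibling_count, sibling_list = None, []
    if cohort_table["in_cohort_B"].any():
        ratio_b = _stage("ratio_B")(
            cohorts_ratios.log2_ratio_matrix,
            tpm, genotypes, cohort_table, "B", kept, cfg.ratio_floor,
        )
        dist_b = _stage("clustering_B")(clustering.pearson_distance_matrix, ratio_b)
        dg_b = clustering.complete_linkage(dist_b)
        pairing = {}
        for t in cohort_table.index[cohort_table["in_cohort_B"]]:
            pairing[f"{t}:GOF"] = f"{t}:nonGOF"
            pairing[f"{t}:nonGOF"] = f"{t}:GOF"
        sibling_count, sibling_list = clustering.sibling_pairs(dg_b, pairing)

    discriminant = _stage("discriminant_genes")(
        stats.extract_discriminant_genes, ratio_a, clusters_a, cfg.alpha, cfg.wilcoxon_mode
    )
    extracted = list(discriminant.loc[discriminant["significant"], "gene"])
    tally = _stage("category_tally")(stats.category_tally, extracted, pathway_map, kept)

    cc_genes = [g for g in pathway_map.genes_in("cell_cycle") if g in kept]
    # sample-level tests run in auto mode: exact for small groups, normal
    # approximation at the cohort sizes where enumeration is impractical
    per_type_counts = _stage("per_type_tests")(
        stats.per_type_gene_tests,
        tpm, genotypes, cc_genes, a_types, cfg.alpha, "auto",
    )
    count_contrast = stats.compare_significant_counts(
        per_type_counts, clusters_a, cfg.wilcoxon_mode, cfg.alpha
    )
    mki67 = _stage("proliferation_contrast")(
        stats.mki67_contrast,
        tpm, genotypes, clusters_a, cfg.alpha, "auto", cfg.proliferation_gene,
    )

    sizes = clusters_a.sizes()
    summary = {
        "n_samples": len(genotypes),
        "n_mutant": sum(g.genotype == "mutant" for g in genotypes),
        "n_wildtype": sum(g.genotype == "wildtype" for g in genotypes),
        "n_excluded": sum(g.genotype == "excluded" for g in genotypes),
        "cohort_a_types": a_types,
        "cohort_b_types": list(cohort_table.index[cohort_table["in_cohort_B"]]),
        "kept_genes": len(kept),
        "excluded_genes": excluded,
        "ratio_a_shape": list(ratio_a.values.shape),
        "ratio_b_shape": list(ratio_b.values.shape) if ratio_b is not None else None,
        "cluster_sizes": sizes,
        "n_discriminant_genes": len(extracted),
        "discriminant_genes": extracted,
        "sibling_pairs": sibling_count,
        "count_contrast_p": count_contrast.p_value,
        "mki67_contingency": mki67["contingency"],
        "mki67_fisher_p": mki67["fisher"].p_value,
        "n_ratio_floored_cells": len(ratio_a.floored_cells)
        + (len(ratio_b.floored_cells) if ratio_b is not None else 0),
    }
    return PipelineResult(
        genotypes=genotypes,
        cohort_table=cohort_table,
        kept_genes=kept,
        excluded_genes=excluded,
        ratio_a=ratio_a,
        ratio_b=ratio_b,
        dendrogram_a=dg_a,
        clusters_a=clusters_a,
        dendrogram_b=dg_b,
        sibling_count=sibling_count,
        sibling_list=sibling_list,
        discriminant=discriminant,
        tally=tally,
        per_type_counts=per_type_counts,
        count_contrast=count_contrast,
        mki67=mki67,
        summary=summary,
    )


def run_from_files(cfg: PipelineConfig) -> PipelineResult:
    """Load the four inputs named in the config and run the analysis."""
    for attr in ("variants_path", "expression_path", "sample_sheet_path",
                 "transactivation_path", "pathway_map_path"):
        p = getattr(cfg, attr)
        if not p or not Path(p).exists():
            raise InputError(f"config {attr}={p!r}: file not found")
    variants = genotyping.read_maf(cfg.variants_path)
    sheet = expression.read_sample_sheet(cfg.sample_sheet_path)
    expr = expression.read_expression(cfg.expression_path, cfg.expression_unit)
    ta = reference_data.load_transactivation_table(
        cfg.transactivation_path, cfg.p21_loss_threshold
    )
    pmap = reference_data.load_pathway_map(cfg.pathway_map_path)
    return run_analysis(variants, sheet, expr, ta, pmap, cfg)


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage output as TSV/JSON/Newick under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotyping.genotypes_frame(result.genotypes).to_csv(
        out / "genotypes.tsv", sep="\t", index=False
    )
    result.cohort_table.to_csv(out / "cohort_table.tsv", sep="\t")
    pd.Series(result.kept_genes, name="gene").to_csv(
        out / "kept_genes.tsv", sep="\t", index=False
    )
    cohorts_ratios.write_ratio_matrix(result.ratio_a, out / "ratio_A.tsv")
    (out / "dendrogram_A.nwk").write_text(result.dendrogram_a.to_newick() + "\n")
    clustering.cluster_frame(result.clusters_a).to_csv(
        out / "clusters_A.tsv", sep="\t", index=False
    )
    if result.ratio_b is not None:
        cohorts_ratios.write_ratio_matrix(result.ratio_b, out / "ratio_B.tsv")
        (out / "dendrogram_B.nwk").write_text(result.dendrogram_b.to_newick() + "\n")
    result.discriminant.to_csv(out / "discriminant_genes.tsv", sep="\t", index=False)
    result.tally.to_csv(out / "category_tally.tsv", sep="\t")
    result.per_type_counts.to_csv(out / "per_type_cell_cycle_counts.tsv", sep="\t")
    result.mki67["per_type"].to_csv(out / "mki67_per_type.tsv", sep="\t")
    with open(out / "mki67_contingency.json", "w") as fh:
        json.dump(
            {"table": result.mki67["contingency"],
             "fisher_p": result.mki67["fisher"].p_value},
            fh, indent=1,
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, default=str)
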
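"""Per-sample TP53 genotype assignment from a MAF-like variant table.

A sample is called *mutant* when it carries at least one qualifying
mutation: a nonsense or frameshift TP53 variant with allele frequency
strictly above the threshold, or a missense variant above threshold whose
transactivation record shows loss of p21 transactivation.  Samples whose
only recognized TP53 variants are retained-activity missense changes are
*excluded* from every downstream cohort; samples with no recognized TP53
variant are *wild-type*.  Mutant samples are subtyped GOF / non-GOF by
GOF-catalog membership of any qualifying variant, and flagged hotspot when
a qualifying missense variant sits at one of the canonical hotspot
residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import InputError, ParseError, SchemaError
from .reference_data import (
    DEFAULT_HOTSPOT_RESIDUES,
    TransactivationRecord,
    normalize_protein_change,
    protein_change_residue,
)

logger = logging.getLogger(__name__)

DEFAULT_AF_THRESHOLD = 0.20

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "other")

# cBioPortal / GDC Variant_Classification labels -> internal class
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
}

# recognize_variant verdicts
QUALIFYING = "qualifying_mutation"
RETAINED = "retained_activity_missense"
IGNORED = "ignored"


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    cancer_type: str
    gene: str
    protein_change: str
    variant_class: str
    allele_frequency: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ParseError("empty gene symbol")
        if self.variant_class not in VARIANT_CLASSES:
            raise ParseError(f"unknown variant class {self.variant_class!r}")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ParseError(
                f"{self.sample_id} {self.protein_change}: allele frequency "
                f"{self.allele_frequency} outside [0, 1]"
            )


@dataclass(frozen=True)
class SampleGenotype:
    sample_id: str
    cancer_type: str
    genotype: str  # mutant | wildtype | excluded
    subtype: str  # gof | non_gof | na
    hotspot: bool
    qualifying_variants: tuple[VariantCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.subtype != "na") != (self.genotype == "mutant"):
            raise InputError(
                f"{self.sample_id}: subtype {self.subtype!r} inconsistent with "
                f"genotype {self.genotype!r}"
            )
        if self.hotspot and self.genotype != "mutant":
            raise InputError(f"{self.sample_id}: hotspot flag on non-mutant sample")


@dataclass(frozen=True)
class GenotypingConfig:
    """Tunable rules of genotype assignment.

    af_threshold: allele-frequency cutoff; the comparison is strict (>).
    missing_missense: what to do with a missense variant absent from the
        transactivation reference: "error" (default) or "retained"
        (treat as retained-activity).
    other_class_policy: a recognized variant of class ``other`` (splice,
        in-frame indel) makes the sample "excluded" (default) or is
        treated as absence of mutation ("wildtype").
    """

    af_threshold: float = DEFAULT_AF_THRESHOLD
    missing_missense: str = "error"
    other_class_policy: str = "excluded"
    hotspot_residues: frozenset[int] = DEFAULT_HOTSPOT_RESIDUES


def read_maf(path: str | Path) -> list[VariantCall]:
    """Read a MAF-like TSV into variant calls.

    Accepts either an ``allele_frequency`` column or ``t_alt_count`` /
    ``t_ref_count`` pairs (AF = alt / (alt + ref)).  Variant classes
    outside missense/nonsense/frameshift map to ``other``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return variant_calls_from_frame(df, source=str(path))


def variant_calls_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[VariantCall]:
    """Validate an in-memory MAF-like table (same schema as the TSV)."""
    df = df.astype(str).reset_index(drop=True)
    path = source
    colmap = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene",
        "HGVSp_Short": "protein_change",
        "Variant_Classification": "variant_class",
    }
    df = df.rename(columns={k: v for k, v in colmap.items() if k in df.columns})
    required = {"sample_id", "cancer_type", "gene", "protein_change", "variant_class"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if "allele_frequency" in df.columns:
        af = df["allele_frequency"].astype(float)
    elif {"t_alt_count", "t_ref_count"} <= set(df.columns):
        alt = df["t_alt_count"].astype(float)
        ref = df["t_ref_count"].astype(float)
        af = alt / (alt + ref)
    else:
        raise SchemaError(
            f"{path}: need allele_frequency or t_alt_count/t_ref_count columns"
        )
    calls = []
    for i, row in df.iterrows():
        raw_class = str(row["variant_class"]).strip().lower()
        calls.append(
            VariantCall(
                sample_id=str(row["sample_id"]),
                cancer_type=str(row["cancer_type"]),
                gene=str(row["gene"]),
                protein_change=normalize_protein_change(str(row["protein_change"])),
                variant_class=_MAF_CLASS_MAP.get(raw_class, "other"),
                allele_frequency=float(af.iloc[i]),
            )
        )
    return calls


def recognize_variant(
    v: VariantCall,
    ref: Mapping[str, TransactivationRecord],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    missing_missense: str = "error",
) -> str:
    """Classify one TP53 variant as qualifying / retained-activity / ignored."""
    if v.gene != "TP53":
        raise InputError(f"recognize_variant applies to TP53 only, got {v.gene}")
    if not 0.0 < af_threshold < 1.0:
        raise InputError(f"af_threshold {af_threshold} outside (0, 1)")
    if v.allele_frequency <= af_threshold:
        return IGNORED
    if v.variant_class in ("nonsense", "frameshift"):
        return QUALIFYING
    if v.variant_class == "missense":
        record = ref.get(v.protein_change)
        if record is None:
            if missing_missense == "retained":
                logger.warning(
                    "%s: missense %s absent from transactivation reference; "
                    "treating as retained activity",
                    v.sample_id,
                    v.protein_change,
                )
                return RETAINED
            raise InputError(
                f"{v.sample_id}: missense {v.protein_change} has no "
                "transactivation record"
            )
        return QUALIFYING if record.functional_class == "non_functional" else RETAINED
    return IGNORED  # class 'other'; its sample-level effect is decided later


def genotype_sample(
    variants: Sequence[VariantCall],
    ref: Mapping[str, TransactivationRecord],
    gof_catalog: frozenset[str],
    config: GenotypingConfig = GenotypingConfig(),
) -> SampleGenotype:
    """Assign the genotype of one sample from its TP53 variants.

    ``variants`` may be empty (pure wild-type sample) but when present must
    share one sample id and cancer type.  Precedence: any qualifying
    mutation makes the sample mutant; otherwise a retained-activity
    missense excludes it; an above-threshold ``other``-class variant
    excludes it too under the default policy; otherwise wild-type.
    """
    if not variants:
        raise InputError("genotype_sample needs at least the sample identity; "
                         "use genotype_samples for cohort-level calls")
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise InputError(f"variants from multiple samples: {sorted(sample_ids)}")
    cancer_types = {v.cancer_type for v in variants}
    if len(cancer_types) > 1:
        raise InputError(
            f"{variants[0].sample_id}: conflicting cancer types {sorted(cancer_types)}"
        )
    sample_id = variants[0].sample_id
    cancer_type = variants[0].cancer_type

    tp53 = [v for v in variants if v.gene == "TP53"]
    verdicts = [
        (v, recognize_variant(v, ref, config.af_threshold, config.missing_missense))
        for v in tp53
    ]
    qualifying = tuple(v for v, verdict in verdicts if verdict == QUALIFYING)
    if qualifying:
        is_gof = any(v.protein_change in gof_catalog for v in qualifying)
        hotspot = any(
            v.variant_class == "missense"
            and protein_change_residue(v.protein_change) in config.hotspot_residues
            for v in qualifying
        )
        return SampleGenotype(
            sample_id=sample_id,
            cancer_type=cancer_type,
            genotype="mutant",
            subtype="gof" if is_gof else "non_gof",
            hotspot=hotspot,
            qualifying_variants=qualifying,
        )
    if any(verdict == RETAINED for _, verdict in verdicts):
        return SampleGenotype(sample_id, cancer_type, "excluded", "na", False)
    if config.other_class_policy == "excluded" and any(
        v.variant_class == "other" and v.allele_frequency > config.af_threshold
        for v in tp53
    ):
        return SampleGenotype(sample_id, cancer_type, "excluded", "na", False)
    return SampleGenotype(sample_id, cancer_type, "wildtype", "na", False)


def genotype_samples(
    variants: Iterable[VariantCall],
    sample_sheet: pd.DataFrame,
    ref: Mapping[str, TransactivationRecord],
    gof_catalog: frozenset[str],
    config: GenotypingConfig = GenotypingConfig(),
) -> list[SampleGenotype]:
    """Genotype every sample in the sample sheet.

    ``sample_sheet`` has columns (sample_id, cancer_type); samples without
    any variant row are wild-type.  A variant row whose cancer type
    conflicts with the sheet is an input error.
    """
    if not {"sample_id", "cancer_type"} <= set(sample_sheet.columns):
        raise SchemaError("sample sheet needs columns sample_id, cancer_type")
    if sample_sheet["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample ids in sample sheet")
    type_of = dict(zip(sample_sheet["sample_id"], sample_sheet["cancer_type"]))

    by_sample: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.sample_id not in type_of:
            raise InputError(f"variant sample {v.sample_id} absent from sample sheet")
        if v.cancer_type != type_of[v.sample_id]:
            raise InputError(
                f"{v.sample_id}: cancer type {v.cancer_type!r} conflicts with "
                f"sample sheet {type_of[v.sample_id]!r}"
            )
        by_sample.setdefault(v.sample_id, []).append(v)

    out = []
    for sample_id, cancer_type in type_of.items():
        if sample_id in by_sample:
            out.append(genotype_sample(by_sample[sample_id], ref, gof_catalog, config))
        else:
            out.append(SampleGenotype(sample_id, cancer_type, "wildtype", "na", False))
    return out


def genotype_counts(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    """Per-cancer-type genotype and variant-class counts with shares.

    Variant-class shares use qualifying mutations as denominator; the GOF
    share uses mutant cases.  Shares are NaN-coded when the denominator is
    zero.  A ``__all__`` row aggregates the whole input.
    """
    if not genotypes:
        raise InputError("genotype_counts: empty input")
    rows = []
    groups: dict[str, list[SampleGenotype]] = {}
    for g in genotypes:
        groups.setdefault(g.cancer_type, []).append(g)
    groups["__all__"] = list(genotypes)
    for cancer_type in sorted(groups):
        gs = groups[cancer_type]
        n_mut = sum(g.genotype == "mutant" for g in gs)
        n_wt = sum(g.genotype == "wildtype" for g in gs)
        n_excl = sum(g.genotype == "excluded" for g in gs)
        n_gof = sum(g.subtype == "gof" for g in gs)
        n_nongof = sum(g.subtype == "non_gof" for g in gs)
        n_hot = sum(g.hotspot for g in gs)
        class_counts = {c: 0 for c in ("missense", "nonsense", "frameshift")}
        for g in gs:
            for v in g.qualifying_variants:
                if v.variant_class in class_counts:
                    class_counts[v.variant_class] += 1
        n_qual = sum(class_counts.values())
        row = {
            "cancer_type": cancer_type,
            "n_samples": len(gs),
            "n_mutant": n_mut,
            "n_wildtype": n_wt,
            "n_excluded": n_excl,
            "n_gof": n_gof,
            "n_nongof": n_nongof,
            "n_hotspot": n_hot,
            "gof_pct": round(100 * n_gof / n_mut, 1) if n_mut else float("nan"),
            "mutant_pct": (
                round(100 * n_mut / (n_mut + n_wt), 1) if n_mut + n_wt else float("nan")
            ),
        }
        for c, n in class_counts.items():
            row[f"n_{c}"] = n
            row[f"{c}_pct"] = round(100 * n / n_qual, 1) if n_qual else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("cancer_type")


def variant_class_shares(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent shares of mutation classes, 1-decimal, over their sum."""
    total = sum(counts.values())
    if total == 0:
        raise InputError("variant_class_shares: zero total")
    return {k: round(100 * v / total, 1) for k, v in counts.items()}


def genotypes_frame(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    """Flatten genotypes to a DataFrame (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in genotypes],
            "cancer_type": [g.cancer_type for g in genotypes],
            "genotype": [g.genotype for g in genotypes],
            "subtype": [g.subtype for g in genotypes],
            "hotspot": [g.hotspot for g in genotypes],
        }
    )
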
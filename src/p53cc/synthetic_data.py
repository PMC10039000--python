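"""TCGA-shaped synthetic inputs with planted, recoverable structure.

The generator emits everything the pipeline reads — an FPKM expression
matrix, a sample sheet, a MAF-like variant table, a transactivation
reference and a pathway gene-category map — together with the planted
ground truth, so every stage can be tested offline and end to end.

Planted structure
-----------------
* Expression is log-normal: log2 FPKM = gene baseline + N(0, noise_sd).
  A block of high-expressed background genes gives each sample a column
  total near 1e6, so TPM values land on a realistic scale.
* Cancer types are split into two planted clusters.  Mutant samples of
  cluster-1 types up-regulate the cell-cycle category and MKI67 by
  ``mutant_effect_fold``; mutant samples of cluster-2 types up-regulate
  the apoptosis category instead.  Each cluster thus has a cohesive,
  distinct pathway response, as the clusters in real tumor data do.
* Every cancer type additionally carries a mutant "signature": a
  per-(type, pathway-gene) log2 offset ~ N(0, type_signature_sd) applied
  to all mutant samples of the type.  GOF and non-GOF mutants of a type
  share it, which is what places their ratio profiles next to each other.
* Four pathway genes are planted at low expression (median TPM < 1 in
  every cancer type) so the low-expression filter has work to do.
* Mutant samples carry one qualifying TP53 variant with allele frequency
  drawn away from the 0.20 threshold; a small fraction of samples carry
  only a retained-activity missense variant (excluded by genotyping) or
  a sub-threshold variant (ignored by genotyping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .reference_data import PATHWAY_CATEGORIES, PathwayGeneMap

# Pathway gene catalog used for paper-shaped runs; category sizes include
# the four planted-low genes (RPRM, TP53AIP1, ADGRB1, IGF1).
PAPER_GENE_CATALOG: dict[str, tuple[str, ...]] = {
    "cell_cycle": (
        "CDKN1A", "CCNB1", "CCNB2", "CCNB3", "CDK1", "CCNE1", "CCNE2",
        "CDK2", "CCND1", "CCND2", "CCND3", "CDK4", "CDK6", "GTSE1", "RPRM",
    ),
    "upstream": (
        "ATM", "ATR", "CHEK1", "CHEK2", "CDKN2A", "GORAB", "MDM4", "TP53", "RCHY1",
    ),
    "apoptosis": (
        "BAX", "BID", "BBC3", "PMAIP1", "APAF1", "CASP3", "CASP8", "CASP9",
        "CYCS", "FAS", "TNFRSF10A", "TNFRSF10B", "PERP", "SIVA1", "PIDD1",
        "EI24", "SHISA5", "TP53I3", "ZMAT3", "BCL2", "BCL2L1", "TP73",
        "AIFM2", "TP53AIP1",
    ),
    "dna_repair": ("DDB2", "RRM2B", "GADD45A", "GADD45B"),
    "angiogenesis_metastasis": ("THBS1", "SERPINB5", "CD82", "SERPINE1", "ADGRB1"),
    "igf1_mtor": ("IGFBP3", "PTEN", "IGF1"),
    "negative_feedback": ("MDM2", "PPM1D", "CCNG1", "CCNG2", "RFWD2", "SIAH1"),
    "exosome": ("STEAP3",),
}

PAPER_LOW_GENES = ("ADGRB1", "IGF1", "RPRM", "TP53AIP1")

PAPER_CANCER_TYPES = (
    "ACC", "BLCA", "BRCA", "CESC", "COAD", "ESCA", "GBM", "HNSC", "KICH",
    "LGG", "LIHC", "LUAD", "LUSC", "MESO", "OV", "PAAD", "PRAD", "READ",
    "SARC", "STAD", "UCEC",
)
PAPER_CLUSTER2_TYPES = ("CESC", "COAD", "HNSC", "READ")
# cluster-1 types planted with too few GOF cases to reach cohort B
PAPER_B_DEFICIENT_TYPES = ("ACC", "KICH", "MESO", "UCEC")

_HOTSPOT_GOF_CHANGES = (
    "R175H", "G245S", "R248Q", "R248W", "R249S", "R273C", "R273H", "R282W",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults emulate the shape of the real pan-cancer study: 21 cancer
    types (17 in planted cluster 1, 4 in cluster 2), a 67-gene pathway
    set with 4 low-expressed genes, GOF in roughly 37% of mutants, and a
    two-fold mutant effect on the responding category.
    """

    seed: int = 0
    cancer_types: tuple[str, ...] = PAPER_CANCER_TYPES
    cluster2_types: tuple[str, ...] = PAPER_CLUSTER2_TYPES
    b_deficient_types: tuple[str, ...] = PAPER_B_DEFICIENT_TYPES
    samples_per_type: int = 120
    mutant_fraction: float = 0.45
    gof_fraction: float = 0.372
    excluded_fraction: float = 0.05
    subthreshold_fraction: float = 0.05
    gene_catalog: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(PAPER_GENE_CATALOG)
    )
    low_genes: tuple[str, ...] = PAPER_LOW_GENES
    n_background_genes: int = 200
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 1.5
    min_kept_baseline_log2: float = 2.0
    low_gene_baseline_log2: float = -1.74  # median TPM ~ 0.3, under the filter floor
    background_log2_mean: float = 12.3  # column totals near 1e6 so TPM ~ FPKM
    background_log2_sd: float = 0.5
    mki67_baseline_log2: float = 6.0
    mutant_effect_fold: float = 2.0
    type_signature_sd: float = 0.35
    noise_sd: float = 1.0
    af_distribution: tuple[float, float] = (0.25, 0.60)
    subthreshold_af: tuple[float, float] = (0.02, 0.15)
    activity_target_r: float = 0.78

    def validate(self) -> None:
        for name in ("mutant_fraction", "gof_fraction", "excluded_fraction",
                     "subthreshold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.mutant_effect_fold <= 0:
            raise InputError("mutant_effect_fold must be positive")
        if self.mutant_fraction * self.samples_per_type < 1:
            raise InputError("infeasible config: mutant_fraction * samples_per_type < 1")
        unknown = set(self.gene_catalog) - set(PATHWAY_CATEGORIES)
        if unknown:
            raise InputError(f"unknown pathway categories {sorted(unknown)}")
        genes = [g for gs in self.gene_catalog.values() for g in gs]
        if len(genes) != len(set(genes)):
            raise InputError("duplicate genes in catalog")
        if not set(self.low_genes) <= set(genes):
            raise InputError("low_genes must be catalog members")
        if not set(self.cluster2_types) <= set(self.cancer_types):
            raise InputError("cluster2_types must be cancer_types members")


@dataclass
class SyntheticBundle:
    """Everything the pipeline reads, plus the planted truth."""

    expression: pd.DataFrame  # genes x samples, FPKM
    sample_sheet: pd.DataFrame  # sample_id, cancer_type
    variants: pd.DataFrame  # MAF-like
    transactivation: pd.DataFrame  # reference table
    pathway_map: PathwayGeneMap
    truth: dict


def _make_transactivation(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic transactivation reference with correlated target activities."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    changes: list[tuple[str, float, bool]] = []  # (change, p21, gof)
    for pc in _HOTSPOT_GOF_CHANGES:
        changes.append((pc, float(rng.uniform(0, 40)), True))
    used = {pc for pc, _, _ in changes}
    residues = rng.choice(np.arange(100, 330), size=60, replace=False)
    i = 0
    while sum(1 for _, p, _ in changes if p <= 75) < 30:  # loss-of-function pool
        pos = int(residues[i]); i += 1
        pc = f"{letters[rng.integers(len(letters))]}{pos}{letters[rng.integers(len(letters))]}"
        if pc in used:
            continue
        used.add(pc)
        # a few generated loss-of-function changes are GOF too
        changes.append((pc, float(rng.uniform(0, 60)), bool(rng.random() < 0.18)))
    for _ in range(10):  # retained-activity pool
        pos = int(residues[i]); i += 1
        pc = f"{letters[rng.integers(len(letters))]}{pos}{letters[rng.integers(len(letters))]}"
        if pc in used:
            continue
        used.add(pc)
        changes.append((pc, float(rng.uniform(90, 140)), False))

    p21 = np.array([p for _, p, _ in changes])
    sd = p21.std()
    r0 = cfg.activity_target_r
    noise_sd = sd * np.sqrt(1.0 / r0**2 - 1.0)
    rows = {"protein_change": [pc for pc, _, _ in changes], "p21": p21}
    for target in ("MDM2", "BAX", "14-3-3s", "AIP1", "GADD45", "NOXA", "p53R2"):
        rows[target] = np.clip(p21 + rng.normal(0, noise_sd, size=len(p21)), 0, None)
    rows["gof"] = [g for _, _, g in changes]
    return pd.DataFrame(rows)


def generate_cohort(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate one synthetic cohort, bit-reproducible from cfg.seed."""
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    pathway_map = PathwayGeneMap(
        {g: cat for cat, gs in cfg.gene_catalog.items() for g in gs}
    )
    pathway_genes = pathway_map.genes
    background = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    genes = pathway_genes + ["MKI67"] + background

    ta = _make_transactivation(cfg, rng)
    p21 = dict(zip(ta["protein_change"], ta["p21"]))
    gof_pool = [pc for pc, g in zip(ta["protein_change"], ta["gof"]) if g]
    lof_nongof_pool = [
        pc for pc, g in zip(ta["protein_change"], ta["gof"])
        if not g and p21[pc] <= 75
    ]
    retained_pool = [pc for pc in ta["protein_change"] if p21[pc] > 75]

    # gene baselines (log2 FPKM)
    baseline = pd.Series(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes)),
        index=genes,
    )
    keepers = [g for g in pathway_genes if g not in cfg.low_genes]
    baseline[keepers] = baseline[keepers].clip(lower=cfg.min_kept_baseline_log2)
    baseline[list(cfg.low_genes)] = cfg.low_gene_baseline_log2
    baseline["MKI67"] = cfg.mki67_baseline_log2
    baseline[background] = rng.normal(
        cfg.background_log2_mean, cfg.background_log2_sd, size=len(background)
    )

    cc_genes = [g for g in pathway_map.genes_in("cell_cycle") if g not in cfg.low_genes]
    apo_genes = [g for g in pathway_map.genes_in("apoptosis") if g not in cfg.low_genes]
    effect_log2 = np.log2(cfg.mutant_effect_fold)

    sample_rows, variant_rows = [], []
    truth_genotype: dict[str, dict[str, str]] = {}
    truth_cluster = {
        t: 2 if t in cfg.cluster2_types else 1 for t in cfg.cancer_types
    }
    log2x = np.empty((len(genes), 0))
    columns: list[str] = []
    gene_index = {g: i for i, g in enumerate(genes)}

    for t in cfg.cancer_types:
        n = cfg.samples_per_type
        n_mut = round(cfg.mutant_fraction * n)
        n_excl = round(cfg.excluded_fraction * n)
        n_wt = n - n_mut - n_excl
        n_gof = 5 if t in cfg.b_deficient_types else round(cfg.gof_fraction * n_mut)
        n_sub = round(cfg.subthreshold_fraction * n_wt)

        ids = [f"{t}-{i:04d}" for i in range(n)]
        roles = (["mutant_gof"] * n_gof
                 + ["mutant_nongof"] * (n_mut - n_gof)
                 + ["excluded"] * n_excl
                 + ["wildtype_sub"] * n_sub
                 + ["wildtype"] * (n_wt - n_sub))
        rng.shuffle(roles)

        # per-type mutant signature, shared by GOF and non-GOF samples
        signature = rng.normal(0, cfg.type_signature_sd, size=len(pathway_genes))
        block = rng.normal(0, cfg.noise_sd, size=(len(genes), n)) + baseline.to_numpy()[:, None]

        responding = cc_genes + ["MKI67"] if truth_cluster[t] == 1 else apo_genes
        resp_idx = [gene_index[g] for g in responding]
        sig_idx = [gene_index[g] for g in pathway_genes]

        for j, (sid, role) in enumerate(zip(ids, roles)):
            sample_rows.append({"sample_id": sid, "cancer_type": t})
            if role.startswith("mutant"):
                block[resp_idx, j] += effect_log2
                block[sig_idx, j] += signature
                if role == "mutant_gof":
                    pc = gof_pool[rng.integers(len(gof_pool))]
                    vclass = "missense"
                else:
                    u = rng.random()
                    if u < 0.551:
                        pc = lof_nongof_pool[rng.integers(len(lof_nongof_pool))]
                        vclass = "missense"
                    elif u < 0.7755:
                        pc = f"R{rng.integers(50, 340)}*"
                        vclass = "nonsense"
                    else:
                        pc = f"P{rng.integers(50, 340)}fs"
                        vclass = "frameshift"
                af = rng.uniform(*cfg.af_distribution)
                truth_genotype[sid] = {
                    "genotype": "mutant",
                    "subtype": "gof" if role == "mutant_gof" else "non_gof",
                }
            elif role == "excluded":
                pc = retained_pool[rng.integers(len(retained_pool))]
                vclass = "missense"
                af = rng.uniform(*cfg.af_distribution)
                truth_genotype[sid] = {"genotype": "excluded", "subtype": "na"}
            elif role == "wildtype_sub":
                pc = lof_nongof_pool[rng.integers(len(lof_nongof_pool))]
                vclass = "missense"
                af = rng.uniform(*cfg.subthreshold_af)
                truth_genotype[sid] = {"genotype": "wildtype", "subtype": "na"}
            else:
                truth_genotype[sid] = {"genotype": "wildtype", "subtype": "na"}
                continue
            variant_rows.append(
                {
                    "sample_id": sid,
                    "cancer_type": t,
                    "gene": "TP53",
                    "protein_change": f"p.{pc}",
                    "variant_class": vclass,
                    "allele_frequency": round(af, 4),
                }
            )
        log2x = np.concatenate([log2x, block], axis=1)
        columns.extend(ids)

    expression = pd.DataFrame(
        np.exp2(log2x), index=pd.Index(genes, name="gene"), columns=columns
    )
    sample_sheet = pd.DataFrame(sample_rows)
    variants = pd.DataFrame(variant_rows)

    cohort_a = list(cfg.cancer_types)
    cohort_b = [t for t in cfg.cancer_types if t not in cfg.b_deficient_types]
    truth = {
        "genotypes": truth_genotype,
        "cluster_of_type": truth_cluster,
        "cohort_a_types": cohort_a,
        "cohort_b_types": cohort_b,
        "low_genes": list(cfg.low_genes),
        "kept_genes": sorted(keepers),
        "cluster1_response_genes": sorted(cc_genes + ["MKI67"]),
        "cluster2_response_genes": sorted(apo_genes),
        "expected_activity_r": cfg.activity_target_r,
        "seed": cfg.seed,
    }
    return SyntheticBundle(
        expression=expression,
        sample_sheet=sample_sheet,
        variants=variants,
        transactivation=ta,
        pathway_map=pathway_map,
        truth=truth,
    )


def paper_shaped_fixture(seed: int = 0) -> SyntheticBundle:
    """The default study-shaped bundle: 21 types (17 + 4 planted clusters),
    67 candidate genes with 4 planted-low genes, 17 cohort-B types."""
    return generate_cohort(SyntheticConfig(seed=seed))


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle to the TSV/JSON files the pipeline reads."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression_fpkm.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "variants": out / "variants.tsv",
        "transactivation": out / "transactivation.tsv",
        "pathway_map": out / "pathway_map.tsv",
        "truth": out / "truth.json",
    }
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    bundle.variants.to_csv(paths["variants"], sep="\t", index=False)
    bundle.transactivation.to_csv(paths["transactivation"], sep="\t", index=False)
    pd.DataFrame(
        {"gene": bundle.pathway_map.genes,
         "category": [bundle.pathway_map[g] for g in bundle.pathway_map.genes]}
    ).to_csv(paths["pathway_map"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    return paths


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down configuration for fast tests: 6 types, 30 samples each."""
    types = ("T1", "T2", "T3", "T4", "T5", "T6")
    base = dict(
        seed=seed,
        cancer_types=types,
        cluster2_types=("T5", "T6"),
        b_deficient_types=(),
        samples_per_type=30,
        n_background_genes=60,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
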
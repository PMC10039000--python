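"""Validation experiments: planted-structure recovery and null calibration.

These are the simulation studies the package uses to demonstrate that the
full pipeline recovers what the synthetic-data generator plants and that
the discriminant-gene extraction is calibrated under the null.  They are
shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterAssignment
from .cohorts_ratios import RatioMatrix
from .expression import ExpressionMatrix
from .genotyping import variant_calls_from_frame
from .pipeline import PipelineConfig, PipelineResult, run_analysis
from .reference_data import transactivation_records_from_frame
from .stats import extract_discriminant_genes
from .synthetic_data import SyntheticBundle, SyntheticConfig, generate_cohort


def run_bundle(bundle: SyntheticBundle, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on an in-memory synthetic bundle."""
    calls = variant_calls_from_frame(bundle.variants)
    expr = ExpressionMatrix(values=bundle.expression, unit="FPKM")
    ta = transactivation_records_from_frame(bundle.transactivation)
    return run_analysis(
        calls, bundle.sample_sheet, expr, ta, bundle.pathway_map, cfg
    )


def cluster_recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    synthetic: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Planted-cluster recovery across seeds.

    Per seed: generate a study-shaped cohort, run the pipeline, and score
    the k=2 cut against the planted cluster labels with the adjusted Rand
    index; also record the GOF/non-GOF sibling-pair count of the cohort-B
    dendrogram (out of the number of cohort-B types).
    """
    rows = []
    for i in range(n_seeds):
        seed = (base_seed + 1_000_003 * i) % (2**31 - 1)
        cfg = synthetic or SyntheticConfig()
        bundle = generate_cohort(
            SyntheticConfig(**{**cfg.__dict__, "seed": seed})
        )
        result = run_bundle(bundle)
        planted = [
            bundle.truth["cluster_of_type"][t] for t in result.clusters_a.labels
        ]
        recovered = [result.clusters_a.labels[t] for t in result.clusters_a.labels]
        rows.append(
            {
                "seed": seed,
                "ari": adjusted_rand_score(planted, recovered),
                "sibling_pairs": result.sibling_count,
                "n_cohort_b_types": len(bundle.truth["cohort_b_types"]),
            }
        )
    return pd.DataFrame(rows)


def null_type1_experiment(
    n_replicates: int = 500,
    n_genes: int = 63,
    n_profiles: int = 40,
    n_cluster1: int = 20,
    alpha: float = 0.05,
    mode: str = "exact",
    seed: int = 0,
) -> dict:
    """Empirical per-gene type-I rate of discriminant-gene extraction.

    Each replicate draws a null ratio matrix (iid standard normal cells:
    what the generator yields with no planted effect, after median and
    log2 summarization the cells are exchangeable noise) and counts genes
    extracted at ``alpha`` between a fixed split of the profiles.
    """
    rng = np.random.default_rng(seed)
    profiles = [f"P{i}" for i in range(n_profiles)]
    labels = {p: (1 if i < n_cluster1 else 2) for i, p in enumerate(profiles)}
    clusters = ClusterAssignment(labels=labels, k=2)
    genes = [f"G{i}" for i in range(n_genes)]
    hits = trials = 0
    for _ in range(n_replicates):
        rm = RatioMatrix(
            values=pd.DataFrame(
                rng.normal(size=(n_genes, n_profiles)), index=genes, columns=profiles
            ),
            mode="A",
        )
        out = extract_discriminant_genes(rm, clusters, alpha=alpha, mode=mode)
        hits += int(out["significant"].sum())
        trials += len(out)
    rate = hits / trials
    return {
        "rate": rate,
        "n_trials": trials,
        "se": float(np.sqrt(alpha * (1 - alpha) / trials)),
    }
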
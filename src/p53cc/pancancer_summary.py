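"""Worked-example data: a pan-cancer TCGA summary of TP53 mutation burden.

One row per cancer type of the mutation-rate cohort: histological class
(adenocarcinoma vs not), developmental origin, percent of cases carrying
a TP53 mutation, percent of mutant cases whose mutation is
gain-of-function, and the 2-cluster assignment obtained from the
expression-ratio dendrogram.  These twenty-one rows drive the
cluster-contrast statistics in the README worked example: rank-sum tests
on the rate columns and Fisher tests on the categorical columns.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # type, histology, origin, tp53_mut_pct, gof_pct, cluster
    ("ACC", "non_adeno", "mesoderm", 15.9, 9.1, 1),
    ("BLCA", "non_adeno", "endoderm", 47.0, 41.3, 1),
    ("BRCA", "adeno", "ectoderm", 31.0, 34.2, 1),
    ("ESCA", "adeno", "endoderm", 86.1, 46.6, 1),
    ("GBM", "non_adeno", "ectoderm", 31.4, 53.5, 1),
    ("KICH", "non_adeno", "mesoderm", 24.6, 21.4, 1),
    ("LGG", "non_adeno", "ectoderm", 46.4, 61.1, 1),
    ("LIHC", "non_adeno", "endoderm", 27.5, 42.2, 1),
    ("LUAD", "adeno", "endoderm", 44.7, 23.2, 1),
    ("LUSC", "non_adeno", "endoderm", 83.0, 32.6, 1),
    ("MESO", "non_adeno", "mesoderm", 15.1, 23.1, 1),
    ("OV", "adeno", "mesoderm", 94.1, 35.9, 1),
    ("PAAD", "non_adeno", "endoderm", 49.6, 42.9, 1),
    ("PRAD", "adeno", "mesoderm", 9.5, 32.6, 1),
    ("SARC", "non_adeno", "mesoderm", 32.5, 32.8, 1),
    ("STAD", "adeno", "endoderm", 43.7, 38.3, 1),
    ("UCEC", "adeno", "mesoderm", 35.1, 49.7, 1),
    ("CESC", "non_adeno", "mesoderm", 7.7, 19.0, 2),
    ("COAD", "adeno", "endoderm", 52.0, 48.5, 2),
    ("HNSC", "non_adeno", "ectoderm", 66.3, 11.2, 2),
    ("READ", "adeno", "endoderm", 71.4, 54.4, 2),
]

#: MKI67 mutant-vs-wild-type contrast: cancer types per cluster with a
#: significant expression difference (rows: cluster 1, cluster 2;
#: columns: significant yes, no).
MKI67_CONTINGENCY = [[12, 5], [1, 3]]

#: Mutation-class case counts across the cohort (missense, nonsense,
#: frameshift) and GOF / non-GOF case counts among mutants.
MUTATION_CLASS_COUNTS = {"missense": 2257, "nonsense": 452, "frameshift": 433}
GOF_COUNTS = {"gof": 1169, "non_gof": 1973}


def cohort_summary() -> pd.DataFrame:
    """The summary table as a DataFrame indexed by cancer type."""
    return pd.DataFrame(
        _ROWS,
        columns=["cancer_type", "histology", "origin", "tp53_mut_pct",
                 "gof_pct", "cluster"],
    ).set_index("cancer_type")


def histology_contingency(df: pd.DataFrame | None = None) -> list[list[int]]:
    """2x2 cluster x (adeno, non-adeno) table from the summary."""
    df = cohort_summary() if df is None else df
    return [
        [
            int(((df["cluster"] == c) & (df["histology"] == "adeno")).sum()),
            int(((df["cluster"] == c) & (df["histology"] == "non_adeno")).sum()),
        ]
        for c in (1, 2)
    ]


def origin_contingency(df: pd.DataFrame | None = None) -> list[list[int]]:
    """2x3 cluster x developmental-origin table from the summary."""
    df = cohort_summary() if df is None else df
    origins = ("endoderm", "mesoderm", "ectoderm")
    return [
        [int(((df["cluster"] == c) & (df["origin"] == o)).sum()) for o in origins]
        for c in (1, 2)
    ]
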
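"""Expression handling: FPKM -> TPM conversion, per-group medians, and the
low-expression gene filter.

TPM rescales each sample so its values sum to one million, which makes
within-sample gene shares comparable across samples.  The low-expression
filter drops candidate genes whose per-cancer-type median TPM falls below
a floor (default 1.0 TPM) in strictly more than half of the cancer types
of the cohort under analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, SchemaError

DEFAULT_TPM_FLOOR = 1.0
_TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    ``values`` is a DataFrame indexed by gene symbol with sample-id
    columns; ``unit`` is "FPKM" or "TPM".
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise SchemaError(f"unknown expression unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise SchemaError("negative expression values")
        if self.values.index.duplicated().any():
            raise SchemaError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "cancer_type"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns sample_id, cancer_type")
    return df


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column to sum to 1e6.

    Idempotent on already TPM-scaled columns and rank-preserving within a
    sample.  An all-zero sample column is an error naming the sample.
    """
    if m.unit != "FPKM":
        raise InputError(f"fpkm_to_tpm expects FPKM input, got {m.unit}")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"all-zero expression column(s): {list(zero.index)}")
    return ExpressionMatrix(values=m.values * (_TPM_TOTAL / totals), unit="TPM")


def group_median(
    m: ExpressionMatrix, sample_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Median expression of each gene within each sample group.

    ``sample_groups`` maps sample id -> group label; samples absent from
    the mapping are ignored.  Median is the midpoint of the two central
    order statistics for even group sizes.
    """
    groups: dict[str, list[str]] = {}
    for s in m.samples:
        g = sample_groups.get(s)
        if g is not None:
            groups.setdefault(g, []).append(s)
    empty = [g for g in set(sample_groups.values()) if g not in groups]
    if empty:
        raise InputError(f"group(s) with no samples in matrix: {sorted(empty)}")
    if not groups:
        raise InputError("no samples matched any group")
    return pd.DataFrame(
        {g: m.values[cols].median(axis=1) for g, cols in sorted(groups.items())}
    )


def filter_low_expression_genes(
    median_table: pd.DataFrame,
    candidate_genes: Sequence[str],
    tpm_floor: float = DEFAULT_TPM_FLOOR,
    unit_count: int | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Split candidate genes into (kept, excluded, missing).

    A gene is excluded iff its median is below ``tpm_floor`` in strictly
    more than half of the ``unit_count`` cancer types (columns of
    ``median_table`` by default).  Genes absent from the table are
    reported as missing, never silently dropped.  The result is invariant
    to gene and column ordering.
    """
    if tpm_floor <= 0:
        raise InputError(f"tpm_floor must be positive, got {tpm_floor}")
    if unit_count is None:
        unit_count = median_table.shape[1]
    kept, excluded, missing = [], [], []
    for gene in candidate_genes:
        if gene not in median_table.index:
            missing.append(gene)
            continue
        n_low = int((median_table.loc[gene] < tpm_floor).sum())
        (excluded if n_low > unit_count / 2 else kept).append(gene)
    return kept, excluded, missing
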
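"""Cohort construction and log2 median-ratio matrices.

Cohort A holds the cancer types with at least ``min_group`` mutant and
``min_group`` wild-type cases; cohort B additionally requires
``min_group`` GOF and ``min_group`` non-GOF mutant cases.  For each
cohort the per-gene effect of mutation is summarized as
log2(median mutant TPM / median wild-type TPM); in cohort B the mutant
numerator is split into GOF and non-GOF groups while both share the full
wild-type denominator of their cancer type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .expression import ExpressionMatrix, group_median
from .genotyping import SampleGenotype

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUP = 10
DEFAULT_RATIO_FLOOR = 0.01  # TPM floor applied to medians before the ratio


def build_cohorts(
    genotypes: Sequence[SampleGenotype], min_group: int = DEFAULT_MIN_GROUP
) -> pd.DataFrame:
    """Tabulate per-type group sizes and set cohort membership flags.

    Excluded-genotype samples are not counted anywhere.  Returns a frame
    indexed by cancer type with columns n_mutant, n_wildtype, n_gof,
    n_nongof, in_cohort_A, in_cohort_B.
    """
    if min_group < 1:
        raise InputError(f"min_group must be >= 1, got {min_group}")
    if not genotypes:
        raise InputError("build_cohorts: empty genotype list")
    rows: dict[str, dict[str, int]] = {}
    for g in genotypes:
        if not g.cancer_type or g.cancer_type != g.cancer_type.strip():
            raise InputError(f"bad cancer type label {g.cancer_type!r}")
        row = rows.setdefault(
            g.cancer_type,
            {"n_mutant": 0, "n_wildtype": 0, "n_gof": 0, "n_nongof": 0},
        )
        if g.genotype == "mutant":
            row["n_mutant"] += 1
            row["n_gof" if g.subtype == "gof" else "n_nongof"] += 1
        elif g.genotype == "wildtype":
            row["n_wildtype"] += 1
        # excluded samples are dropped from all counts
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "cancer_type"
    df["in_cohort_A"] = (df["n_mutant"] >= min_group) & (df["n_wildtype"] >= min_group)
    df["in_cohort_B"] = (
        df["in_cohort_A"] & (df["n_gof"] >= min_group) & (df["n_nongof"] >= min_group)
    )
    return df


@dataclass
class RatioMatrix:
    """Gene x profile matrix of log2 median-expression ratios.

    Profiles are cancer types (mode A) or ``TYPE:GOF`` / ``TYPE:nonGOF``
    pairs (mode B).  All values are finite; zero medians are floored
    before the ratio, and each flooring event is logged.
    """

    values: pd.DataFrame
    mode: str
    floored_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def profiles(self) -> list[str]:
        return list(self.values.columns)


def _floored_log2_ratio(
    num: pd.Series, den: pd.Series, floor: float, profile: str, events: list
) -> pd.Series:
    for gene, v in num.items():
        if v < floor:
            events.append((gene, profile))
    return np.log2(num.clip(lower=floor) / den.clip(lower=floor))


def log2_ratio_matrix(
    expr: ExpressionMatrix,
    genotypes: Sequence[SampleGenotype],
    cohort_table: pd.DataFrame,
    mode: str,
    genes: Sequence[str] | None = None,
    floor_tpm: float = DEFAULT_RATIO_FLOOR,
) -> RatioMatrix:
    """Build the log2 median-ratio matrix for cohort A or B.

    Mode "A" emits one profile per cohort-A cancer type
    (mutant vs wild-type); mode "B" emits two profiles per cohort-B type
    (GOF vs wild-type and non-GOF vs wild-type, sharing the wild-type
    denominator).
    """
    if expr.unit != "TPM":
        raise InputError("log2_ratio_matrix expects TPM expression")
    if mode not in ("A", "B"):
        raise InputError(f"mode must be 'A' or 'B', got {mode!r}")
    flag = "in_cohort_A" if mode == "A" else "in_cohort_B"
    types = [t for t in cohort_table.index if cohort_table.loc[t, flag]]
    if not types:
        raise InputError(f"no cancer types qualify for cohort {mode}")
    values = expr.values.loc[list(genes)] if genes is not None else expr.values

    sub = ExpressionMatrix(values=values, unit="TPM")
    cols: dict[str, pd.Series] = {}
    events: list[tuple[str, str]] = []
    for t in types:
        wt = {
            g.sample_id: "wt"
            for g in genotypes
            if g.cancer_type == t and g.genotype == "wildtype"
        }
        if mode == "A":
            mt = {
                g.sample_id: "mt"
                for g in genotypes
                if g.cancer_type == t and g.genotype == "mutant"
            }
            med = group_median(sub, {**wt, **mt})
            cols[t] = _floored_log2_ratio(med["mt"], med["wt"], floor_tpm, t, events)
        else:
            gof = {
                g.sample_id: "gof"
                for g in genotypes
                if g.cancer_type == t and g.subtype == "gof"
            }
            nongof = {
                g.sample_id: "nongof"
                for g in genotypes
                if g.cancer_type == t and g.subtype == "non_gof"
            }
            med = group_median(sub, {**wt, **gof, **nongof})
            cols[f"{t}:GOF"] = _floored_log2_ratio(
                med["gof"], med["wt"], floor_tpm, f"{t}:GOF", events
            )
            cols[f"{t}:nonGOF"] = _floored_log2_ratio(
                med["nongof"], med["wt"], floor_tpm, f"{t}:nonGOF", events
            )
    for gene, profile in events:
        logger.info("ratio floored for gene %s in profile %s", gene, profile)
    return RatioMatrix(values=pd.DataFrame(cols), mode=mode, floored_cells=events)


def write_ratio_matrix(rm: RatioMatrix, path) -> None:
    rm.values.to_csv(path, sep="\t", index_label="gene")


def read_ratio_matrix(path, mode: str) -> RatioMatrix:
    return RatioMatrix(values=pd.read_csv(path, sep="\t", index_col=0), mode=mode)
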
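"""Reference tables: mutant-p53 transactivation activities, GOF catalog,
hotspot residues, and the p53-pathway gene-category map.

The transactivation reference records, for each single-amino-acid p53
mutant, its residual transcriptional activity (percent of wild-type) on
eight canonical p53 target promoters: p21, MDM2, BAX, 14-3-3sigma, AIP1,
GADD45, NOXA and p53R2.  p21 activity is the surrogate used to call a
missense mutant "loss of transactivation"; the cutoff is configurable
because the wild-type range varies between assays.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .exceptions import ParseError, SchemaError, UndefinedCorrelationError

#: The eight target promoters of the transactivation assay, in table order.
TRANSACTIVATION_TARGETS = (
    "p21",
    "MDM2",
    "BAX",
    "14-3-3s",
    "AIP1",
    "GADD45",
    "NOXA",
    "p53R2",
)

#: Canonical p53 hotspot residues.
DEFAULT_HOTSPOT_RESIDUES = frozenset({175, 245, 248, 249, 273, 282})

#: Percent-of-wild-type p21 activity at or below which a missense mutant is
#: considered to have lost transactivation (below the wild-type range).
DEFAULT_P21_LOSS_THRESHOLD = 75.0

#: The eight functional categories of the p53-signaling-pathway gene set.
PATHWAY_CATEGORIES = (
    "cell_cycle",
    "upstream",
    "apoptosis",
    "dna_repair",
    "angiogenesis_metastasis",
    "igf1_mtor",
    "negative_feedback",
    "exosome",
)

FUNCTIONAL_CLASSES = ("functional", "partially_functional", "non_functional", "unknown")

_PROTEIN_CHANGE_RE = re.compile(r"^[A-Z]\d+[A-Z*]$")


def normalize_protein_change(raw: str) -> str:
    """Normalize a protein-change string to the ``R175H`` dialect.

    Strips an optional ``p.`` prefix and upper-cases the residue letters;
    ``*`` is kept as the target residue of nonsense changes.  Frameshift
    suffixes (``fs``) are upper-cased but otherwise preserved so variant
    tables round-trip; strict single-substitution validation is applied
    only where the transactivation table requires it.
    """
    s = raw.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    return s.upper()


def protein_change_residue(protein_change: str) -> int | None:
    """Residue position of a normalized protein change, or None."""
    m = re.match(r"^[A-Z](\d+)", protein_change)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class TransactivationRecord:
    """One mutant's percent-of-wild-type activities on the eight targets.

    ``activities`` maps each target name to a non-negative percent or
    ``nan`` when the assay value is missing.
    """

    protein_change: str
    activities: Mapping[str, float]
    functional_class: str
    gof: bool

    def __post_init__(self) -> None:
        if not _PROTEIN_CHANGE_RE.match(self.protein_change):
            raise ParseError(
                f"malformed protein change {self.protein_change!r}; "
                "expected e.g. 'R175H' after normalization"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ParseError(f"unknown functional class {self.functional_class!r}")
        for target in TRANSACTIVATION_TARGETS:
            if target not in self.activities:
                raise SchemaError(
                    f"{self.protein_change}: activity for target {target!r} "
                    "neither given nor missing-coded"
                )
            v = self.activities[target]
            if not math.isnan(v) and v < 0:
                raise ParseError(
                    f"{self.protein_change}: negative activity {v} for {target}"
                )

    @property
    def p21_activity(self) -> float:
        return self.activities["p21"]


def classify_functional(p21_activity: float, p21_loss_threshold: float) -> str:
    """Derive a functional class from residual p21 activity."""
    if math.isnan(p21_activity):
        return "unknown"
    return "non_functional" if p21_activity <= p21_loss_threshold else "functional"


def load_transactivation_table(
    path: str | Path,
    p21_loss_threshold: float = DEFAULT_P21_LOSS_THRESHOLD,
) -> list[TransactivationRecord]:
    """Load a TSV transactivation reference into records.

    The header must name ``protein_change``, the eight targets and ``gof``;
    a ``functional_class`` column is honoured when present, otherwise the
    class is derived from the p21 column.  Duplicate protein changes are a
    schema error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return transactivation_records_from_frame(df, p21_loss_threshold, source=str(path))


def transactivation_records_from_frame(
    df: pd.DataFrame,
    p21_loss_threshold: float = DEFAULT_P21_LOSS_THRESHOLD,
    source: str = "<frame>",
) -> list[TransactivationRecord]:
    """Validate an in-memory transactivation table (same schema as the TSV)."""
    df = df.astype(str)
    path = source
    required = {"protein_change", "gof", *TRANSACTIVATION_TARGETS}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    records: list[TransactivationRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pc = normalize_protein_change(str(row["protein_change"]))
        if pc in seen:
            raise SchemaError(f"{path}: duplicate protein change {pc!r} (row {i})")
        seen.add(pc)
        activities: dict[str, float] = {}
        for target in TRANSACTIVATION_TARGETS:
            raw = row[target]
            if pd.isna(raw) or str(raw).strip() in ("", "NA", "nan"):
                activities[target] = float("nan")
            else:
                try:
                    activities[target] = float(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"{path} row {i}: bad activity {raw!r} for {target}"
                    ) from exc
        if "functional_class" in df.columns and not pd.isna(row["functional_class"]):
            fclass = str(row["functional_class"]).strip()
        else:
            fclass = classify_functional(activities["p21"], p21_loss_threshold)
        gof = str(row["gof"]).strip().lower() in ("true", "1", "yes")
        records.append(
            TransactivationRecord(
                protein_change=pc,
                activities=activities,
                functional_class=fclass,
                gof=gof,
            )
        )
    return records


def transactivation_lookup(
    records: Iterable[TransactivationRecord],
) -> dict[str, TransactivationRecord]:
    """Index records by normalized protein change."""
    return {r.protein_change: r for r in records}


def gof_catalog(records: Iterable[TransactivationRecord]) -> frozenset[str]:
    """Protein changes annotated as gain-of-function."""
    return frozenset(r.protein_change for r in records if r.gof)


def activity_correlations(
    records: Iterable[TransactivationRecord],
    reference_target: str = "p21",
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of each target's activity with the reference.

    Missing values are dropped pairwise.  Returns, per non-reference
    target, ``(r, two-sided P)`` from the usual t transform of r.
    Targets with no measured values at all are omitted; fewer than three
    complete pairs or a constant vector raise.
    """
    if reference_target not in TRANSACTIVATION_TARGETS:
        raise SchemaError(f"unknown reference target {reference_target!r}")
    recs = list(records)
    ref = np.array([r.activities[reference_target] for r in recs], dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for target in TRANSACTIVATION_TARGETS:
        if target == reference_target:
            continue
        other = np.array([r.activities[target] for r in recs], dtype=float)
        mask = ~(np.isnan(ref) | np.isnan(other))
        if not np.isfinite(other).any():
            continue  # target entirely unmeasured in this table
        if mask.sum() < 3:
            raise SchemaError(
                f"fewer than 3 complete activity pairs for {reference_target} vs {target}"
            )
        x, y = ref[mask], other[mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError(
                f"zero variance in activities for {reference_target} vs {target}"
            )
        r, p = _sstats.pearsonr(x, y)
        out[target] = (float(r), float(p))
    return out


@dataclass(frozen=True)
class PathwayGeneMap:
    """Gene symbol -> functional category, over the fixed 8 categories."""

    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, cat in self.categories.items():
            if cat not in PATHWAY_CATEGORIES:
                raise SchemaError(f"gene {gene!r}: unknown category {cat!r}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.categories

    def __getitem__(self, gene: str) -> str:
        return self.categories[gene]

    @property
    def genes(self) -> list[str]:
        return list(self.categories)

    def category_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in PATHWAY_CATEGORIES}
        for cat in self.categories.values():
            sizes[cat] += 1
        return sizes

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in self.categories.items() if c == category]


def load_pathway_map(path: str | Path) -> PathwayGeneMap:
    """Read a two-column (gene, category) TSV into a PathwayGeneMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "category"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns 'gene' and 'category'")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicated gene(s) {sorted(set(dup))}")
    return PathwayGeneMap(dict(zip(df["gene"], df["category"])))


def hotspot_set(residues: Iterable[int] | None = None) -> frozenset[int]:
    """Validated hotspot residue set (defaults to the canonical six)."""
    resolved = frozenset(residues) if residues is not None else DEFAULT_HOTSPOT_RESIDUES
    if any(r < 1 for r in resolved):
        raise SchemaError("hotspot residues must be positive")
    return resolved
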
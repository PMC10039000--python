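"""Comparative statistics: rank-sum and Fisher exact tests, discriminant
genes, pathway-category tallies, per-type mutant-vs-wild-type tests and
the MKI67 proliferation contrast.

The exact Wilcoxon rank-sum test enumerates the permutation distribution
of the smaller group's rank sum with the shift (convolution) algorithm on
mid-ranks, so ties are handled without approximation.  The normal mode
uses the classic z statistic without continuity or tie correction.  Both
Fisher tests use the probability-ordering two-sided definition: the
p-value sums the probabilities of every margin-matched table whose
hypergeometric probability does not exceed the observed one (times
1 + 1e-7 to absorb floating-point noise).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.special import gammaln

from .clustering import ClusterAssignment
from .cohorts_ratios import RatioMatrix
from .exceptions import EnumerationLimitError, InputError
from .expression import ExpressionMatrix
from .genotyping import SampleGenotype
from .reference_data import PathwayGeneMap

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
_PROB_TOL = 1.0 + 1e-7
_EXACT_N_LIMIT = 100  # permutation enumeration guard for the rank-sum test
_AUTO_EXACT_LIMIT = 50  # mode="auto": exact up to here, normal beyond
_RXC_TABLE_LIMIT = 10_000_000


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _rank_sum_counts(scaled_ranks: tuple[int, ...], m: int) -> np.ndarray:
    """Number of m-subsets of ``scaled_ranks`` attaining each sum.

    Shift algorithm: one convolution per rank.  Entry s of the result is
    the count of subsets of size m with scaled-rank sum s.
    """
    total = sum(scaled_ranks)
    ways = np.zeros((m + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in scaled_ranks:
        for j in range(m, 0, -1):
            ways[j, r:] += ways[j - 1, : total + 1 - r]
    return ways[m]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "exact",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two samples.

    Mid-ranks are assigned over the pooled data; the statistic is the
    rank sum W of the smaller group (the first on ties).  ``mode``:

    - ``exact``: full enumeration of the permutation distribution of W;
      p = min(1, 2 * min(P(W <= w), P(W >= w))).
    - ``normal``: z = (W - m(N+1)/2) / sqrt(mn(N+1)/12), two-sided
      normal p, no continuity correction and no tie correction.
    - ``auto``: exact for pooled N <= 50, normal beyond (the usual
      switch-over of exact rank-test packages).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("wilcoxon_rank_sum: empty group")
    if mode not in ("exact", "normal", "auto"):
        raise InputError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if len(x) + len(y) <= _AUTO_EXACT_LIMIT else "normal"
    swap = len(y) < len(x)
    a, b = (y, x) if swap else (x, y)
    m, n = len(a), len(b)
    N = m + n
    ranks = _sstats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:m].sum())

    if mode == "normal":
        mu = m * (N + 1) / 2.0
        sigma = math.sqrt(m * n * (N + 1) / 12.0)
        z = (w - mu) / sigma
        p = 2.0 * _sstats.norm.sf(abs(z))
        return TestResult("wilcoxon_normal", z, min(1.0, float(p)), m, n, alpha)

    if N > _EXACT_N_LIMIT:
        raise EnumerationLimitError(
            f"exact enumeration guarded at N <= {_EXACT_N_LIMIT} (got {N}); "
            "use mode='normal'"
        )
    scaled = tuple(int(round(2 * r)) for r in sorted(ranks))
    counts = _rank_sum_counts(scaled, m)
    total = math.comb(N, m)
    ws = int(round(2 * w))
    p_le = counts[: ws + 1].sum() / total
    p_ge = counts[ws:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult("wilcoxon_exact", w, float(p), m, n, alpha)


# ---------------------------------------------------------------------------
# Fisher exact tests
# ---------------------------------------------------------------------------

def fisher_2x2(table: Sequence[Sequence[int]], alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (probability ordering)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("fisher_2x2 needs a non-negative 2x2 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    N = int(t.sum())
    if 0 in row or 0 in col:
        warnings.warn("fisher_2x2: zero margin, p = 1", stacklevel=2)
        return TestResult("fisher_2x2", float("nan"), 1.0, int(row[0]), int(row[1]), alpha)
    # hypergeometric over cell (0, 0)
    rv = _sstats.hypergeom(N, int(row[0]), int(col[0]))
    lo = max(0, col[0] - row[1])
    hi = min(row[0], col[0])
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(int(t[0, 0]))
    p = float(pmf[pmf <= p_obs * _PROB_TOL].sum())
    if p > 1.0 - 1e-9:
        p = 1.0  # full support summed; absorb accumulation error
    odds = (
        (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        if t[0, 1] * t[1, 0] > 0
        else float("inf")
    )
    return TestResult("fisher_2x2", float(odds), min(1.0, p), int(row[0]), int(row[1]), alpha)


def _log_table_prob(t: np.ndarray, logfact_margins: float, log_n_fact: float) -> float:
    return logfact_margins - log_n_fact - gammaln(t + 1).sum()


def fisher_rxc(table: Sequence[Sequence[int]], alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Freeman-Halton exact test on an r x c table.

    Exhaustively enumerates all tables with the observed margins; the
    two-sided p sums the multivariate-hypergeometric probabilities of
    tables no more probable than the observed one.  Enumeration is
    guarded at 10^7 tables.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise InputError("fisher_rxc needs a non-negative 2-D table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    N = int(t.sum())
    if (rows == 0).any() or (cols == 0).any() or t.shape[0] < 2 or t.shape[1] < 2:
        warnings.warn("fisher_rxc: degenerate table, p = 1", stacklevel=2)
        return TestResult("fisher_rxc", float("nan"), 1.0, int(rows[0]), N - int(rows[0]), alpha)

    logfact_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
    log_n_fact = gammaln(N + 1)
    log_p_obs = _log_table_prob(t, logfact_margins, log_n_fact)
    cutoff = log_p_obs + math.log(_PROB_TOL)

    r, c = t.shape
    p_total = 0.0
    n_tables = 0

    def recurse(row_idx: int, remaining_cols: np.ndarray, log_acc: float) -> None:
        nonlocal p_total, n_tables
        if row_idx == r - 1:
            # last row forced by column margins
            n_tables += 1
            if n_tables > _RXC_TABLE_LIMIT:
                raise EnumerationLimitError(
                    f"fisher_rxc enumeration exceeds {_RXC_TABLE_LIMIT} tables"
                )
            lp = log_acc - gammaln(remaining_cols + 1).sum()
            if lp <= cutoff:
                p_total += math.exp(lp)
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, left: int, cells_log: float, rem: np.ndarray) -> None:
            if col_idx == c - 1:
                if left <= rem[col_idx]:
                    rem2 = rem.copy()
                    rem2[col_idx] -= left
                    recurse(row_idx + 1, rem2, cells_log - gammaln(left + 1))
                return
            for v in range(min(left, int(rem[col_idx])) + 1):
                rem2 = rem.copy()
                rem2[col_idx] -= v
                fill(col_idx + 1, left - v, cells_log - gammaln(v + 1), rem2)

        fill(0, target, log_acc, remaining_cols)

    recurse(0, cols.copy(), logfact_margins - log_n_fact)
    if p_total > 1.0 - 1e-9:
        p_total = 1.0
    return TestResult(
        "fisher_rxc", float("nan"), min(1.0, p_total), int(rows[0]), N - int(rows[0]), alpha
    )


# ---------------------------------------------------------------------------
# Discriminant genes and category tallies
# ---------------------------------------------------------------------------

def extract_discriminant_genes(
    rm: RatioMatrix,
    clusters: ClusterAssignment,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "exact",
) -> pd.DataFrame:
    """Per-gene rank-sum test of ratio values between the two clusters.

    Returns a frame (gene, statistic, p_value, significant) sorted by
    gene; no multiple-testing correction is applied.
    """
    if clusters.k != 2:
        raise InputError("extract_discriminant_genes needs exactly 2 clusters")
    g1 = [p for p in rm.profiles if clusters.labels[p] == 1]
    g2 = [p for p in rm.profiles if clusters.labels[p] == 2]
    rows = []
    for gene in rm.genes:
        vals = rm.values.loc[gene]
        res = wilcoxon_rank_sum(vals[g1], vals[g2], mode=mode, alpha=alpha)
        rows.append(
            {
                "gene": gene,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)


def category_tally(
    extracted: Sequence[str],
    pathway_map: PathwayGeneMap,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count extracted genes per pathway category.

    ``universe`` restricts the per-category gene totals to the analysed
    (kept) gene set; by default all mapped genes count.  Percentages are
    100 * extracted / total, one decimal.  A ``total`` row sums both
    columns.  Extracted genes missing from the map are an error.
    """
    unmapped = [g for g in extracted if g not in pathway_map]
    if unmapped:
        raise InputError(f"extracted gene(s) not in pathway map: {unmapped}")
    genes = list(universe) if universe is not None else pathway_map.genes
    extracted_set = set(extracted)
    rows = []
    for cat in pathway_map.category_sizes():
        members = [g for g in genes if g in pathway_map and pathway_map[g] == cat]
        n_ext = sum(g in extracted_set for g in members)
        rows.append(
            {
                "category": cat,
                "n_genes": len(members),
                "n_extracted": n_ext,
                "percent": round(100 * n_ext / len(members), 1) if members else 0.0,
            }
        )
    total = {
        "category": "total",
        "n_genes": sum(r["n_genes"] for r in rows),
        "n_extracted": sum(r["n_extracted"] for r in rows),
        "percent": float("nan"),
    }
    if total["n_extracted"] != len(extracted_set):
        raise InputError("tally total does not match extracted gene count")
    return pd.DataFrame(rows + [total]).set_index("category")


# ---------------------------------------------------------------------------
# Per-type expression tests and the MKI67 contrast
# ---------------------------------------------------------------------------

def _groups_for_type(
    genotypes: Sequence[SampleGenotype], cancer_type: str
) -> tuple[list[str], list[str]]:
    mt = [g.sample_id for g in genotypes
          if g.cancer_type == cancer_type and g.genotype == "mutant"]
    wt = [g.sample_id for g in genotypes
          if g.cancer_type == cancer_type and g.genotype == "wildtype"]
    return mt, wt


def per_type_gene_tests(
    expr: ExpressionMatrix,
    genotypes: Sequence[SampleGenotype],
    gene_set: Sequence[str],
    cancer_types: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    mode: str = "normal",
) -> pd.DataFrame:
    """Per cancer type, count genes differentially expressed mutant vs wild-type.

    For each gene in ``gene_set`` and each cancer type, a rank-sum test
    compares TPM values between the mutant and wild-type groups; the
    output row holds the count of genes with p < alpha.  Types with an
    empty group are skipped with a warning.
    """
    if not gene_set:
        raise InputError("per_type_gene_tests: empty gene set")
    if expr.unit != "TPM":
        raise InputError("per_type_gene_tests expects TPM expression")
    rows = []
    for t in cancer_types:
        mt, wt = _groups_for_type(genotypes, t)
        if not mt or not wt:
            warnings.warn(f"cancer type {t}: empty mutant or wild-type group, skipped")
            continue
        n_sig = 0
        for gene in gene_set:
            res = wilcoxon_rank_sum(
                expr.values.loc[gene, mt], expr.values.loc[gene, wt], mode=mode, alpha=alpha
            )
            n_sig += res.significant
        rows.append({"cancer_type": t, "n_significant": n_sig, "n_genes": len(gene_set)})
    return pd.DataFrame(rows).set_index("cancer_type")


def compare_significant_counts(
    counts: pd.DataFrame,
    clusters: ClusterAssignment,
    mode: str = "exact",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Second stage: rank-sum test of per-type significant-gene counts
    between cluster 1 and cluster 2 cancer types."""
    c1 = [t for t in counts.index if clusters.labels.get(t) == 1]
    c2 = [t for t in counts.index if clusters.labels.get(t) == 2]
    if not c1 or not c2:
        raise InputError("both clusters must contribute cancer types")
    return wilcoxon_rank_sum(
        counts.loc[c1, "n_significant"], counts.loc[c2, "n_significant"], mode=mode, alpha=alpha
    )


def mki67_contrast(
    expr: ExpressionMatrix,
    genotypes: Sequence[SampleGenotype],
    clusters: ClusterAssignment,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "normal",
    gene: str = "MKI67",
) -> dict:
    """Per-type MKI67 mutant-vs-wild-type tests and the cluster contrast.

    Returns a dict with the per-type test table, the 2x2 contingency
    (clusters x significant yes/no) and its Fisher result.
    """
    if gene not in expr.values.index:
        raise InputError(f"{gene} missing from expression matrix")
    rows = []
    for t in sorted({g.cancer_type for g in genotypes}):
        if t not in clusters.labels:
            continue
        mt, wt = _groups_for_type(genotypes, t)
        if not mt or not wt:
            warnings.warn(f"cancer type {t}: empty group for {gene} contrast, skipped")
            continue
        res = wilcoxon_rank_sum(
            expr.values.loc[gene, mt], expr.values.loc[gene, wt], mode=mode, alpha=alpha
        )
        rows.append(
            {
                "cancer_type": t,
                "cluster": clusters.labels[t],
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "mutant_higher": float(expr.values.loc[gene, mt].median())
                > float(expr.values.loc[gene, wt].median()),
            }
        )
    per_type = pd.DataFrame(rows).set_index("cancer_type")
    table = [
        [
            int(((per_type["cluster"] == c) & per_type["significant"]).sum()),
            int(((per_type["cluster"] == c) & ~per_type["significant"]).sum()),
        ]
        for c in (1, 2)
    ]
    fisher = fisher_2x2(table, alpha=alpha)
    return {"per_type": per_type, "contingency": table, "fisher": fisher}
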
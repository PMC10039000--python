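import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from p53cc import stats as st
from p53cc.clustering import ClusterAssignment
from p53cc.cohorts_ratios import RatioMatrix
from p53cc.exceptions import InputError
from p53cc.expression import ExpressionMatrix
from p53cc.genotyping import SampleGenotype
from p53cc.pancancer_summary import cohort_summary
from p53cc.reference_data import PathwayGeneMap


def brute_force_wilcoxon_exact(x, y):
    """Independent oracle: enumerate every assignment of pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    m = min(len(x), len(y))
    first = x if len(x) <= len(y) else y
    w_obs = ranks[: len(x)].sum() if len(x) <= len(y) else ranks[len(x):].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, m)]
    n_le = sum(s <= w_obs + 1e-9 for s in sums)
    n_ge = sum(s >= w_obs - 1e-9 for s in sums)
    total = len(sums)
    return min(1.0, 2 * min(n_le / total, n_ge / total))


def brute_force_fisher_2x2(table):
    """Independent oracle: enumerate every 2x2 table with the margins."""
    a, b = table[0]
    c, d = table[1]
    r0, r1, c0 = a + b, c + d, a + c
    N = r0 + r1

    def prob(aa):
        return (
            math.comb(r0, aa) * math.comb(r1, c0 - aa) / math.comb(N, c0)
        )

    p_obs = prob(a)
    return sum(
        prob(aa)
        for aa in range(max(0, c0 - r1), min(r0, c0) + 1)
        if prob(aa) <= p_obs * (1 + 1e-7)
    )


class TestWilcoxon:
    def test_identical_groups_give_one(self):
        assert st.wilcoxon_rank_sum([1, 2], [1, 2], "exact").p_value == 1.0

    def test_fully_separated_small_groups(self):
        res = st.wilcoxon_rank_sum([1, 2], [3, 4], "exact")
        assert res.p_value == pytest.approx(1 / 3)

    def test_normal_mode_mutation_rate_contrast(self):
        """Cohort summary mutation-rate column split 17 vs 4."""
        df = cohort_summary()
        c1 = df.loc[df["cluster"] == 1, "tp53_mut_pct"]
        c2 = df.loc[df["cluster"] == 2, "tp53_mut_pct"]
        res = st.wilcoxon_rank_sum(c1, c2, mode="normal")
        assert res.p_value == pytest.approx(0.4737, abs=5e-5)

    def test_symmetry_in_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=9)
        for mode in ("exact", "normal"):
            a = st.wilcoxon_rank_sum(x, y, mode).p_value
            b = st.wilcoxon_rank_sum(y, x, mode).p_value
            assert a == pytest.approx(b)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 6), rng.integers(2, 7)
        x = rng.integers(0, 6, size=m).astype(float)  # integer data: ties happen
        y = rng.integers(0, 6, size=n).astype(float)
        ours = st.wilcoxon_rank_sum(x, y, "exact").p_value
        assert ours == pytest.approx(brute_force_wilcoxon_exact(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=5), rng.normal(size=7)
        ours = st.wilcoxon_rank_sum(x, y, "exact").p_value
        ref = sstats.mannwhitneyu(x, y, method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(size=13)
        ours = st.wilcoxon_rank_sum(x, y, "normal").p_value
        ref = sstats.mannwhitneyu(
            x, y, method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_auto_switches_on_pooled_size(self):
        rng = np.random.default_rng(1)
        small = st.wilcoxon_rank_sum(rng.normal(size=10), rng.normal(size=10), "auto")
        big = st.wilcoxon_rank_sum(rng.normal(size=40), rng.normal(size=40), "auto")
        assert small.method == "wilcoxon_exact"
        assert big.method == "wilcoxon_normal"

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            st.wilcoxon_rank_sum([], [1.0], "exact")


class TestFisher2x2:
    def test_proliferation_contingency(self):
        assert st.fisher_2x2([[12, 5], [1, 3]]).p_value == pytest.approx(0.2528, abs=5e-5)

    def test_symmetric_table(self):
        assert st.fisher_2x2([[1, 1], [1, 1]]).p_value == 1.0

    def test_diagonal_table(self):
        assert st.fisher_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert st.fisher_2x2([[0, 0], [3, 4]]).p_value == 1.0

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            t = rng.integers(0, 7, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert st.fisher_2x2(t).p_value == pytest.approx(
                brute_force_fisher_2x2(t.tolist()), abs=1e-10
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = rng.integers(1, 30, size=(2, 2))
            assert st.fisher_2x2(t).p_value == pytest.approx(
                sstats.fisher_exact(t)[1], rel=1e-6
            )

    def test_hypergeometric_pmf_sums_to_one(self):
        for N, K, n in [(20, 8, 5), (30, 12, 15), (12, 6, 6)]:
            rv = sstats.hypergeom(N, K, n)
            support = np.arange(max(0, n + K - N), min(K, n) + 1)
            assert rv.pmf(support).sum() == pytest.approx(1.0, abs=1e-12)


class TestFisherRxc:
    def test_consistent_with_2x2(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = rng.integers(1, 9, size=(2, 2))
            assert st.fisher_rxc(t).p_value == pytest.approx(
                st.fisher_2x2(t).p_value, abs=1e-10
            )

    def test_origin_table_against_r(self):
        """2x3 developmental-origin contingency from the cohort summary.

        Independent oracle value from R: fisher.test(matrix(c(3,1,7,1,7,2),2)).
        """
        table = [[3, 7, 7], [1, 1, 2]]
        res = st.fisher_rxc(table)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_single_row_degenerate(self):
        with pytest.warns(UserWarning):
            assert st.fisher_rxc([[3, 4, 5]]).p_value == 1.0

    def test_matches_brute_force_multivariate_enumeration(self):
        # independent oracle: enumerate all 2x3 tables with fixed margins
        table = np.array([[2, 3, 1], [1, 2, 4]])
        rows, cols = table.sum(1), table.sum(0)
        N = table.sum()

        def prob(t):
            num = sum(math.lgamma(r + 1) for r in rows) + sum(
                math.lgamma(c + 1) for c in cols
            )
            den = math.lgamma(N + 1) + sum(math.lgamma(v + 1) for v in t.flat)
            return math.exp(num - den)

        p_obs = prob(table)
        total = 0.0
        for a in range(rows[0] + 1):
            for b in range(rows[0] - a + 1):
                c = rows[0] - a - b
                t = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
                if (t >= 0).all():
                    p = prob(t)
                    if p <= p_obs * (1 + 1e-7):
                        total += p
        assert st.fisher_rxc(table).p_value == pytest.approx(total, abs=1e-10)


def _ratio_matrix_with_shift(seed=0, shift=3.0):
    rng = np.random.default_rng(seed)
    profiles = [f"C1_{i}" for i in range(10)] + [f"C2_{i}" for i in range(5)]
    values = pd.DataFrame(
        rng.normal(size=(6, 15)), index=[f"G{i}" for i in range(6)], columns=profiles
    )
    values.loc["G0", [p for p in profiles if p.startswith("C2")]] += shift
    values.loc["G5"] = 0.7  # constant gene: never extracted
    labels = {p: (1 if p.startswith("C1") else 2) for p in profiles}
    return RatioMatrix(values=values, mode="A"), ClusterAssignment(labels=labels, k=2)


class TestDiscriminantGenes:
    def test_planted_shift_extracted_constant_not(self):
        rm, clusters = _ratio_matrix_with_shift()
        out = st.extract_discriminant_genes(rm, clusters)
        by_gene = out.set_index("gene")
        assert bool(by_gene.loc["G0", "significant"])
        assert not bool(by_gene.loc["G5", "significant"])

    def test_requires_two_clusters(self):
        rm, clusters = _ratio_matrix_with_shift()
        clusters3 = ClusterAssignment(labels=clusters.labels, k=3)
        with pytest.raises(InputError):
            st.extract_discriminant_genes(rm, clusters3)

    def test_conservative_size_at_17_vs_4_split(self):
        """At a 17/4 split the exact test's attainable size is 0.0404, not
        the nominal 0.05; the empirical null rate should match the
        analytic size."""
        # analytic size from the exact null distribution of the rank sum
        counts = st._rank_sum_counts(tuple(2 * r for r in range(1, 22)), 4)
        total = math.comb(21, 4)
        cdf = np.cumsum(counts) / total
        sf = counts[::-1].cumsum()[::-1] / total
        size = sum(
            counts[w] / total
            for w in range(len(counts))
            if counts[w] and min(1, 2 * min(cdf[w], sf[w])) < 0.05
        )
        assert size == pytest.approx(0.04043, abs=1e-4)
        rng = np.random.default_rng(42)
        hits = trials = 0
        for _ in range(150):
            values = pd.DataFrame(
                rng.normal(size=(20, 21)),
                index=[f"G{i}" for i in range(20)],
                columns=[f"P{i}" for i in range(21)],
            )
            rm = RatioMatrix(values=values, mode="A")
            clusters = ClusterAssignment(
                labels={f"P{i}": (1 if i < 17 else 2) for i in range(21)}, k=2
            )
            out = st.extract_discriminant_genes(rm, clusters)
            hits += int(out["significant"].sum())
            trials += len(out)
        rate = hits / trials
        se = math.sqrt(size * (1 - size) / trials)
        assert abs(rate - size) < 4 * se


class TestCategoryTally:
    @pytest.fixture()
    def pmap(self):
        genes = {f"CC{i}": "cell_cycle" for i in range(14)}
        genes.update({f"AP{i}": "apoptosis" for i in range(23)})
        return PathwayGeneMap(genes)

    def test_cell_cycle_share(self, pmap):
        extracted = [f"CC{i}" for i in range(6)] + [f"AP{i}" for i in range(4)]
        tally = st.category_tally(extracted, pmap)
        assert tally.loc["cell_cycle", "n_extracted"] == 6
        assert tally.loc["cell_cycle", "percent"] == 42.9
        assert tally.loc["apoptosis", "percent"] == 17.4  # 4/23
        assert tally.loc["total", "n_extracted"] == 10

    def test_empty_and_full_extractions(self, pmap):
        empty = st.category_tally([], pmap)
        assert (empty.drop("total")["n_extracted"] == 0).all()
        full = st.category_tally([f"CC{i}" for i in range(14)], pmap)
        assert full.loc["cell_cycle", "percent"] == 100.0

    def test_unmapped_gene_rejected(self, pmap):
        with pytest.raises(InputError, match="UNKNOWN"):
            st.category_tally(["UNKNOWN"], pmap)

    def test_universe_restricts_totals(self, pmap):
        tally = st.category_tally(["CC0"], pmap, universe=["CC0", "CC1", "AP0"])
        assert tally.loc["cell_cycle", "n_genes"] == 2
        assert tally.loc["cell_cycle", "percent"] == 50.0


def _small_expression(seed=0, effect_types=(), gene="MKI67"):
    rng = np.random.default_rng(seed)
    types = ["T1", "T2", "T3", "T4"]
    genotypes, cols = [], {}
    for t in types:
        for i in range(14):
            sid = f"{t}-{i}"
            mutant = i < 7
            genotypes.append(
                SampleGenotype(sid, t, "mutant" if mutant else "wildtype",
                               "non_gof" if mutant else "na", False)
            )
            shift = 3.0 if (mutant and t in effect_types) else 0.0
            cols[sid] = rng.normal(10, 1, size=2) + [shift, 0.0]
    values = pd.DataFrame(cols, index=[gene, "OTHER"])
    return ExpressionMatrix(values=values, unit="TPM"), genotypes, types


class TestPerTypeAndProliferation:
    def test_single_gene_identical_groups_count_zero(self):
        values = pd.DataFrame(
            {f"s{i}": [5.0] for i in range(8)}, index=["G"]
        )
        expr = ExpressionMatrix(values=values, unit="TPM")
        gts = [
            SampleGenotype(f"s{i}", "T", "mutant" if i < 4 else "wildtype",
                           "non_gof" if i < 4 else "na", False)
            for i in range(8)
        ]
        out = st.per_type_gene_tests(expr, gts, ["G"], ["T"], mode="exact")
        assert out.loc["T", "n_significant"] == 0

    def test_planted_effect_separates_clusters(self):
        expr, gts, types = _small_expression(effect_types=("T1", "T2"))
        counts = st.per_type_gene_tests(expr, gts, ["MKI67"], types, mode="exact")
        assert counts.loc["T1", "n_significant"] == 1
        assert counts.loc["T3", "n_significant"] == 0
        clusters = ClusterAssignment(
            labels={"T1": 1, "T2": 1, "T3": 2, "T4": 2}, k=2
        )
        res = st.compare_significant_counts(counts, clusters)
        assert res.p_value < 0.4  # 2v2 exact test cannot go below 1/3

    def test_mki67_contrast_strong_effect(self):
        expr, gts, types = _small_expression(effect_types=("T1", "T2"))
        clusters = ClusterAssignment(labels={"T1": 1, "T2": 1, "T3": 2, "T4": 2}, k=2)
        out = st.mki67_contrast(expr, gts, clusters, mode="exact")
        assert out["contingency"][0] == [2, 0]  # both cluster-1 types significant
        assert out["contingency"][1] == [0, 2]
        assert out["per_type"].loc["T1", "mutant_higher"]

    def test_mki67_missing_rejected(self):
        expr, gts, types = _small_expression()
        clusters = ClusterAssignment(labels={t: 1 for t in types}, k=1)
        with pytest.raises(InputError, match="ABSENT"):
            st.mki67_contrast(expr, gts, clusters, gene="ABSENT")

    def test_all_nonsignificant_degenerate_column(self):
        expr, gts, types = _small_expression(effect_types=())
        clusters = ClusterAssignment(labels={"T1": 1, "T2": 1, "T3": 2, "T4": 2}, k=2)
        with pytest.warns(UserWarning, match="zero margin"):
            out = st.mki67_contrast(expr, gts, clusters, mode="exact")
        assert out["fisher"].p_value == 1.0
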
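import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from p53cc import clustering as cl
from p53cc.exceptions import InputError, UndefinedCorrelationError


def dist_df(d, labels):
    return pd.DataFrame(np.asarray(d, dtype=float), index=labels, columns=labels)


def brute_force_complete_linkage(dist: pd.DataFrame):
    """Naive re-agglomeration oracle: recompute max-linkage from scratch
    each step, same lexicographic tie-break, independent bookkeeping."""
    labels = list(dist.index)
    clusters = {frozenset([l]) for l in labels}
    merges = []
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(sorted(clusters, key=sorted), 2):
            h = max(dist.loc[x, y] for x in a for y in b)
            key = tuple(sorted((tuple(sorted(a)), tuple(sorted(b)))))
            candidates.append((h, key, a, b))
        h, _, a, b = min(candidates)
        clusters.remove(a)
        clusters.remove(b)
        clusters.add(a | b)
        merges.append((set(a), set(b), h))
    return merges


class TestPearsonDistance:
    def test_identity_negation_and_known_value(self):
        df = pd.DataFrame(
            {"p": [1.0, 2.0, 3.0], "neg": [3.0, 2.0, 1.0], "near": [1.0, 2.0, 4.0]}
        )
        d = cl.pearson_distance_matrix(df)
        assert d.loc["p", "p"] == 0.0
        assert d.loc["p", "neg"] == pytest.approx(2.0)
        assert d.loc["p", "near"] == pytest.approx(1 - 0.9820, abs=1e-4)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 2)).all()

    def test_zero_variance_profile_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            cl.pearson_distance_matrix(df)

    def test_uncentered_variant_differs(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 5.0]})
        centered = cl.pearson_distance_matrix(df, centered=True)
        uncentered = cl.pearson_distance_matrix(df, centered=False)
        assert centered.loc["a", "b"] != pytest.approx(uncentered.loc["a", "b"])


class TestCompleteLinkage:
    def test_three_point_trace(self):
        d = dist_df([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ["a", "b", "c"])
        dg = cl.complete_linkage(d)
        assert dg.merges[0][:2] == (0, 1) and dg.merges[0][2] == 1.0
        assert dg.merges[1][2] == 3.0  # max(d(a,c), d(b,c))

    def test_identical_profiles_merge_at_zero(self):
        d = dist_df(np.zeros((4, 4)), list("abcd"))
        dg = cl.complete_linkage(d)
        assert all(h == 0.0 for _, _, h in dg.merges)

    def test_heights_monotone_and_count(self, paper_result):
        dg = paper_result.dendrogram_a
        heights = [h for _, _, h in dg.merges]
        assert len(dg.merges) == dg.n - 1
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (7, 4)])
    def test_matches_naive_reagglomeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(n)]
        df = dist_df(d, labels)
        dg = cl.complete_linkage(df)
        oracle = brute_force_complete_linkage(df)
        for (a, b, h), (oa, ob, oh) in zip(dg.merges, oracle):
            assert h == pytest.approx(oh)
            assert {frozenset(dg.members(a)), frozenset(dg.members(b))} == {
                frozenset(oa), frozenset(ob),
            }

    def test_heights_match_scipy(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dg = cl.complete_linkage(dist_df(d, [f"p{i}" for i in range(9)]))
        Z = linkage(squareform(d, checks=False), method="complete")
        assert np.allclose(sorted(h for _, _, h in dg.merges), sorted(Z[:, 2]))

    def test_input_order_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(6)]
        df = dist_df(d, labels)
        perm = [3, 0, 5, 1, 4, 2]
        df2 = df.iloc[perm, perm]
        cuts1 = cl.cut_k(cl.complete_linkage(df), 3)
        cuts2 = cl.cut_k(cl.complete_linkage(df2), 3)
        assert cuts1.labels == cuts2.labels


class TestCutK:
    def test_extremes(self):
        d = dist_df([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ["a", "b", "c"])
        dg = cl.complete_linkage(d)
        assert set(cl.cut_k(dg, 1).labels.values()) == {1}
        assert sorted(cl.cut_k(dg, 3).labels.values()) == [1, 2, 3]
        with pytest.raises(InputError):
            cl.cut_k(dg, 0)
        with pytest.raises(InputError):
            cl.cut_k(dg, 4)

    def test_two_blob_recovery_and_largest_first(self):
        rng = np.random.default_rng(21)
        big = rng.normal(0, 0.05, size=(5, 2))
        small = rng.normal(10, 0.05, size=(2, 2))
        pts = np.vstack([small, big])  # small blob listed first
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(2)] + [f"b{i}" for i in range(5)]
        assignment = cl.cut_k(cl.complete_linkage(dist_df(d, labels)), 2)
        assert sorted(assignment.cluster(1)) == [f"b{i}" for i in range(5)]
        assert sorted(assignment.cluster(2)) == ["s0", "s1"]
        # last merge height dwarfs the within-blob merges
        dg = cl.complete_linkage(dist_df(d, labels))
        assert dg.merges[-1][2] > 10 * dg.merges[-2][2]

    def test_matches_scipy_fcluster_on_generic_data(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.3, (6, 3)), rng.normal(4, 0.3, (4, 3))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(10)]
        ours = cl.cut_k(cl.complete_linkage(dist_df(d, labels)), 2)
        ref = fcluster(
            linkage(squareform(d, checks=False), "complete"), 2, criterion="maxclust"
        )
        ours_sets = {frozenset(ours.cluster(c)) for c in (1, 2)}
        ref_sets = {
            frozenset(l for l, r in zip(labels, ref) if r == c) for c in set(ref)
        }
        assert ours_sets == ref_sets


class TestSiblingPairs:
    def test_duplicated_columns_all_siblings(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 4))
        df = pd.DataFrame(
            np.hstack([base, base + rng.normal(0, 1e-6, size=base.shape)]),
            columns=[f"T{i}:GOF" for i in range(4)] + [f"T{i}:nonGOF" for i in range(4)],
        )
        dg = cl.complete_linkage(cl.pearson_distance_matrix(df))
        pairing = {}
        for i in range(4):
            pairing[f"T{i}:GOF"] = f"T{i}:nonGOF"
            pairing[f"T{i}:nonGOF"] = f"T{i}:GOF"
        count, pairs = cl.sibling_pairs(dg, pairing)
        assert count == 4

    def test_corrupted_partner_not_counted(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 3))
        cols = {
            "T0:GOF": base[:, 0], "T0:nonGOF": base[:, 0] + rng.normal(0, 1e-3, 10),
            "T1:GOF": base[:, 1], "T1:nonGOF": base[:, 2],  # corrupted: unrelated
            "T2:GOF": base[:, 2] + rng.normal(0, 1e-3, 10),
        }
        cols["T2:nonGOF"] = base[:, 1]  # swapped with T1's partner
        df = pd.DataFrame(cols)
        dg = cl.complete_linkage(cl.pearson_distance_matrix(df))
        pairing = {}
        for t in ("T0", "T1", "T2"):
            pairing[f"{t}:GOF"] = f"{t}:nonGOF"
            pairing[f"{t}:nonGOF"] = f"{t}:GOF"
        count, pairs = cl.sibling_pairs(dg, pairing)
        assert ("T0:GOF", "T0:nonGOF") in pairs
        assert count == 1

    def test_non_involution_rejected(self):
        d = dist_df([[0, 1], [1, 0]], ["a", "b"])
        dg = cl.complete_linkage(d)
        with pytest.raises(InputError):
            cl.sibling_pairs(dg, {"a": "b"})

    def test_planted_shared_signal_gives_full_pairing(self, paper_result):
        assert paper_result.sibling_count == 17


class TestNewick:
    def test_round_trip_parses(self):
        d = dist_df([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ["a", "b", "c"])
        nwk = cl.complete_linkage(d).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]
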
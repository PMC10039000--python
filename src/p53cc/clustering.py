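"""Hierarchical clustering of ratio profiles.

Distance between two profiles is the Pearson correlation distance
d = 1 - r computed over genes (anticorrelated profiles are maximally
far apart, d -> 2).  Agglomeration uses complete linkage (inter-cluster
distance = maximum pairwise distance), which yields monotone merge
heights.  Ties are broken on the lexicographically smallest pair of
member-id tuples so the dendrogram is reproducible regardless of input
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts_ratios import RatioMatrix
from .exceptions import InputError, UndefinedCorrelationError


def pearson_distance_matrix(
    rm: RatioMatrix | pd.DataFrame, centered: bool = True
) -> pd.DataFrame:
    """Symmetric profile x profile matrix of d = 1 - r.

    ``centered`` selects the ordinary (mean-centered) Pearson r; the
    uncentered variant (cosine of the raw vectors) is available for
    parity with tools that offer it.  A zero-variance profile makes r
    undefined and raises, naming the profile.
    """
    values = rm.values if isinstance(rm, RatioMatrix) else rm
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise InputError("need at least 2 profiles and 2 genes")
    x = values.to_numpy(dtype=float).T  # profiles x genes
    if centered:
        x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    bad = np.where(norms == 0)[0]
    if len(bad):
        name = values.columns[bad[0]]
        raise UndefinedCorrelationError(
            f"profile {name!r} has zero variance; correlation undefined"
        )
    r = (x @ x.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


@dataclass
class Dendrogram:
    """Merge tree over profiles.

    ``leaves`` are the profile ids; leaf node i is ``leaves[i]``.  Each
    merge is (node_a, node_b, height) with internal node n + j created by
    merge j.  Complete linkage guarantees non-decreasing heights.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n(self) -> int:
        return len(self.leaves)

    def members(self, node: int) -> list[str]:
        """Leaf labels under a node id."""
        if node < self.n:
            return [self.leaves[node]]
        a, b, _ = self.merges[node - self.n]
        return self.members(a) + self.members(b)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""

        def height(node: int) -> float:
            return 0.0 if node < self.n else self.merges[node - self.n][2]

        def render(node: int) -> str:
            if node < self.n:
                return self.leaves[node].replace(" ", "_")
            a, b, h = self.merges[node - self.n]
            return (
                f"({render(a)}:{h - height(a):.6g},{render(b)}:{h - height(b):.6g})"
            )

        root = self.n + len(self.merges) - 1 if self.merges else 0
        return render(root) + ";"


@dataclass
class ClusterAssignment:
    """Profile id -> 1-based cluster label, largest cluster first."""

    labels: dict[str, int]
    k: int

    def cluster(self, label: int) -> list[str]:
        return [p for p, c in self.labels.items() if c == label]

    def sizes(self) -> list[int]:
        return [len(self.cluster(c)) for c in range(1, self.k + 1)]


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerate profiles under complete (maximum) linkage.

    Naive O(n^3) agglomeration, deterministic: among equally close
    cluster pairs, the pair whose sorted member-id tuples are
    lexicographically smallest merges first.
    """
    labels = list(dist.index)
    if list(dist.columns) != labels:
        raise InputError("distance matrix index and columns differ")
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise InputError("distance matrix is not symmetric")
    n = len(labels)
    # active clusters: node id -> (sorted member-label tuple, member leaf indices)
    active: dict[int, tuple[tuple[str, ...], list[int]]] = {
        i: ((labels[i],), [i]) for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                h = max(d[i, j] for i in active[a][1] for j in active[b][1])
                key_ab = tuple(sorted((active[a][0], active[b][0])))
                cand = (h, key_ab, a, b)
                if best is None or cand < best:
                    best = cand
        h, _, a, b = best
        merges.append((a, b, h))
        merged_key = tuple(sorted(active[a][0] + active[b][0]))
        merged_idx = active[a][1] + active[b][1]
        del active[a], active[b]
        active[next_node] = (merged_key, merged_idx)
        next_node += 1
    return Dendrogram(leaves=labels, merges=merges)


def cut_k(dg: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k clusters by removing the k-1 highest merges.

    Complete-linkage heights are non-decreasing in merge order, so the
    highest merges are the last ones.  Clusters are numbered by
    decreasing size (ties broken by smallest member label).
    """
    if not 1 <= k <= dg.n:
        raise InputError(f"k={k} out of range 1..{dg.n}")
    parent = list(range(dg.n + len(dg.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j, (a, b, _) in enumerate(dg.merges[: dg.n - k]):
        node = dg.n + j
        parent[find(a)] = node
        parent[find(b)] = node

    comps: dict[int, list[str]] = {}
    for i, leaf in enumerate(dg.leaves):
        comps.setdefault(find(i), []).append(leaf)
    ordered = sorted(comps.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {m: c for c, members in enumerate(ordered, start=1) for m in members}
    return ClusterAssignment(labels=labels, k=k)


def sibling_pairs(
    dg: Dendrogram, pairing: Mapping[str, str]
) -> tuple[int, list[tuple[str, str]]]:
    """Count partner pairs that merge while both are still singletons.

    ``pairing`` must be an involution on the leaves (each profile maps to
    its partner and back).  Returns the number of sibling pairs and the
    list of pairs, each ordered and the list sorted.
    """
    leaf_set = set(dg.leaves)
    for a, b in pairing.items():
        if a not in leaf_set or b not in leaf_set:
            raise InputError(f"pairing member missing from leaves: {a!r} or {b!r}")
        if pairing.get(b) != a or a == b:
            raise InputError(f"pairing is not an involution at {a!r}")
    index_of = {leaf: i for i, leaf in enumerate(dg.leaves)}
    found = []
    for a, b, _ in dg.merges:
        if a < dg.n and b < dg.n:
            la, lb = dg.leaves[a], dg.leaves[b]
            if pairing.get(la) == lb:
                found.append(tuple(sorted((la, lb))))
    return len(found), sorted(found)


def cluster_frame(assignment: ClusterAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(assignment.labels.items()), columns=["profile", "cluster"]
    )
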
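"""UPGMA clustering of a segment's GLOCON matrix into conformational states.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two clusters with the smallest *average* pairwise dissimilarity; the
merge height is that average.  The dendrogram is cut at a fraction of the
maximum pairwise score (default 70%), and each resulting cluster —
approximating one conformational state — is represented by its medoid.

The implementation is written in-house rather than via scipy linkage so
that tie-breaking is fully specified: among equally dissimilar cluster
pairs the pair with the lexicographically smallest (min member id, min
member id) is merged first.  This makes cluster labels and representatives
reproducible across platforms and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .score import GloconMatrix


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree.

    ``leaves`` are chain ids; node i < n is leaf i, node n + k is the
    cluster created by ``merges[k] = (left, right, height)``.  Heights are
    non-decreasing (average linkage is monotone).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth = height/2)."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        label: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for k, (lhs, rhs, h) in enumerate(self.merges):
            node = n + k
            height[node] = h
            bl_l = (h - height[lhs]) / 2.0
            bl_r = (h - height[rhs]) / 2.0
            label[node] = f"({label[lhs]}:{bl_l:.6f},{label[rhs]}:{bl_r:.6f})"
        return label[n + len(self.merges) - 1] + ";"


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering obtained by cutting a dendrogram.

    Labels are 1-based, ordered by decreasing cluster size (ties broken by
    the lexicographically smallest member id).  Each cluster's
    representative is its medoid under the GLOCON matrix.
    """

    labels: dict[str, int]
    cut_height: float
    representatives: dict[int, str]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, label: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == label)


def _validate_matrix(G: np.ndarray) -> None:
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(G, G.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(G) != 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if np.any(G < 0):
        raise ValueError("dissimilarity matrix must be non-negative")


def upgma(g: GloconMatrix) -> Dendrogram:
    """Average-linkage merge tree of a segment's chains.

    Heights are maintained with the Lance-Williams update
    ``d(k, i+j) = (n_i d(k,i) + n_j d(k,j)) / (n_i + n_j)``, which keeps
    every inter-cluster value an exact average of original entries.
    """
    n = len(g.chain_ids)
    if n < 2:
        raise ValueError("need at least 2 chains to cluster")
    _validate_matrix(g.G)

    # active cluster state: node id, size, lexicographically smallest member id
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(g.G[i, j])
    active = {i: (i, 1, g.chain_ids[i]) for i in range(n)}  # key -> (node, size, min id)
    next_node = n
    merges: list[tuple[int, int, float]] = []

    def pair_dist(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        keys = sorted(active)
        best = None
        for ii, a in enumerate(keys):
            for b in keys[ii + 1:]:
                d = pair_dist(a, b)
                ids = tuple(sorted((active[a][2], active[b][2])))
                cand = (d, ids, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, a, b = best
        node_a, size_a, min_a = active[a]
        node_b, size_b, min_b = active[b]
        # child order in the merge record: smaller min member id on the left
        if min_a <= min_b:
            merges.append((node_a, node_b, d))
        else:
            merges.append((node_b, node_a, d))
        for other in keys:
            if other in (a, b):
                continue
            da, db = pair_dist(a, other), pair_dist(b, other)
            dnew = (size_a * da + size_b * db) / (size_a + size_b)
            dist[(min(a, other), max(a, other))] = dnew
        del active[b]
        active[a] = (next_node, size_a + size_b, min(min_a, min_b))
        next_node += 1

    return Dendrogram(tuple(g.chain_ids), tuple(merges))


def select_representative(members: Sequence[str], g: GloconMatrix) -> str:
    """Medoid: the member minimizing summed GLOCON to the other members.

    Ties go to the lexicographically smallest chain id.  A singleton cluster
    is its own representative.
    """
    if not members:
        raise ValueError("cluster has no members")
    idx = {cid: g.chain_ids.index(cid) for cid in members}
    best = min(
        members,
        key=lambda cid: (sum(float(g.G[idx[cid], idx[o]]) for o in members), cid),
    )
    return best


def cut_dendrogram(
    d: Dendrogram, g: GloconMatrix, cut_fraction: float = 0.7
) -> ClusterAssignment:
    """Cut the merge tree at ``cut_fraction`` times the maximum pairwise score.

    Merges with height strictly above the cut are discarded; merges at
    exactly the cut height are kept (threshold inclusive).  The connected
    components of the remaining merges are the clusters.
    """
    if not 0 < cut_fraction <= 1:
        raise ValueError("cut_fraction must be in (0, 1]")
    cut_height = cut_fraction * g.max_offdiagonal

    n = len(d.leaves)
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, (lhs, rhs, h) in enumerate(d.merges):
        if h <= cut_height:
            node = n + k
            parent[find(lhs)] = node
            parent[find(rhs)] = node

    comps: dict[int, list[str]] = {}
    for i, leaf in enumerate(d.leaves):
        comps.setdefault(find(i), []).append(leaf)

    clusters = sorted(comps.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {cid: lbl for lbl, ms in enumerate(clusters, start=1) for cid in ms}
    reps = {lbl: select_representative(ms, g) for lbl, ms in enumerate(clusters, start=1)}
    return ClusterAssignment(labels, cut_height, reps)


def cluster_segment(g: GloconMatrix, cut_fraction: float = 0.7) -> tuple[Dendrogram, ClusterAssignment]:
    """Convenience wrapper: UPGMA then cut."""
    d = upgma(g)
    return d, cut_dendrogram(d, g, cut_fraction)
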
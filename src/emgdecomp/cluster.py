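"""MST single-linkage clustering of isolated MUAPs, with refinement.

Cutting the n−1 largest edges of the minimum spanning tree of the complete
distance graph yields exactly the single-linkage partition into n
clusters, independent of presentation order.  Refinement dissolves
clusters with fewer than three members into an unassigned pool and splits
clusters whose internal MST contains one disproportionately large edge —
the signature of two motor units merged by waveform similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNASSIGNED = -1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(dist: np.ndarray) -> list[tuple[float, int, int]]:
    """Kruskal MST of a complete graph given its distance matrix.

    Edges are processed in (weight, i, j) lexicographic order, so ties are
    broken deterministically by node index.  Returns (w, i, j) tree edges.
    """
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, dist[iu, ju]))
    uf = _UnionFind(n)
    tree = []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        if uf.union(i, j):
            tree.append((float(dist[i, j]), i, j))
            if len(tree) == n - 1:
                break
    return tree


def _components(n: int, edges: list[tuple[float, int, int]]) -> np.ndarray:
    uf = _UnionFind(n)
    for _, i, j in edges:
        uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = remap.setdefault(r, len(remap))
    return labels


def mst_cluster(distance_matrix: np.ndarray, n_clusters: int) -> np.ndarray:
    """Single-linkage partition by removing the largest MST edges.

    Removing the ``n_clusters − 1`` largest-weight edges of the minimum
    spanning tree leaves connected components that are exactly the
    single-linkage clusters.  Labels are integers in order of first
    occurrence.
    """
    dist = np.asarray(distance_matrix, dtype=np.float64)
    n = dist.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    tree = minimum_spanning_tree(dist)
    # ties on weight resolved by (w, i, j) so repeated runs cut identically
    tree_sorted = sorted(tree)
    kept = tree_sorted[: len(tree_sorted) - (n_clusters - 1)] if n_clusters > 1 else tree_sorted
    return _components(n, kept)


def default_n_clusters(n_segments: int, lo: int = 8, hi: int = 12) -> int:
    """Heuristic initial cluster count: n/10 clipped to [8, 12], capped at n."""
    return max(1, min(int(np.clip(n_segments // 10, lo, hi)), n_segments))


def refine(
    labels: np.ndarray,
    distance_matrix: np.ndarray,
    min_size: int = 3,
    split_gap_factor: float = 3.0,
) -> tuple[np.ndarray, list[int]]:
    """Delete undersized clusters and split internally gapped ones.

    Clusters with fewer than ``min_size`` members are dissolved and their
    members moved to the unassigned pool.  A surviving cluster is split
    when the largest edge of its internal MST exceeds
    ``split_gap_factor`` times the mean of its remaining edges *and* both
    resulting components keep at least ``min_size`` members; splitting
    repeats until stable.  Returns the relabelled array (UNASSIGNED = −1)
    and the pool of unassigned indices.
    """
    labels = np.asarray(labels).copy()
    dist = np.asarray(distance_matrix, dtype=np.float64)
    pool: list[int] = []

    changed = True
    while changed:
        changed = False
        for lab in [l for l in np.unique(labels) if l != UNASSIGNED]:
            members = np.flatnonzero(labels == lab)
            if members.size < min_size:
                labels[members] = UNASSIGNED
                pool.extend(members.tolist())
                changed = True
                continue
            sub = dist[np.ix_(members, members)]
            tree = minimum_spanning_tree(sub)
            if len(tree) < 2:
                continue
            weights = np.array([w for w, _, _ in tree])
            k = int(np.argmax(weights))
            others = np.delete(weights, k)
            if others.mean() <= 0 or weights[k] <= split_gap_factor * others.mean():
                continue
            comp = _components(members.size, [e for i, e in enumerate(tree) if i != k])
            side_a = members[comp == comp[0]]
            side_b = members[comp != comp[0]]
            if side_a.size >= min_size and side_b.size >= min_size:
                labels[side_b] = labels.max() + 1
                changed = True

    # compact the surviving labels to 0..n_classes-1 in order of appearance
    remap: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == UNASSIGNED:
            continue
        labels[i] = remap.setdefault(lab, len(remap))
    return labels, sorted(pool)


@dataclass
class ClassTemplates:
    """Per-class mean waveform and mean feature vector."""

    class_ids: list[int]
    waveforms: np.ndarray  # (n_classes, L)
    features: np.ndarray  # (n_classes, p)


def compute_templates(
    labels: np.ndarray, aligned_waveforms: np.ndarray, feature_vectors: np.ndarray
) -> ClassTemplates:
    """Pointwise mean waveform and feature vector of each class."""
    labels = np.asarray(labels)
    W = np.asarray(aligned_waveforms, dtype=np.float64)
    F = np.asarray(feature_vectors, dtype=np.float64)
    class_ids = [int(l) for l in np.unique(labels) if l != UNASSIGNED]
    if not class_ids:
        raise ValueError("no non-empty classes to average")
    wf, ft = [], []
    for lab in class_ids:
        members = labels == lab
        if not members.any():
            raise ValueError(f"class {lab} is empty")
        wf.append(W[members].mean(axis=0))
        ft.append(F[members].mean(axis=0))
    return ClassTemplates(class_ids, np.vstack(wf), np.vstack(ft))
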
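"""Independent brute-force oracles used to cross-check the pipeline.

Every function here re-derives a quantity from first principles (exhaustive
loops, naive agglomeration, textbook formulas) without calling the package's
own implementation, so agreement is evidence of correctness rather than
self-consistency.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_cover_membership(coords: np.ndarray, lower: np.ndarray,
                           upper: np.ndarray, tol: float = 0.0) -> set[int]:
    """Point-in-rectangle check over every (point, bin) pair."""
    members = set()
    for i, p in enumerate(coords):
        if all(lower[a] - tol <= p[a] <= upper[a] + tol for a in range(len(p))):
            members.add(i)
    return members


def brute_single_linkage(D: np.ndarray) -> list[tuple[float, set[frozenset]]]:
    """Naive agglomerative single linkage on a dense distance matrix.

    Returns the merge history as (height, partition-after-merge) pairs.
    """
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    history = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = min(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
        history.append((dist, set(clusters)))
    return history


def brute_gap_partition(D: np.ndarray, n_hist_bins: int = 10) -> set[frozenset]:
    """Single-linkage partition cut at the first empty histogram bin.

    Replays the naive merge history and stops merging at the first height
    inside (or beyond) the first empty bin of the height histogram.
    """
    n = D.shape[0]
    if n == 1:
        return {frozenset([0])}
    history = brute_single_linkage(D)
    heights = np.array([h for h, _ in history])
    if heights.max() == heights.min():
        return history[-1][1]
    counts, edges = np.histogram(heights, bins=n_hist_bins,
                                 range=(heights.min(), heights.max()))
    empty = np.nonzero(counts == 0)[0]
    if empty.size == 0:
        return history[-1][1]
    thr = 0.5 * (edges[empty[0]] + edges[empty[0] + 1])
    partition = {frozenset([i]) for i in range(n)}
    for height, part in history:
        if height > thr:
            break
        partition = part
    return partition


def brute_edges(member_sets: list[np.ndarray]) -> set[tuple[int, int]]:
    """O(n^2) pairwise member-set intersection."""
    edges = set()
    for i in range(len(member_sets)):
        si = set(int(m) for m in member_sets[i])
        for j in range(i + 1, len(member_sets)):
            if si & set(int(m) for m in member_sets[j]):
                edges.add((i, j))
    return edges


def brute_geodesics(X: np.ndarray, k: int) -> np.ndarray:
    """Dijkstra on an independently built symmetric kNN graph (networkx)."""
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    n = len(X)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        neigh = np.argsort(D[i])
        added = 0
        for j in neigh:
            if j == i:
                continue
            g.add_edge(i, j, weight=D[i, j])
            added += 1
            if added == k:
                break
    out = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n):
        for j in range(n):
            out[i, j] = lengths[i][j]
    return out


def brute_participation(edges: list[tuple[int, int]],
                        communities: dict[int, str]) -> dict[int, float]:
    """Per-node PC by explicit link counting over every community."""
    nodes = sorted(communities)
    pc = {}
    for i in nodes:
        links = [v for u, v in edges if u == i] + [u for u, v in edges if v == i]
        links = [v for v in links if v in communities]
        k_i = len(links)
        if k_i == 0:
            pc[i] = np.nan
            continue
        total = 0.0
        for s in set(communities.values()):
            kappa = sum(1 for v in links if communities[v] == s)
            total += (kappa / k_i) ** 2
        pc[i] = 1.0 - total
    return pc


def brute_partial_spearman(x: np.ndarray, y: np.ndarray, cov: np.ndarray) -> float:
    """Step-by-step rank -> residualise -> Pearson pipeline."""
    from scipy.stats import pearsonr, rankdata

    rx, ry = rankdata(x), rankdata(y)
    design = np.column_stack([np.ones(len(x)), cov])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(pearsonr(ex, ey)[0])
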
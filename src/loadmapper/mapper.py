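"""TDA Mapper for frame-by-parcel activation matrices.

Four stages:

1. *Filter*: pairwise distances in the original high-dimensional space, a
   symmetric k-nearest-neighbour graph, all-pairs geodesic (shortest-path)
   distances, and a classical MDS embedding into d dimensions (Isomap-style
   neighbourhood embedding).
2. *Cover*: an r x r grid of axis-aligned bins over the embedding, each bin
   widened so adjacent bins overlap by the gain fraction g of their width.
3. *Partial clustering*: single-linkage clustering of each bin's members
   using original-space distances, cut at the first empty bin of a 10-bin
   histogram of linkage heights; each cluster becomes a graph node.
4. *Graph*: nodes are connected whenever they share at least one frame.

The result is a "shape graph" whose nodes are sets of time frames with
similar whole-brain activation patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .preprocess import CleanSeries


@dataclass
class FilterEmbedding:
    """Low-dimensional coordinates from the geodesic filter."""

    coordinates: np.ndarray  # (n_frames, d)
    k: int
    metric: str
    eigenvalues: np.ndarray | None = None


@dataclass
class CoverBin:
    index: tuple[int, ...]  # grid position per axis
    lower: np.ndarray
    upper: np.ndarray
    members: np.ndarray  # frame indices (rows of the embedding)


@dataclass
class Cover:
    resolution: int
    gain: float
    bins: list[CoverBin]


@dataclass
class MapperNode:
    node_id: int
    members: np.ndarray  # frame indices
    bin_index: tuple[int, ...]


@dataclass
class MapperGraph:
    """Shape graph: member sets per node, intersection edges, provenance."""

    nodes: list[MapperNode]
    edges: list[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def members(self, node_id: int) -> np.ndarray:
        return self.nodes[node_id].members

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(**{k: v for k, v in self.provenance.items()})
        for node in self.nodes:
            g.add_node(
                node.node_id,
                size=int(len(node.members)),
                members=",".join(str(int(m)) for m in node.members),
                bin=",".join(str(i) for i in node.bin_index),
            )
        g.add_edges_from(self.edges)
        return g


def pairwise_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Dense pairwise distance matrix; ``correlation`` is 1 - Pearson r."""
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    return squareform(pdist(X, metric=metric))


def default_k(n_frames: int) -> int:
    return int(np.ceil(np.log2(max(n_frames, 2))))


def _knn_adjacency(D: np.ndarray, k: int) -> csr_matrix:
    """Symmetric kNN graph (union of directed neighbourhoods), weights = D."""
    n = D.shape[0]
    masked = D + np.diag(np.full(n, np.inf))  # exclude self-neighbours
    neigh = np.argpartition(masked, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = neigh.ravel()
    adj = csr_matrix((D[rows, cols], (rows, cols)), shape=(n, n))
    return adj.maximum(adj.T)


def _bridge_components(adj: csr_matrix, D: np.ndarray) -> csr_matrix:
    """Connect components with their single shortest inter-component link."""
    adj = adj.tolil()
    while True:
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        if n_comp == 1:
            return csr_matrix(adj)
        # shortest edge leaving component 0's partition
        in0 = labels == labels[0]
        sub = D[np.ix_(in0, ~in0)]
        i_loc, j_loc = np.unravel_index(np.argmin(sub), sub.shape)
        i = np.nonzero(in0)[0][i_loc]
        j = np.nonzero(~in0)[0][j_loc]
        adj[i, j] = adj[j, i] = D[i, j]


def geodesic_distances(
    X: np.ndarray,
    k: int | None = None,
    metric: str = "euclidean",
) -> tuple[np.ndarray, int]:
    """All-pairs geodesic distances over a symmetric kNN graph.

    If ``k`` is ``None``, the smallest ``k >= ceil(log2(n))`` yielding a
    connected graph is used; an explicitly requested ``k`` whose graph is
    disconnected gets its components bridged by their shortest
    inter-component links.  Returns the distance matrix and the ``k``
    actually used.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    D = pairwise_distances(X, metric)
    if not D.any():
        return np.zeros((n, n)), k or 0
    if k is not None:
        if not 1 <= k < n:
            raise ValueError(f"k must satisfy 1 <= k < n_frames, got {k}")
        adj = _bridge_components(_knn_adjacency(D, k), D)
    else:
        k = min(default_k(n), n - 1)
        while True:
            adj = _knn_adjacency(D, k)
            n_comp, _ = connected_components(adj, directed=False)
            if n_comp == 1 or k >= n - 1:
                break
            k += 1
        if n_comp > 1:
            adj = _bridge_components(adj, D)
    return shortest_path(adj, method="D", directed=False), k


def geodesic_filter(
    X: np.ndarray,
    k: int | None = None,
    d: int = 2,
    metric: str = "euclidean",
) -> FilterEmbedding:
    """Geodesic-distance embedding of frames into ``d`` dimensions.

    Computes :func:`geodesic_distances` and embeds the matrix with classical
    MDS (double centering, top-d eigenvectors scaled by the square root of
    their eigenvalues).  Eigenvector signs are fixed so the largest-magnitude
    loading of each axis is positive, making outputs reproducible.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    G, k_used = geodesic_distances(X, k=k, metric=metric)
    if not G.any():
        warnings.warn("all frames identical; returning a zero embedding")
        return FilterEmbedding(np.zeros((n, d)), k=k_used, metric=metric,
                               eigenvalues=np.zeros(d))
    coords, eigvals = classical_mds(G, d)
    return FilterEmbedding(coordinates=coords, k=k_used, metric=metric, eigenvalues=eigvals)


def classical_mds(D: np.ndarray, d: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Returns coordinates scaled by sqrt(eigenvalue) for the top ``d``
    components (axes with non-positive eigenvalues collapse to zero) and the
    eigenvalues themselves.  Sign convention: each axis is oriented so its
    largest-magnitude coordinate is positive.
    """
    from scipy.linalg import eigh as scipy_eigh

    n = D.shape[0]
    D2 = D**2
    # double centering without forming J explicitly
    row_mean = D2.mean(axis=1, keepdims=True)
    B = -0.5 * (D2 - row_mean - row_mean.T + D2.mean())
    B = (B + B.T) / 2
    eigvals, eigvecs = scipy_eigh(B, subset_by_index=[max(n - d, 0), n - 1])
    idx = np.argsort(eigvals)[::-1][:d]
    lam = eigvals[idx]
    vecs = eigvecs[:, idx]
    coords = np.zeros((n, d))
    for j in range(d):
        if lam[j] > 0:
            axis = vecs[:, j] * np.sqrt(lam[j])
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, j] = axis
    return coords, lam


def cover_bins(emb: FilterEmbedding, r: int = 18, g: float = 0.70) -> Cover:
    """Overlapping axis-aligned grid cover of the embedding.

    Per axis the coordinate range is split into ``r`` base intervals of width
    ``w``; each is widened symmetrically to ``w / (1 - g)`` so that adjacent
    intervals overlap by exactly the fraction ``g`` of their widened width.
    A zero-range axis degenerates to a single interval.  Membership is by
    closed-interval containment; only non-empty bins are kept.
    """
    if r < 1:
        raise ValueError("resolution must be >= 1")
    if not 0 <= g < 1:
        raise ValueError("gain must lie in [0, 1)")
    coords = emb.coordinates
    n, d = coords.shape
    axis_masks: list[np.ndarray] = []  # (n, r_axis) bool per axis
    axis_bounds: list[tuple[np.ndarray, np.ndarray]] = []
    for a in range(d):
        x = coords[:, a]
        mn, mx = x.min(), x.max()
        if mx == mn:
            axis_masks.append(np.ones((n, 1), dtype=bool))
            axis_bounds.append((np.array([mn - 0.5]), np.array([mn + 0.5])))
            continue
        w = (mx - mn) / r
        half = w / (2.0 * (1.0 - g))
        centers = mn + (np.arange(r) + 0.5) * w
        lower = centers - half
        upper = centers + half
        tol = 1e-12 * max(abs(mn), abs(mx), 1.0)
        mask = (x[:, None] >= lower[None, :] - tol) & (x[:, None] <= upper[None, :] + tol)
        axis_masks.append(mask)
        axis_bounds.append((lower, upper))

    bins: list[CoverBin] = []
    shape = [m.shape[1] for m in axis_masks]
    for flat in range(int(np.prod(shape))):
        idx = np.unravel_index(flat, shape)
        mask = axis_masks[0][:, idx[0]]
        for a in range(1, d):
            mask = mask & axis_masks[a][:, idx[a]]
        members = np.nonzero(mask)[0]
        if members.size == 0:
            continue
        bins.append(
            CoverBin(
                index=tuple(int(i) for i in idx),
                lower=np.array([axis_bounds[a][0][idx[a]] for a in range(d)]),
                upper=np.array([axis_bounds[a][1][idx[a]] for a in range(d)]),
                members=members,
            )
        )
    return Cover(resolution=r, gain=g, bins=bins)


def _gap_cut_threshold(heights: np.ndarray, n_hist_bins: int = 10) -> float:
    """First-empty-bin heuristic on the linkage-height histogram.

    The histogram spans the observed height range, so an empty bin marks a
    genuine gap between within-cluster and between-cluster merge distances.
    Returns the cut threshold (midpoint of the first empty bin), or ``inf``
    when no bin is empty or all heights coincide (a single cluster).
    """
    hmin, hmax = heights.min(), heights.max()
    if hmax == hmin:
        return np.inf
    counts, edges = np.histogram(heights, bins=n_hist_bins, range=(hmin, hmax))
    empty = np.nonzero(counts == 0)[0]
    if empty.size == 0:
        return np.inf
    i = int(empty[0])
    return 0.5 * (edges[i] + edges[i + 1])


def partial_cluster(
    cover: Cover,
    X: np.ndarray,
    metric: str = "euclidean",
    n_hist_bins: int = 10,
) -> list[MapperNode]:
    """Single-linkage partial clustering of each cover bin in original space.

    Each bin's members are clustered on their original high-dimensional
    distances; the dendrogram is cut with the histogram-gap heuristic, and
    every resulting cluster becomes one node.  Singleton bins yield singleton
    nodes; empty bins were already dropped by the cover.
    """
    nodes: list[MapperNode] = []
    node_id = 0
    for cbin in cover.bins:
        members = cbin.members
        if members.size == 1:
            nodes.append(MapperNode(node_id, members.copy(), cbin.index))
            node_id += 1
            continue
        dists = pdist(X[members], metric=metric)
        Z = linkage(dists, method="single")
        thr = _gap_cut_threshold(Z[:, 2], n_hist_bins)
        if np.isinf(thr):
            labels = np.ones(members.size, dtype=int)
        else:
            labels = fcluster(Z, t=thr, criterion="distance")
        for lab in np.unique(labels):
            nodes.append(MapperNode(node_id, members[labels == lab], cbin.index))
            node_id += 1
    return nodes


def build_graph(nodes: Sequence[MapperNode], provenance: dict | None = None) -> MapperGraph:
    """Connect nodes sharing at least one frame (no self-edges)."""
    frame_to_nodes: dict[int, list[int]] = {}
    for node in nodes:
        for f in node.members:
            frame_to_nodes.setdefault(int(f), []).append(node.node_id)
    edges: set[tuple[int, int]] = set()
    for owners in frame_to_nodes.values():
        for i in range(len(owners)):
            for j in range(i + 1, len(owners)):
                u, v = owners[i], owners[j]
                edges.add((u, v) if u < v else (v, u))
    return MapperGraph(nodes=list(nodes), edges=sorted(edges),
                       provenance=dict(provenance or {}))


def mapper_from_embedding(
    emb: FilterEmbedding,
    X: np.ndarray,
    r: int = 18,
    g: float = 0.70,
    metric: str = "euclidean",
) -> MapperGraph:
    """Cover + partial clustering + graph, given a precomputed filter.

    Splitting the filter out lets resolution/gain sweeps reuse the embedding,
    which does not depend on r or g.
    """
    cover = cover_bins(emb, r=r, g=g)
    nodes = partial_cluster(cover, X, metric=metric)
    provenance = {
        "k": int(emb.k),
        "resolution": int(r),
        "gain": float(g),
        "metric": metric,
        "dim": int(emb.coordinates.shape[1]),
    }
    return build_graph(nodes, provenance)


def run_mapper(
    clean: CleanSeries | np.ndarray,
    k: int | None = None,
    r: int = 18,
    g: float = 0.70,
    d: int = 2,
    metric: str = "euclidean",
) -> MapperGraph:
    """Full Mapper pipeline on a cleaned session (both runs concatenated).

    Node member indices refer to rows of the input matrix (retained frames);
    when a :class:`CleanSeries` is given, the mapping back to the original
    labelled timeline is recorded in the provenance as ``retained_indices``.
    """
    if isinstance(clean, CleanSeries):
        X = clean.data
        retained = clean.retained_indices
    else:
        X = np.asarray(clean, dtype=float)
        retained = None
    emb = geodesic_filter(X, k=k, d=d, metric=metric)
    graph = mapper_from_embedding(emb, X, r=r, g=g, metric=metric)
    if retained is not None:
        graph.provenance["retained_indices"] = [int(i) for i in retained]
    return graph
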
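"""Mapper stages against exhaustive oracles, plus structural properties."""

import numpy as np
import pytest

import oracles
from loadmapper.mapper import (
    FilterEmbedding,
    MapperNode,
    build_graph,
    classical_mds,
    cover_bins,
    geodesic_distances,
    geodesic_filter,
    mapper_from_embedding,
    partial_cluster,
    run_mapper,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestGeodesicFilter:
    def test_planar_points_embed_with_high_distance_fidelity(self):
        """Points on a 2-D affine plane in 8-D: embedded distances correlate
        with true planar distances at r^2 > 0.99."""
        rng = _rng(1)
        uv = rng.uniform(-1, 1, (100, 2))
        basis = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        X = uv @ basis.T + 0.5
        emb = geodesic_filter(X, k=40, d=2)
        from scipy.spatial.distance import pdist

        d_true = pdist(uv)
        d_emb = pdist(emb.coordinates)
        r = np.corrcoef(d_true, d_emb)[0, 1]
        assert r**2 > 0.99

    def test_arc_geodesics_match_dijkstra_oracle(self):
        """1-D arc in high-D: geodesic matrix equals an independent networkx
        Dijkstra oracle exactly, and the first embedding axis orders points
        monotonically along the arc."""
        rng = _rng(2)
        # near-even spacing keeps the kNN chain connected; jitter avoids
        # distance ties that implementations may break differently
        t = np.linspace(0, np.pi, 60) + rng.uniform(-0.008, 0.008, 60)
        t.sort()
        circle = np.column_stack([np.cos(t), np.sin(t)])
        basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        X = circle @ basis.T
        k = 3
        G, k_used = geodesic_distances(X, k=k)
        assert k_used == k
        oracle = oracles.brute_geodesics(X, k)
        np.testing.assert_allclose(G, oracle, atol=1e-10)
        emb = geodesic_filter(X, k=k, d=2)
        coord0 = emb.coordinates[:, 0]
        diffs = np.diff(coord0)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_identical_points_embed_to_zero_with_warning(self):
        X = np.ones((10, 4))
        with pytest.warns(UserWarning, match="identical"):
            emb = geodesic_filter(X, d=2)
        np.testing.assert_array_equal(emb.coordinates, np.zeros((10, 2)))

    def test_k_bounds_enforced(self):
        X = _rng(3).normal(size=(10, 3))
        with pytest.raises(ValueError):
            geodesic_filter(X, k=0)
        with pytest.raises(ValueError):
            geodesic_filter(X, k=10)

    def test_disconnected_graph_bridged(self):
        """Two distant clouds with tiny k still yield finite geodesics."""
        rng = _rng(4)
        X = np.vstack([rng.normal(0, 0.1, (15, 3)), rng.normal(50, 0.1, (15, 3))])
        G, _ = geodesic_distances(X, k=2)
        assert np.isfinite(G).all()
        assert G[0, 20] > 40  # bridge preserves the large separation

    def test_mds_sign_convention_deterministic(self):
        X = _rng(5).normal(size=(30, 6))
        e1 = geodesic_filter(X, k=5)
        e2 = geodesic_filter(X, k=5)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)
        for j in range(e1.coordinates.shape[1]):
            axis = e1.coordinates[:, j]
            assert axis[np.argmax(np.abs(axis))] >= 0


class TestCover:
    def test_single_bin_contains_everything(self):
        emb = FilterEmbedding(_rng(0).normal(size=(25, 2)), k=3, metric="euclidean")
        cover = cover_bins(emb, r=1, g=0.0)
        assert len(cover.bins) == 1
        assert set(cover.bins[0].members) == set(range(25))

    def test_disjoint_corner_bins(self):
        emb = FilterEmbedding(np.array([[0.0, 0.0], [1.0, 1.0]]), k=1,
                              metric="euclidean")
        cover = cover_bins(emb, r=2, g=0.0)
        member_sets = [set(b.members) for b in cover.bins]
        assert {0} in member_sets and {1} in member_sets
        for b in cover.bins:
            assert len(b.members) == 1

    def test_membership_matches_point_in_rectangle_oracle(self):
        coords = _rng(7).normal(size=(150, 2))
        emb = FilterEmbedding(coords, k=4, metric="euclidean")
        cover = cover_bins(emb, r=18, g=0.7)
        for b in cover.bins:
            oracle = oracles.brute_cover_membership(coords, b.lower, b.upper,
                                                    tol=1e-9)
            assert set(int(m) for m in b.members) == oracle
        # coverage: every frame in at least one bin
        covered = set()
        for b in cover.bins:
            covered.update(int(m) for m in b.members)
        assert covered == set(range(150))

    def test_adjacent_bins_overlap_by_gain_fraction(self):
        emb = FilterEmbedding(np.linspace(0, 1, 50)[:, None] * [1, 0], k=3,
                              metric="euclidean")
        g = 0.7
        cover = cover_bins(emb, r=5, g=g)
        axis0 = sorted({(b.lower[0], b.upper[0]) for b in cover.bins})
        for (lo1, hi1), (lo2, hi2) in zip(axis0[:-1], axis0[1:]):
            width = hi1 - lo1
            overlap = hi1 - lo2
            assert overlap / width == pytest.approx(g)

    def test_zero_range_axis_collapses_to_one_interval(self):
        coords = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        emb = FilterEmbedding(coords, k=3, metric="euclidean")
        cover = cover_bins(emb, r=4, g=0.5)
        assert {b.index[1] for b in cover.bins} == {0}

    def test_gain_monotonicity(self):
        """Increasing g (fixed r) never decreases total membership count."""
        emb = FilterEmbedding(_rng(9).normal(size=(100, 2)), k=4,
                              metric="euclidean")
        totals = []
        for g in (0.0, 0.3, 0.6, 0.7, 0.8):
            cover = cover_bins(emb, r=10, g=g)
            totals.append(sum(len(b.members) for b in cover.bins))
        assert all(b >= a for a, b in zip(totals[:-1], totals[1:]))

    def test_invalid_parameters_rejected(self):
        emb = FilterEmbedding(np.zeros((5, 2)), k=1, metric="euclidean")
        with pytest.raises(ValueError):
            cover_bins(emb, r=0)
        with pytest.raises(ValueError):
            cover_bins(emb, g=1.0)


class TestPartialClustering:
    def _one_bin_cover(self, n):
        emb = FilterEmbedding(np.zeros((n, 2)), k=1, metric="euclidean")
        return cover_bins(emb, r=1, g=0.0)

    def test_singleton_bin_yields_singleton_node(self):
        X = np.array([[0.0, 0.0]])
        nodes = partial_cluster(self._one_bin_cover(1), X)
        assert len(nodes) == 1
        assert list(nodes[0].members) == [0]

    def test_two_separated_clouds_yield_two_nodes(self):
        rng = _rng(11)
        X = np.vstack([rng.normal(0, 0.05, (10, 3)), rng.normal(10, 0.05, (10, 3))])
        nodes = partial_cluster(self._one_bin_cover(20), X)
        parts = {frozenset(int(m) for m in n.members) for n in nodes}
        assert parts == {frozenset(range(10)), frozenset(range(10, 20))}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partition_matches_naive_single_linkage_oracle(self, seed):
        rng = _rng(seed)
        X = rng.normal(size=(rng.integers(5, 25), 4))
        nodes = partial_cluster(self._one_bin_cover(len(X)), X)
        got = {frozenset(int(m) for m in n.members) for n in nodes}
        from scipy.spatial.distance import cdist

        expected = oracles.brute_gap_partition(cdist(X, X))
        assert got == expected


class TestGraph:
    def test_shared_frame_creates_edge(self):
        nodes = [MapperNode(0, np.array([1, 2]), (0,)),
                 MapperNode(1, np.array([2, 3]), (1,)),
                 MapperNode(2, np.array([4]), (2,))]
        g = build_graph(nodes)
        assert g.edges == [(0, 1)]

    def test_disjoint_cover_gives_empty_edge_set(self):
        nodes = [MapperNode(i, np.array([i]), (i,)) for i in range(5)]
        assert build_graph(nodes).edges == []

    def test_edges_match_pairwise_intersection_oracle(self):
        rng = _rng(13)
        member_sets = [rng.choice(60, size=rng.integers(1, 8), replace=False)
                       for _ in range(40)]
        nodes = [MapperNode(i, m, (i,)) for i, m in enumerate(member_sets)]
        g = build_graph(nodes)
        assert set(g.edges) == oracles.brute_edges(member_sets)


class TestRunMapper:
    def test_two_state_data_separates_into_load_like_communities(self):
        """Frames alternating between two distant activation states give a
        graph whose nodes are pure in state."""
        rng = _rng(17)
        state = np.repeat(np.arange(8) % 2, 25)
        X = rng.normal(0, 0.3, (200, 10)) + state[:, None] * 8.0
        graph = run_mapper(X, r=6, g=0.5)
        for node in graph.nodes:
            states = state[node.members]
            assert len(set(states.tolist())) == 1
        # edges never cross the two state groups
        for u, v in graph.edges:
            assert state[graph.nodes[u].members[0]] == state[graph.nodes[v].members[0]]

    def test_frame_order_permutation_equivalence(self):
        """Shuffling frame order yields the same graph up to node identity."""
        rng = _rng(19)
        X = rng.normal(size=(80, 6))
        perm = rng.permutation(80)
        g1 = run_mapper(X, k=6, r=4, g=0.4)
        g2 = run_mapper(X[perm], k=6, r=4, g=0.4)
        sets1 = {frozenset(int(m) for m in n.members) for n in g1.nodes}
        sets2 = {frozenset(int(perm[m]) for m in n.members) for n in g2.nodes}
        assert sets1 == sets2
        def edge_sets(g, mapper=lambda m: int(m)):
            out = set()
            for u, v in g.edges:
                a = frozenset(mapper(m) for m in g.nodes[u].members)
                b = frozenset(mapper(m) for m in g.nodes[v].members)
                out.add(frozenset([a, b]))
            return out
        assert edge_sets(g1) == edge_sets(g2, mapper=lambda m: int(perm[m]))

    def test_degenerate_cover_r1_g0(self):
        rng = _rng(23)
        X = rng.normal(size=(40, 5))
        graph = run_mapper(X, r=1, g=0.0)
        covered = set()
        for n in graph.nodes:
            covered.update(int(m) for m in n.members)
        assert covered == set(range(40))
        # clusters within one bin partition the frames: no shared members
        assert graph.edges == []

    def test_coverage_for_default_parameters(self):
        rng = _rng(29)
        X = rng.normal(size=(120, 8))
        graph = run_mapper(X, r=18, g=0.7)
        covered = set()
        for n in graph.nodes:
            covered.update(int(m) for m in n.members)
        assert covered == set(range(120))
        assert graph.provenance["resolution"] == 18
        assert graph.provenance["gain"] == 0.7
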
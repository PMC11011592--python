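import itertools

import numpy as np
import pytest

from dfcb import baselines, dfc


# ---------------------------------------------------------------- oracles
# Exhaustive enumeration oracles for small graphs (≤ 6 nodes): Floyd-
# Warshall distances, DFS enumeration of all shortest paths, triangle
# counting. Independent of the implementations they check.

def oracle_distances(adj):
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
    return dist


def oracle_clustering(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def oracle_transitivity(adj):
    n = adj.shape[0]
    triangles = sum(
        adj[a, b] * adj[b, c] * adj[a, c]
        for a, b, c in itertools.combinations(range(n), 3)
    )
    triads = sum(
        int(adj[v].sum() * (adj[v].sum() - 1) / 2) for v in range(n)
    )
    return 3.0 * triangles / triads if triads else 0.0


def oracle_cpl(adj):
    dist = oracle_distances(adj)
    finite = dist[(dist > 0) & np.isfinite(dist)]
    return finite.mean() if finite.size else 0.0


def oracle_efficiency(adj):
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = oracle_distances(adj)
    inv = np.zeros_like(dist)
    mask = (dist > 0) & np.isfinite(dist)
    inv[mask] = 1.0 / dist[mask]
    return inv.sum() / (n * (n - 1))


def _all_shortest_paths(adj, s, t, dist):
    """All simple shortest s→t paths by depth-first enumeration."""
    if not np.isfinite(dist[s, t]) or s == t:
        return []
    target = dist[s, t]
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        if len(path) - 1 >= target:
            return
        for w in np.flatnonzero(adj[v]):
            if w not in path and dist[s, w] == len(path) and dist[w, t] == target - len(path):
                extend(path + [w])

    extend([s])
    return paths


def oracle_betweenness(adj):
    n = adj.shape[0]
    dist = oracle_distances(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def oracle_within_module_z(adj, part):
    n = adj.shape[0]
    z = np.zeros(n)
    for mod in np.unique(part):
        nodes = np.flatnonzero(part == mod)
        kappa = np.array([adj[v, nodes].sum() for v in nodes], dtype=float)
        sd = kappa.std()
        if sd > 0:
            z[nodes] = (kappa - kappa.mean()) / sd
    return z


def oracle_participation(adj, part):
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        k = adj[v].sum()
        if k == 0:
            continue
        out[v] = 1.0 - sum(
            (adj[v, part == mod].sum() / k) ** 2 for mod in np.unique(part)
        )
    return out


def random_graph(rng, n):
    adj = (rng.random((n, n)) < rng.uniform(0.2, 0.8)).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T


# ------------------------------------------------------------------ tests

class TestCentralMoments:
    def test_first_moment_vanishes(self, rng):
        x = rng.standard_normal(30)
        assert baselines.central_moments(x, 3)[0] == 0.0

    def test_second_is_population_sd(self, rng):
        x = rng.standard_normal(30)
        assert baselines.central_moments(x, 2)[1] == pytest.approx(x.std(), abs=1e-12)

    def test_hand_computed_third_moment(self):
        # series [0,0,3]: mean 1, third central moment 2, signed cube root
        m = baselines.central_moments(np.array([0.0, 0.0, 3.0]), 3)
        assert m[2] == pytest.approx(2 ** (1 / 3), abs=1e-12)

    def test_signed_root_preserves_skew_direction(self):
        m = baselines.central_moments(np.array([0.0, 0.0, -3.0]), 3)
        assert m[2] == pytest.approx(-(2 ** (1 / 3)), abs=1e-12)

    def test_location_invariance(self, rng):
        x = rng.standard_normal(25)
        np.testing.assert_allclose(
            baselines.central_moments(x, 4),
            baselines.central_moments(x + 42.0, 4),
            atol=1e-9,
        )

    def test_positive_homogeneity_degree_one(self, rng):
        x = rng.standard_normal(25)
        c = 3.7
        np.testing.assert_allclose(
            baselines.central_moments(c * x, 4),
            c * baselines.central_moments(x, 4),
            atol=1e-9,
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            baselines.central_moments(np.array([1.0]), 2)


class TestCentralMomentFeatures:
    def _A(self, values):
        values = np.asarray(values, float)
        pairs = np.array([[1, 2], [1, 3], [2, 3]])[: values.shape[0]]
        return dfc.EdgeTimeMatrix(values, pairs, 3)

    def test_constant_edge_series_all_zero(self):
        feats = baselines.central_moment_features(self._A(np.full((3, 6), 0.4)), 4)
        np.testing.assert_allclose(feats, 0, atol=1e-12)

    def test_rowwise_composition(self, rng):
        vals = rng.standard_normal((3, 9))
        feats = baselines.central_moment_features(self._A(vals), 4)
        for m in range(3):
            np.testing.assert_allclose(
                feats[m], baselines.central_moments(vals[m], 4), atol=1e-12
            )

    def test_symmetric_distribution_small_odd_moments(self, rng):
        # undo the cube root: the third central moment itself should be
        # near zero for a symmetric distribution (sd ≈ √(15/K))
        vals = rng.standard_normal((2, 20000))
        feats = baselines.central_moment_features(self._A(vals), 3)
        mu3 = np.sign(feats[:, 2]) * np.abs(feats[:, 2]) ** 3
        assert np.all(np.abs(mu3) < 3 * np.sqrt(15 / 20000))


class TestBinarize:
    def test_exact_edge_count(self, rng):
        D = dfc.devectorize(rng.random(10), 5)
        adj = baselines.binarize_top_fraction(D, 0.2)
        assert adj[np.triu_indices(5, 1)].sum() == 2  # floor(0.2·10)

    def test_aal_scale_density(self, rng):
        D = dfc.devectorize(rng.random(6670), 116)
        adj = baselines.binarize_top_fraction(D, 0.2)
        assert adj[np.triu_indices(116, 1)].sum() == 1334

    def test_ties_resolved_by_edge_order(self):
        D = dfc.devectorize(np.full(10, 0.5), 5)
        adj = baselines.binarize_top_fraction(D, 0.2)
        iu, ju = np.triu_indices(5, 1)
        kept = [(iu[m] + 1, ju[m] + 1) for m in range(10) if adj[iu[m], ju[m]]]
        assert kept == [(1, 2), (1, 3)]

    def test_output_symmetric_zero_diagonal(self, rng):
        adj = baselines.binarize_top_fraction(dfc.devectorize(rng.random(15), 6), 0.4)
        np.testing.assert_array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        assert set(np.unique(adj)) <= {0, 1}


class TestGraphMetrics:
    def test_triangle_graph(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        per, mean = baselines.clustering_coefficient(adj)
        np.testing.assert_allclose(per, 1.0)
        assert mean == 1.0
        assert baselines.transitivity(adj) == 1.0
        assert baselines.characteristic_path_length(adj) == 1.0
        assert baselines.global_efficiency(adj) == 1.0

    def test_path_graph_p3(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        per, _ = baselines.clustering_coefficient(adj)
        np.testing.assert_allclose(per, 0.0)
        assert baselines.characteristic_path_length(adj) == pytest.approx(4 / 3)
        assert baselines.global_efficiency(adj) == pytest.approx(5 / 6)
        np.testing.assert_allclose(baselines.betweenness(adj), [0, 1, 0])

    def test_disconnected_pair_contributes_zero_efficiency(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        assert baselines.global_efficiency(adj) == pytest.approx((2 * 1) / 6)
        assert baselines.characteristic_path_length(adj) == 1.0  # reachable pairs only

    @pytest.mark.parametrize("trial", range(25))
    def test_metrics_match_enumeration_oracles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        adj = random_graph(rng, int(rng.integers(3, 7)))
        per, mean = baselines.clustering_coefficient(adj)
        np.testing.assert_allclose(per, oracle_clustering(adj), atol=1e-10)
        assert baselines.transitivity(adj) == pytest.approx(oracle_transitivity(adj), abs=1e-10)
        assert baselines.characteristic_path_length(adj) == pytest.approx(oracle_cpl(adj), abs=1e-10)
        assert baselines.global_efficiency(adj) == pytest.approx(oracle_efficiency(adj), abs=1e-10)
        np.testing.assert_allclose(baselines.betweenness(adj), oracle_betweenness(adj), atol=1e-8)
        part = rng.integers(0, 2, adj.shape[0])
        np.testing.assert_allclose(
            baselines.within_module_z(adj, part), oracle_within_module_z(adj, part), atol=1e-10
        )
        np.testing.assert_allclose(
            baselines.participation(adj, part), oracle_participation(adj, part), atol=1e-10
        )

    def test_single_module_regular_graph_zero_z(self):
        adj = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)  # 3-regular
        np.testing.assert_allclose(baselines.within_module_z(adj, np.zeros(4, int)), 0.0)

    def test_participation_edge_cases(self):
        # star center with edges split evenly across 2 modules → 1 − 2·(1/2)² = 0.5
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        part = np.array([0, 0, 0, 1, 1])
        p = baselines.participation(adj, part)
        assert p[0] == pytest.approx(0.5)
        # leaves connect only to the center's module (module 0)
        assert p[1] == pytest.approx(0.0)
        assert p[3] == pytest.approx(0.0)


class TestTopoFeatures:
    def _dfc(self, rng, R=6, K=3):
        mats = np.stack([dfc.devectorize(rng.random(R * (R - 1) // 2), R) for _ in range(K)])
        return dfc.DFCSeries(mats, dfc.WindowSpec(4, 2))

    def test_feature_length(self, rng):
        R = 6
        feats = baselines.topo_features(self._dfc(rng, R=R), 0.3)
        assert feats.size == (4 + 3 * R) * 2

    def test_single_window_zero_sd(self, rng):
        feats = baselines.topo_features(self._dfc(rng, K=1), 0.3)
        half = feats.size // 2
        np.testing.assert_allclose(feats[half:], 0.0, atol=1e-12)

    def test_identical_windows_zero_sd_mean_equals_single(self, rng):
        series = self._dfc(rng, K=1)
        tripled = dfc.DFCSeries(np.repeat(series.matrices, 3, axis=0), series.window_spec)
        f1 = baselines.topo_features(series, 0.3, partition=np.zeros(6, int))
        f3 = baselines.topo_features(tripled, 0.3, partition=np.zeros(6, int))
        np.testing.assert_allclose(f3, f1, atol=1e-12)

    def test_fixed_partition_deterministic(self, rng):
        series = self._dfc(rng)
        part = np.array([0, 0, 0, 1, 1, 1])
        f1 = baselines.topo_features(series, 0.3, partition=part)
        f2 = baselines.topo_features(series, 0.3, partition=part)
        np.testing.assert_array_equal(f1, f2)
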
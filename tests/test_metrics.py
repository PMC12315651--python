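"""Graph-metric correctness against brute-force oracles and closed forms."""

import itertools

import networkx as nx
import numpy as np
import pytest

from scnmorph import metrics as gm

from conftest import random_adjacency


# ---------------------------------------------------------------- oracles


def brute_clustering(a: np.ndarray) -> float:
    """Triangle/triple enumeration over all node triples."""
    n = a.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def bfs_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(a[u]):
                    if d[s, v] == np.inf:
                        d[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return d


def brute_lp(a: np.ndarray) -> float:
    """Mean distance over ordered pairs in the largest component (BFS oracle)."""
    d = bfs_distances(a)
    comps = []
    seen = set()
    for i in range(a.shape[0]):
        if i in seen:
            continue
        comp = set(np.flatnonzero(np.isfinite(d[i])).tolist())
        seen |= comp
        comps.append(sorted(comp))
    big = max(comps, key=len)
    vals = [d[i, j] for i in big for j in big if i != j]
    return float(np.mean(vals))


def brute_eglob(a: np.ndarray) -> float:
    d = bfs_distances(a)
    n = a.shape[0]
    s = sum(1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j]))
    return s / (n * (n - 1))


def brute_eloc(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) >= 2:
            total += brute_eglob(a[np.ix_(nbrs, nbrs)])
    return total / n


# ------------------------------------------------------------ closed forms


def complete_graph(n):
    return np.ones((n, n)) - np.eye(n)


def star_graph(n):
    a = np.zeros((n, n))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def path3():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return a


@pytest.mark.parametrize(
    "adj,expected",
    [
        (complete_graph(5), 1.0),
        (star_graph(5), 0.0),
    ],
)
def test_clustering_closed_forms(adj, expected):
    assert gm.clustering_coefficient(adj) == pytest.approx(expected, abs=1e-12)


def test_path_length_closed_forms():
    assert gm.characteristic_path_length(complete_graph(6)) == pytest.approx(1.0)
    assert gm.characteristic_path_length(path3()) == pytest.approx(4 / 3)


def test_global_efficiency_closed_forms():
    assert gm.global_efficiency(complete_graph(6)) == pytest.approx(1.0)
    assert gm.global_efficiency(path3()) == pytest.approx(5 / 6)
    # two disjoint edges on 4 nodes: disconnected pairs contribute 0
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
    assert gm.global_efficiency(a) == pytest.approx(1 / 3)


def test_local_efficiency_closed_forms():
    assert gm.local_efficiency(complete_graph(4)) == pytest.approx(1.0)
    assert gm.local_efficiency(star_graph(5)) == pytest.approx(0.0)


def test_edgeless_lp_undefined():
    with pytest.raises(gm.UndefinedMetricError):
        gm.characteristic_path_length(np.zeros((4, 4)))


# ----------------------------------------------------- brute-force equality


@pytest.mark.parametrize("seed,p", [(0, 0.3), (1, 0.5), (2, 0.7), (3, 0.25)])
def test_metrics_match_brute_force(seed, p, rng):
    a = random_adjacency(9, p, np.random.default_rng(seed))
    assert gm.clustering_coefficient(a) == pytest.approx(brute_clustering(a), abs=1e-12)
    assert gm.global_efficiency(a) == pytest.approx(brute_eglob(a), abs=1e-12)
    assert gm.local_efficiency(a) == pytest.approx(brute_eloc(a), abs=1e-12)
    if a.sum() > 0:
        assert gm.characteristic_path_length(a) == pytest.approx(brute_lp(a), abs=1e-12)


def test_nodal_profile_against_oracles():
    a = random_adjacency(9, 0.4, np.random.default_rng(5))
    prof = gm.nodal_profile(a)
    # degrees sum to 2|E|
    assert prof.degree.sum() == a.sum()
    d = bfs_distances(a)
    n = a.shape[0]
    for i in range(n):
        eff = np.mean([1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0 for j in range(n) if j != i])
        assert prof.nodal_efficiency[i] == pytest.approx(eff, abs=1e-12)
    g = nx.from_numpy_array(a)
    btw = nx.betweenness_centrality(g, normalized=True)
    for i in range(n):
        assert prof.betweenness[i] == pytest.approx(btw[i], abs=1e-12)


def test_nodal_profile_star_and_complete():
    prof = gm.nodal_profile(complete_graph(4))
    assert np.allclose(prof.degree, 3)
    assert np.allclose(prof.nodal_efficiency, 1.0)
    assert np.allclose(prof.betweenness, 0.0)
    prof = gm.nodal_profile(star_graph(5))
    assert prof.betweenness[0] == pytest.approx(1.0)
    assert np.allclose(prof.betweenness[1:], 0.0)


# -------------------------------------------------------- random reference


def test_random_reference_preserves_degrees():
    a = nx.to_numpy_array(nx.watts_strogatz_graph(30, 4, 0.1, seed=0))
    refs = gm.random_reference(a, n_graphs=5, seed=1)
    deg = np.sort(a.sum(1))
    for r in refs:
        assert r.sum() == a.sum()  # edge count preserved
        assert np.allclose(np.sort(r.sum(1)), deg)  # degree sequence preserved
        assert np.allclose(r, r.T)
        assert np.all(np.diag(r) == 0)


def test_random_reference_lowers_lattice_clustering():
    a = nx.to_numpy_array(nx.watts_strogatz_graph(50, 4, 0.0, seed=0))
    refs = gm.random_reference(a, n_graphs=30, seed=2)
    cp_refs = np.mean([gm.clustering_coefficient(r) for r in refs])
    assert cp_refs < gm.clustering_coefficient(a)


def test_random_reference_too_sparse():
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 1
    with pytest.raises(ValueError):
        gm.random_reference(a, n_graphs=2, seed=0)


def test_small_world_self_reference():
    a = random_adjacency(12, 0.4, np.random.default_rng(0))
    gamma, lam, sigma = gm.small_world_indices(a, [a])
    assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)


# ------------------------------------------------------------------- AUC


def test_curve_auc_constant_and_identity():
    grid = np.round(np.arange(5, 41) / 100, 10)
    c = gm.MetricCurve("m", grid, np.full(36, 2.0))
    assert c.auc == pytest.approx(0.35 * 2.0, abs=1e-12)
    ident = gm.MetricCurve("m", grid, grid)
    assert ident.auc == pytest.approx((0.40**2 - 0.05**2) / 2, abs=1e-12)


def test_curve_auc_matches_riemann_refinement(rng):
    grid = np.sort(rng.uniform(0.05, 0.4, 12))
    grid[0], grid[-1] = 0.05, 0.40
    vals = rng.normal(size=12)
    curve = gm.MetricCurve("m", grid, vals)
    # trapezoid rule is exact for the piecewise-linear interpolant
    fine = np.linspace(0.05, 0.40, 200001)
    interp = np.interp(fine, grid, vals)
    riemann = np.sum((interp[1:] + interp[:-1]) / 2 * np.diff(fine))
    assert curve.auc == pytest.approx(riemann, abs=1e-7)


def test_curve_auc_errors():
    with pytest.raises(ValueError):
        gm.MetricCurve("m", np.array([0.1, 0.2]), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        gm.curve_auc_arrays(np.array([0.2, 0.1]), np.array([1.0, 2.0]))


# -------------------------------------------------------------- properties


def test_metrics_invariant_under_relabeling(rng):
    a = random_adjacency(12, 0.3, rng)
    perm = np.random.default_rng(1).permutation(12)
    b = a[np.ix_(perm, perm)]
    for f in (gm.clustering_coefficient, gm.global_efficiency, gm.local_efficiency,
              gm.characteristic_path_length):
        assert f(a) == pytest.approx(f(b), abs=1e-12)


def test_eglob_at_least_inverse_lp_on_connected(rng):
    # Jensen: mean(1/d) >= 1/mean(d) for connected graphs
    for seed in range(5):
        g = nx.gnp_random_graph(15, 0.4, seed=seed)
        if not nx.is_connected(g):
            continue
        a = nx.to_numpy_array(g)
        assert gm.global_efficiency(a) >= 1.0 / gm.characteristic_path_length(a) - 1e-12


def test_edge_addition_monotone(rng):
    a = random_adjacency(12, 0.3, rng)
    zero = np.argwhere(np.triu(a == 0, k=1))
    zero = zero[~(zero[:, 0] == zero[:, 1])]
    i, j = zero[len(zero) // 2]
    b = a.copy()
    b[i, j] = b[j, i] = 1
    assert gm.global_efficiency(b) >= gm.global_efficiency(a) - 1e-12
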
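"""Topological properties of binary undirected graphs.

Global metrics (clustering coefficient Cp, characteristic path length Lp,
global and local efficiency), normalized small-world indices (gamma, lambda,
sigma) against degree-preserving random references, nodal profiles, and
trapezoidal AUC summaries over a density grid.

All functions accept a dense square ``numpy`` adjacency matrix (symmetric,
zero diagonal, entries 0/1).  Conventions for disconnected graphs:

* Lp is averaged over pairs in the largest connected component only.
* Efficiencies count disconnected pairs as zero contribution.

These are the standard conventions of the connectomics literature and matter
here because low-density thresholded networks (e.g. density 0.05 on 68 nodes)
are frequently disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "GraphMetrics",
    "MetricCurve",
    "NodalProfile",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "random_reference",
    "small_world_indices",
    "nodal_profile",
    "curve_auc",
    "compute_global_metrics",
    "GLOBAL_METRICS",
]

#: The seven global metrics reported for each density-thresholded network.
GLOBAL_METRICS: tuple[str, ...] = (
    "sigma",
    "gamma",
    "lambda",
    "Cp",
    "E_global",
    "E_local",
    "Lp",
)


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given graph (e.g. Lp of an edgeless graph)."""


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    return (adj != 0).astype(np.float64)


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix (np.inf for disconnected pairs)."""
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean Watts–Strogatz clustering coefficient.

    Per node: closed triangles / possible triangles among neighbors; nodes of
    degree < 2 contribute 0.  Averaged over all nodes.
    """
    a = _check_adjacency(adj)
    deg = a.sum(axis=1)
    # triangles through node i = (A^3)_ii / 2 = sum_j (A^2 * A)_ij / 2
    a2 = a @ a
    tri = (a2 * a).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path length over ordered pairs in the largest component."""
    a = _check_adjacency(adj)
    if a.sum() == 0:
        raise UndefinedMetricError("characteristic path length undefined for edgeless graph")
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == sizes.argmax()
        a = a[np.ix_(keep, keep)]
    d = _pairwise_distances(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(d[off].mean())


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over all node pairs (0 if disconnected)."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = _pairwise_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbor-induced subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("local efficiency requires at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def _edges_of(adj: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(np.triu(adj, k=1))
    return list(zip(rows.tolist(), cols.tolist()))


def random_reference(
    adj: np.ndarray,
    n_graphs: int = 100,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> list[np.ndarray]:
    """Ensemble of degree-preserving randomized references.

    Each reference is produced by double-edge swaps (at least
    ``swaps_per_edge * |E|`` successful swaps), which preserves the degree
    sequence exactly.  If the graph is too sparse to rewire (fewer than 2
    edges, or swaps repeatedly fail), falls back to Erdős–Rényi graphs with
    matched node and edge counts; the fallback is recorded on the returned
    list as the attribute-free convention of returning ER graphs (callers that
    care can compare degree sequences).
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    edges = _edges_of(a)
    m = len(edges)
    if m < 2:
        raise ValueError("random_reference requires at least 2 edges")
    rng = np.random.default_rng(seed)
    target = swaps_per_edge * m
    out: list[np.ndarray] = []
    for _ in range(n_graphs):
        rewired = _double_edge_swap(edges, n, target, rng)
        if rewired is None:  # too sparse / stuck: matched Erdős–Rényi fallback
            rewired = _gnm_graph(n, m, rng)
        out.append(rewired)
    return out


def _double_edge_swap(
    edges: list[tuple[int, int]], n: int, n_swaps: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Rewire by double-edge swaps; None if the swap chain stalls."""
    m = len(edges)
    edge_list = list(edges)
    edge_set = set(edges)
    max_tries = 100 * n_swaps
    swaps = tries = 0
    chunk = 4096
    buf_idx = rng.integers(0, m, size=(chunk, 2))
    buf_flip = rng.random(chunk)
    ptr = 0
    while swaps < n_swaps and tries < max_tries:
        if ptr >= chunk:
            buf_idx = rng.integers(0, m, size=(chunk, 2))
            buf_flip = rng.random(chunk)
            ptr = 0
        i, j = buf_idx[ptr]
        flip = buf_flip[ptr] < 0.5
        ptr += 1
        tries += 1
        if i == j:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if flip:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove(edge_list[i])
        edge_set.remove(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
        swaps += 1
    if swaps < n_swaps:
        return None
    adj = np.zeros((n, n))
    idx = np.array(edge_list)
    adj[idx[:, 0], idx[:, 1]] = 1.0
    adj[idx[:, 1], idx[:, 0]] = 1.0
    return adj


def _gnm_graph(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random simple graph with n nodes and m edges."""
    iu = np.triu_indices(n, k=1)
    pick = rng.choice(iu[0].size, size=m, replace=False)
    adj = np.zeros((n, n))
    adj[iu[0][pick], iu[1][pick]] = 1.0
    return adj + adj.T


def small_world_indices(
    adj: np.ndarray, ensemble: list[np.ndarray]
) -> tuple[float, float, float]:
    """Normalized small-world indices against a reference ensemble.

    gamma = Cp / mean(Cp_rand); lambda = Lp / mean(Lp_rand); sigma = gamma/lambda.
    """
    if not ensemble:
        raise ValueError("reference ensemble is empty")
    cp = clustering_coefficient(adj)
    lp = characteristic_path_length(adj)
    cp_rand = float(np.mean([clustering_coefficient(g) for g in ensemble]))
    lp_rand = float(np.mean([characteristic_path_length(g) for g in ensemble]))
    if cp_rand == 0 or lp_rand == 0:
        raise UndefinedMetricError("zero reference mean; indices undefined")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


@dataclass
class GraphMetrics:
    """The seven global metrics of one density-thresholded network."""

    density: float
    Cp: float
    Lp: float
    E_global: float
    E_local: float
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "density": self.density,
            "Cp": self.Cp,
            "Lp": self.Lp,
            "E_global": self.E_global,
            "E_local": self.E_local,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass
class NodalProfile:
    """Per-node topological characteristics."""

    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    labels: list[str] | None = None


@dataclass
class MetricCurve:
    """A global metric evaluated along the density grid, with its AUC."""

    metric: str
    densities: np.ndarray
    values: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.densities.shape != self.values.shape:
            raise ValueError(
                f"grid/value length mismatch: {self.densities.shape} vs {self.values.shape}"
            )
        self.auc = curve_auc_arrays(self.densities, self.values)


def curve_auc_arrays(densities: np.ndarray, values: np.ndarray) -> float:
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.ndim != 1 or densities.size < 2:
        raise ValueError("density grid must be 1-D with at least 2 points")
    if np.any(np.diff(densities) <= 0):
        raise ValueError("density grid must be strictly increasing")
    if densities.shape != values.shape:
        raise ValueError("grid/value length mismatch")
    return float(np.trapezoid(values, densities))


def curve_auc(curve: MetricCurve) -> float:
    """Trapezoidal area of a metric-vs-density curve."""
    return curve_auc_arrays(curve.densities, curve.values)


def nodal_profile(adj: np.ndarray, labels: list[str] | None = None) -> NodalProfile:
    """Per-node degree, nodal efficiency and normalized betweenness centrality."""
    import networkx as nx

    a = _check_adjacency(adj)
    n = a.shape[0]
    deg = a.sum(axis=1)
    d = _pairwise_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    nodal_eff = inv.sum(axis=1) / max(n - 1, 1)
    g = nx.from_numpy_array(a)
    btw = np.array([nx.betweenness_centrality(g, normalized=True)[i] for i in range(n)])
    return NodalProfile(degree=deg, nodal_efficiency=nodal_eff, betweenness=btw, labels=labels)


def compute_global_metrics(
    adj: np.ndarray,
    density: float,
    ensemble: list[np.ndarray] | None = None,
) -> GraphMetrics:
    """All seven global metrics of one graph; small-world indices if an ensemble is given."""
    gm = GraphMetrics(
        density=density,
        Cp=clustering_coefficient(adj),
        Lp=characteristic_path_length(adj),
        E_global=global_efficiency(adj),
        E_local=local_efficiency(adj),
    )
    if ensemble is not None:
        gm.gamma, gm.lambda_, gm.sigma = small_world_indices(adj, ensemble)
    return gm
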
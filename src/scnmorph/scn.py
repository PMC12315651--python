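"""Group-level structural covariance network construction.

A structural covariance network (SCN) is a group-level graph whose edge
weights are inter-regional partial correlations of mean cortical thickness
across subjects.  The pipeline here is: residualize each ROI's thickness on
the nuisance covariates (OLS), correlate the residual columns pairwise
(equivalent to partial correlation given those covariates), map weights to
positive values, and binarize by retaining the strongest connections at each
target density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovarianceNetwork",
    "GraphSet",
    "density_grid",
    "residualize",
    "partial_correlation_matrix",
    "to_positive",
    "threshold_by_density",
    "build_graph_set",
]


class SingularDesignError(ValueError):
    """Covariate design matrix is rank deficient."""


class DegenerateGraphWarning(UserWarning):
    """Requested density produces an edgeless graph."""


@dataclass
class CovarianceNetwork:
    """Symmetric ROI-by-ROI partial-correlation matrix for one group."""

    group: str
    roi_labels: list[str]
    weights: np.ndarray
    n_subjects: int
    transform: str = "none"  # provenance of the positive-value transform

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.roi_labels):
            raise ValueError("weights shape does not match roi_labels")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        self.weights = w

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)


@dataclass
class GraphSet:
    """Binary adjacency matrices of one network across the density grid."""

    group: str
    roi_labels: list[str]
    densities: np.ndarray
    adjacencies: list[np.ndarray]
    transform: str = "abs"

    def __post_init__(self) -> None:
        if len(self.adjacencies) != len(self.densities):
            raise ValueError("one adjacency per density required")


def density_grid(
    low: float = 0.05, high: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """Density grid inclusive of both endpoints (default 0.05..0.40, 36 levels)."""
    n = int(round((high - low) / step)) + 1
    return np.round(low + step * np.arange(n), 10)


def residualize(thickness: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each ROI column by its OLS residual on intercept + covariates.

    With no covariates the columns are simply mean-centered.  Raises
    :class:`SingularDesignError` on a rank-deficient design (after dropping
    all-constant covariate columns, which carry no information beyond the
    intercept).
    """
    y = np.asarray(thickness, dtype=float)
    if y.ndim != 2:
        raise ValueError("thickness must be a subjects x ROIs matrix")
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates and thickness disagree on subject count")
        keep = c.std(axis=0) > 0  # constant columns are absorbed by the intercept
        x = np.column_stack([np.ones(n), c[:, keep]])
    if n <= x.shape[1]:
        raise ValueError(
            f"need more subjects ({n}) than design columns ({x.shape[1]})"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("covariate design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation_matrix(
    residualized: np.ndarray,
    roi_labels: list[str] | None = None,
    group: str = "",
) -> CovarianceNetwork:
    """Pairwise Pearson correlation of residualized ROI columns.

    On covariate-residualized data this equals the partial correlation of the
    raw columns given those covariates.
    """
    r = np.asarray(residualized, dtype=float)
    if r.shape[0] < 4:
        raise ValueError("at least 4 subjects required")
    sd = r.std(axis=0)
    if np.any(sd == 0):
        labels = roi_labels or [f"roi{i}" for i in range(r.shape[1])]
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant ROI column(s), correlation undefined: {bad}")
    w = np.corrcoef(r, rowvar=False)
    if roi_labels is None:
        roi_labels = [f"roi{i}" for i in range(r.shape[1])]
    return CovarianceNetwork(
        group=group, roi_labels=list(roi_labels), weights=w, n_subjects=r.shape[0]
    )


def to_positive(network: CovarianceNetwork, mode: str = "abs") -> CovarianceNetwork:
    """Map partial-correlation weights to positive values.

    ``abs`` (default) takes absolute values; ``shift`` subtracts the minimum
    off-diagonal weight, mapping it to 0 while preserving the weight ordering.
    """
    w = network.weights.copy()
    off = ~np.eye(w.shape[0], dtype=bool)
    if mode == "abs":
        w[off] = np.abs(w[off])
    elif mode == "shift":
        w[off] = w[off] - w[off].min()
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return CovarianceNetwork(
        group=network.group,
        roi_labels=network.roi_labels,
        weights=w,
        n_subjects=network.n_subjects,
        transform=mode,
    )


def _ranked_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by decreasing weight, ties by (row, col)."""
    n = weights.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    w = weights[rows, cols]
    # lexsort: last key is primary → sort by -w, then row, then col
    order = np.lexsort((cols, rows, -w))
    return rows[order], cols[order]


def threshold_by_density(
    network: CovarianceNetwork | np.ndarray, density: float
) -> np.ndarray:
    """Binary adjacency keeping the K = round(density·N(N−1)/2) strongest edges.

    Cutoff ties are broken by lexicographic (row, column) order so the result
    is deterministic and edge sets are nested across increasing densities.
    """
    w = network.weights if isinstance(network, CovarianceNetwork) else np.asarray(network)
    n = w.shape[0]
    if not 0 < density < 1:
        raise ValueError(f"density must be in (0, 1), got {density}")
    max_edges = n * (n - 1) // 2
    k = int(round(density * max_edges))
    if k > max_edges:
        raise ValueError(f"density {density} exceeds complete graph")
    if k == 0:
        import warnings

        warnings.warn(
            f"density {density} keeps zero edges on {n} nodes", DegenerateGraphWarning
        )
    rows, cols = _ranked_edges(w)
    adj = np.zeros((n, n))
    adj[rows[:k], cols[:k]] = 1.0
    return adj + adj.T


def build_graph_set(
    network: CovarianceNetwork,
    densities: np.ndarray | None = None,
    transform: str = "abs",
) -> GraphSet:
    """Positive transform + thresholding across the whole density grid."""
    if densities is None:
        densities = density_grid()
    pos = to_positive(network, mode=transform)
    adjs = [threshold_by_density(pos, float(d)) for d in densities]
    return GraphSet(
        group=network.group,
        roi_labels=network.roi_labels,
        densities=np.asarray(densities, dtype=float),
        adjacencies=adjs,
        transform=transform,
    )
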
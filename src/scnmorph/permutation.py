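"""Group-level metric curves and permutation/AUC inference.

Because each group yields a single covariance network (and hence a single
metric value per density), between-group differences cannot be tested with
subject-level statistics.  Inference is by permutation: subjects are shuffled
between groups (preserving group sizes), the entire network pipeline —
within-group residualization, partial correlation, positive transform,
density thresholding, metric computation, AUC — is recomputed per shuffle,
and the observed AUC difference is referred to the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas, metrics as gm
from .scn import density_grid, residualize
from .synthetic import COVARIATE_COLUMNS

__all__ = ["GroupCurves", "PermutationResult", "group_metric_curves", "permutation_test"]

#: Metrics that require a random-reference ensemble per graph.
_NORMALIZED = {"sigma", "gamma", "lambda"}


@dataclass
class GroupCurves:
    """Per-group metric curves over the density grid."""

    densities: np.ndarray
    curves: dict[str, dict[str, gm.MetricCurve]]  # group -> metric -> curve

    def auc(self, group: str, metric: str) -> float:
        return self.curves[group][metric].auc


@dataclass
class PermutationResult:
    metric: str
    observed_auc_diff: float  # group A minus group B
    null_diffs: np.ndarray
    p_two_sided: float
    ci_low: float
    ci_high: float
    densities: np.ndarray
    observed_density_diffs: np.ndarray
    pointwise_p: np.ndarray
    n_perm: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_perm = len(self.null_diffs)


def _metric_values(
    thickness: np.ndarray,
    covariates: np.ndarray,
    mask: np.ndarray,
    densities: np.ndarray,
    metric_names: tuple[str, ...],
    n_random: int,
    rng: np.random.Generator,
    transform: str = "abs",
) -> dict[str, np.ndarray]:
    """Metric-vs-density values for one group defined by a boolean mask.

    Fast path shared by observed and permuted pipelines: residualize within
    the group, correlate, rank |weights| once, then threshold incrementally
    along the (nested) density grid.  The ``shift`` transform yields the same
    ranking as raw weights; ``abs`` ranks by magnitude.
    """
    r = residualize(thickness[mask], covariates[mask])
    w = np.corrcoef(r, rowvar=False)
    n = w.shape[0]
    rows_all, cols_all = np.triu_indices(n, k=1)
    if transform == "abs":
        key = np.abs(w[rows_all, cols_all])
    elif transform == "shift":
        key = w[rows_all, cols_all]  # shifting preserves the ordering
    else:
        raise ValueError(f"unknown transform {transform!r}")
    order = np.lexsort((cols_all, rows_all, -key))
    rows, cols = rows_all[order], cols_all[order]
    max_edges = n * (n - 1) // 2
    out: dict[str, list[float]] = {m: [] for m in metric_names}
    need_norm = bool(_NORMALIZED & set(metric_names))
    for d in densities:
        k = int(round(float(d) * max_edges))
        adj = np.zeros((n, n))
        adj[rows[:k], cols[:k]] = 1.0
        adj += adj.T
        vals: dict[str, float] = {}
        try:
            if "Cp" in metric_names or need_norm:
                vals["Cp"] = gm.clustering_coefficient(adj)
            if "Lp" in metric_names or need_norm:
                vals["Lp"] = gm.characteristic_path_length(adj)
            if "E_global" in metric_names:
                vals["E_global"] = gm.global_efficiency(adj)
            if "E_local" in metric_names:
                vals["E_local"] = gm.local_efficiency(adj)
            if need_norm:
                ensemble = gm.random_reference(adj, n_graphs=n_random, seed=rng)
                gamma, lam, sigma = gm.small_world_indices(adj, ensemble)
                vals.update({"gamma": gamma, "lambda": lam, "sigma": sigma})
        except (gm.UndefinedMetricError, ValueError):
            for m in metric_names:
                out[m].append(np.nan)
            continue
        for m in metric_names:
            out[m].append(vals[m])
    return {m: np.asarray(v) for m, v in out.items()}


def _extract_arrays(
    cohort: pd.DataFrame, covariate_cols: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    thick_cols = [c for c in atlas.THICKNESS_COLUMNS if c in cohort.columns]
    if len(thick_cols) < 4:
        raise ValueError("cohort has too few recognized thickness columns")
    thickness = cohort[thick_cols].to_numpy(dtype=float)
    covariates = cohort[list(covariate_cols)].to_numpy(dtype=float)
    labels = (cohort["group"] == "B").to_numpy()
    return thickness, covariates, labels


def group_metric_curves(
    cohort: pd.DataFrame,
    metric_names: tuple[str, ...] = gm.GLOBAL_METRICS,
    covariate_cols: tuple[str, ...] = COVARIATE_COLUMNS,
    densities: np.ndarray | None = None,
    n_random: int = 100,
    seed: int | np.random.Generator | None = None,
    transform: str = "abs",
) -> GroupCurves:
    """Build both group networks and evaluate metric curves with AUCs.

    Residualization is performed within each group separately, then each
    group's partial-correlation network is transformed, thresholded across
    the density grid, and summarized by each requested metric.
    """
    if densities is None:
        densities = density_grid()
    thickness, covariates, is_b = _extract_arrays(cohort, covariate_cols)
    n_cov = covariates.shape[1]
    for name, mask in (("A", ~is_b), ("B", is_b)):
        if mask.sum() < n_cov + 2:
            raise ValueError(f"group {name} too small to residualize ({mask.sum()} subjects)")
    rng = np.random.default_rng(seed)
    curves: dict[str, dict[str, gm.MetricCurve]] = {}
    for name, mask in (("A", ~is_b), ("B", is_b)):
        vals = _metric_values(
            thickness, covariates, mask, densities, metric_names, n_random, rng, transform
        )
        curves[name] = {
            m: gm.MetricCurve(metric=m, densities=densities, values=v)
            for m, v in vals.items()
        }
    return GroupCurves(densities=np.asarray(densities, dtype=float), curves=curves)


def permutation_test(
    cohort: pd.DataFrame,
    metric: str = "sigma",
    n_perm: int = 1000,
    seed: int | None = None,
    covariate_cols: tuple[str, ...] = COVARIATE_COLUMNS,
    densities: np.ndarray | None = None,
    n_random: int = 100,
    transform: str = "abs",
) -> PermutationResult:
    """Two-sided permutation test of the between-group AUC difference.

    Subjects are shuffled between groups ``n_perm`` times (group sizes
    preserved); the full pipeline including within-group residualization is
    recomputed per permutation.  The p-value uses the add-one estimator
    ``(1 + #{|null| ≥ |observed|}) / (n_perm + 1)``, which never returns 0.
    Densities where the metric is undefined for any rebuilt network are
    dropped from the AUC consistently for observed and null pipelines.
    """
    if metric not in gm.GLOBAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {gm.GLOBAL_METRICS}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if densities is None:
        densities = density_grid()
    densities = np.asarray(densities, dtype=float)
    thickness, covariates, is_b = _extract_arrays(cohort, covariate_cols)
    rng = np.random.default_rng(seed)
    names = (metric,)

    def diff_for(labels_b: np.ndarray) -> np.ndarray:
        va = _metric_values(
            thickness, covariates, ~labels_b, densities, names, n_random, rng, transform
        )[metric]
        vb = _metric_values(
            thickness, covariates, labels_b, densities, names, n_random, rng, transform
        )[metric]
        return va - vb

    all_diffs = np.empty((n_perm + 1, len(densities)))
    all_diffs[0] = diff_for(is_b)
    n = len(is_b)
    n_b = int(is_b.sum())
    for i in range(n_perm):
        perm = rng.permutation(n)
        labels = np.zeros(n, dtype=bool)
        labels[perm[:n_b]] = True
        all_diffs[i + 1] = diff_for(labels)

    valid = np.all(np.isfinite(all_diffs), axis=0)
    if not valid.all():
        dropped = densities[~valid]
        warnings.warn(f"metric {metric!r} undefined at densities {dropped}; dropped from AUC")
    if valid.sum() < 2:
        raise RuntimeError(f"metric {metric!r} defined at fewer than 2 densities")
    grid = densities[valid]
    aucs = np.trapezoid(all_diffs[:, valid], grid, axis=1)
    observed, null = float(aucs[0]), aucs[1:]
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)

    obs_d = all_diffs[0]
    pw = np.full(len(densities), np.nan)
    pw[valid] = (
        1.0 + (np.abs(all_diffs[1:, valid]) >= np.abs(obs_d[valid])[None, :]).sum(axis=0)
    ) / (n_perm + 1.0)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        metric=metric,
        observed_auc_diff=observed,
        null_diffs=null,
        p_two_sided=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        densities=densities,
        observed_density_diffs=obs_d,
        pointwise_p=pw,
    )
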
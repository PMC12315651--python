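"""Simple and serial (two-mediator chain) mediation with bootstrap CIs.

Path models are estimated by OLS with an identical covariate set in every
regression, so the effect decomposition c = c′ + Σ(indirect effects) holds
exactly.  Confidence intervals come from a percentile bootstrap over subject
resampling (bias-corrected variant available); the proportion mediated is
reported as a signed percentage and may be negative or exceed 100% under
suppression.

Simple model:  X → M → Y.   Paths: a (X→M), b (M→Y|X), c′ (X→Y|M),
c (total X→Y); indirect = a·b.

Serial model:  X → M1 → M2 → Y.   Paths: a1 (X→M1), a2 (X→M2|M1),
d21 (M1→M2|X), b1 (M1→Y|X,M2), b2 (M2→Y|X,M1), c′, c; specific indirect
effects a1·b1, a2·b2 and the chained a1·d21·b2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MediationResult", "mediate_simple", "mediate_serial"]


@dataclass
class MediationResult:
    kind: str  # "simple" | "serial"
    paths: dict[str, float]
    indirect: dict[str, float]
    ci: dict[str, tuple[float, float]]  # percentile bootstrap per effect
    proportion_mediated: dict[str, float]  # indirect / total, signed fraction
    n_boot: int
    seed: int | None
    n: int = 0
    boot_estimates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def total_effect(self) -> float:
        return self.paths["c"]


def _fit(y: np.ndarray, *predictors: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS coefficients of y on intercept + predictors + covariates.

    Returns the coefficients of the listed predictors only, in order.
    """
    n = y.shape[0]
    x = np.column_stack([np.ones(n), *predictors, covariates]) if covariates.size else (
        np.column_stack([np.ones(n), *predictors])
    )
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design in mediation path regression")
    return beta[1 : 1 + len(predictors)]


def _prepare(vectors: list[np.ndarray], covariates, min_n: int) -> np.ndarray:
    n = vectors[0].shape[0]
    for v in vectors:
        if v.shape[0] != n:
            raise ValueError("all variables must have equal length")
    if covariates is None or np.size(covariates) == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if n <= cov.shape[1] + min_n:
        raise ValueError(f"too few complete cases: n={n}, covariates={cov.shape[1]}")
    stacked = np.column_stack(vectors + [cov] if cov.size else vectors)
    if not np.all(np.isfinite(stacked)):
        raise ValueError("mediation requires complete (finite) cases")
    if cov.size:
        # standardize covariate columns internally: OLS path coefficients are
        # exactly invariant to affine recoding of covariates, and raw scales
        # (e.g. eTIV in mm^3) would otherwise ruin the design conditioning
        sd = cov.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        cov = (cov - cov.mean(axis=0)) / sd
    return cov


def _simple_paths(x, m, y, cov) -> dict[str, float]:
    a = _fit(m, x, covariates=cov)[0]
    cprime, b = _fit(y, x, m, covariates=cov)
    c = _fit(y, x, covariates=cov)[0]
    return {"a": float(a), "b": float(b), "c_prime": float(cprime), "c": float(c)}


def _serial_paths(x, m1, m2, y, cov) -> dict[str, float]:
    a1 = _fit(m1, x, covariates=cov)[0]
    a2, d21 = _fit(m2, x, m1, covariates=cov)
    cprime, b1, b2 = _fit(y, x, m1, m2, covariates=cov)
    c = _fit(y, x, covariates=cov)[0]
    return {
        "a1": float(a1),
        "a2": float(a2),
        "d21": float(d21),
        "b1": float(b1),
        "b2": float(b2),
        "c_prime": float(cprime),
        "c": float(c),
    }


def _simple_indirect(p: dict[str, float]) -> dict[str, float]:
    return {"a*b": p["a"] * p["b"]}


def _serial_indirect(p: dict[str, float]) -> dict[str, float]:
    eff = {
        "a1*b1": p["a1"] * p["b1"],
        "a2*b2": p["a2"] * p["b2"],
        "a1*d21*b2": p["a1"] * p["d21"] * p["b2"],
    }
    eff["total_indirect"] = sum(eff.values())
    return eff


def _bootstrap(
    vectors: list[np.ndarray],
    cov: np.ndarray,
    path_fn,
    indirect_fn,
    n_boot: int,
    rng: np.random.Generator,
    track: tuple[str, ...],
) -> dict[str, np.ndarray]:
    n = vectors[0].shape[0]
    out = {k: np.empty(n_boot) for k in track}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        vs = [v[idx] for v in vectors]
        cv = cov[idx] if cov.size else cov
        try:
            p = path_fn(*vs, cv)
        except np.linalg.LinAlgError:  # degenerate resample: redraw
            p = path_fn(*[v[rng.integers(0, n, n)] for v in vectors], cv)
        eff = {**p, **indirect_fn(p)}
        for k in track:
            out[k][i] = eff[k]
    return out


def _percentile_ci(boot: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in boot.items()
    }


def _bc_ci(
    boot: dict[str, np.ndarray], estimates: dict[str, float]
) -> dict[str, tuple[float, float]]:
    """Bias-corrected (BC, no acceleration) bootstrap interval."""
    from scipy.stats import norm

    out = {}
    for k, v in boot.items():
        frac = np.clip(np.mean(v < estimates[k]), 1e-6, 1 - 1e-6)
        z0 = norm.ppf(frac)
        lo, hi = norm.cdf(2 * z0 + norm.ppf(0.025)), norm.cdf(2 * z0 + norm.ppf(0.975))
        out[k] = (float(np.percentile(v, 100 * lo)), float(np.percentile(v, 100 * hi)))
    return out


def _finish(
    kind: str,
    paths: dict[str, float],
    indirect: dict[str, float],
    boot: dict[str, np.ndarray],
    n_boot: int,
    seed: int | None,
    n: int,
    ci_method: str = "percentile",
) -> MediationResult:
    c = paths["c"]
    prop = {k: (v / c if c != 0 else np.nan) for k, v in indirect.items()}
    if ci_method == "percentile":
        ci = _percentile_ci(boot)
    elif ci_method == "bc":
        ci = _bc_ci(boot, {**paths, **indirect})
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MediationResult(
        kind=kind,
        paths=paths,
        indirect=indirect,
        ci=ci,
        proportion_mediated=prop,
        n_boot=n_boot,
        seed=seed,
        n=n,
        boot_estimates=boot,
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def mediate_simple(
    x, m, y, covariates=None, n_boot: int = 5000, seed: int | None = None,
    standardize: bool = False,
    ci_method: str = "percentile",
) -> MediationResult:
    """Single-mediator model with percentile-bootstrap CIs.

    Three OLS fits (M~X+C, Y~X+M+C, Y~X+C) give a, b, c′ and the total
    effect c; the indirect effect is a·b and c = c′ + a·b exactly.
    Variables are carried on their raw scales unless ``standardize`` z-scores
    x, m and y first.
    """
    xv, mv, yv = (np.asarray(v, dtype=float) for v in (x, m, y))
    if standardize:
        xv, mv, yv = _zscore(xv), _zscore(mv), _zscore(yv)
    cov = _prepare([xv, mv, yv], covariates, min_n=4)
    paths = _simple_paths(xv, mv, yv, cov)
    indirect = _simple_indirect(paths)
    rng = np.random.default_rng(seed)
    track = ("a", "b", "c_prime", "c", "a*b")
    boot = _bootstrap(
        [xv, mv, yv], cov, _simple_paths, _simple_indirect, n_boot, rng, track
    )
    return _finish("simple", paths, indirect, boot, n_boot, seed, len(xv), ci_method)


def mediate_serial(
    x, m1, m2, y, covariates=None, n_boot: int = 5000, seed: int | None = None,
    standardize: bool = False,
    ci_method: str = "percentile",
) -> MediationResult:
    """Serial two-mediator chain model with percentile-bootstrap CIs.

    Four OLS fits (M1~X+C, M2~X+M1+C, Y~X+M1+M2+C, Y~X+C); the specific
    indirect effects are a1·b1, a2·b2 and the chained a1·d21·b2, and
    c = c′ + total indirect exactly.
    """
    xv, m1v, m2v, yv = (np.asarray(v, dtype=float) for v in (x, m1, m2, y))
    if standardize:
        xv, m1v, m2v, yv = (_zscore(v) for v in (xv, m1v, m2v, yv))
    cov = _prepare([xv, m1v, m2v, yv], covariates, min_n=4)
    paths = _serial_paths(xv, m1v, m2v, yv, cov)
    indirect = _serial_indirect(paths)
    rng = np.random.default_rng(seed)
    track = (
        "a1", "a2", "d21", "b1", "b2", "c_prime", "c",
        "a1*b1", "a2*b2", "a1*d21*b2", "total_indirect",
    )
    boot = _bootstrap(
        [xv, m1v, m2v, yv], cov, _serial_paths, _serial_indirect, n_boot, rng, track
    )
    return _finish("serial", paths, indirect, boot, n_boot, seed, len(xv), ci_method)
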
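"""Covariate-adjusted ROI-wise group comparison and demographics statistics.

Group differences in mean cortical thickness are tested per ROI by
OLS-ANCOVA: thickness regressed on intercept + group indicator + nuisance
covariates (age, education years, smoking, drinking, eTIV), with the
two-sided t-test on the group coefficient and Bonferroni correction across
the ROI family.  Demographic tables use Shapiro–Wilk-gated t / Mann–Whitney
tests for continuous variables and chi-square tests for categorical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import atlas
from .scn import SingularDesignError
from .synthetic import COVARIATE_COLUMNS

__all__ = [
    "RoiComparisonResult",
    "DemographicsRow",
    "ancova_roi",
    "compare_all_rois",
    "demographics_table",
]


@dataclass
class RoiComparisonResult:
    roi: str
    beta_group: float  # mm, group B minus group A adjusted difference
    t_stat: float
    p_raw: float
    p_adj: float
    n_tests: int


@dataclass
class DemographicsRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str
    statistic: float | None
    p: float | None


def _design(group: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = group.shape[0]
    cols = [np.ones(n), group.astype(float)]
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols.extend(c.T)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify collinear columns by checking rank drop when each is removed
        names = ["intercept", "group"] + [f"covariate_{i}" for i in range(x.shape[1] - 2)]
        full = np.linalg.matrix_rank(x)
        bad = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == full
        ]
        raise SingularDesignError(f"design matrix rank deficient; collinear columns: {bad}")
    return x


def _group_t_stats(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS group-coefficient t-tests for every column of y."""
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > covariates + 2: n={n}, design columns={p}")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    # saturated (zero-residual) fits: the t test is degenerate; report t = 0
    # for a numerically-zero coefficient, +/-inf otherwise
    y_scale = np.sqrt((y**2).mean(axis=0)) + np.finfo(float).tiny
    degenerate = sigma2 <= (1e-12 * y_scale) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate,
                     np.where(np.abs(beta[1]) <= 1e-10 * y_scale, 0.0,
                              np.sign(beta[1]) * np.inf),
                     beta[1] / se)
    return beta[1], t, dof


def ancova_roi(
    thickness: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    roi: str = "",
    n_tests: int = 1,
) -> RoiComparisonResult:
    """OLS-ANCOVA of one ROI's thickness on group + covariates.

    ``group`` is a binary indicator (1 = case).  Returns the adjusted group
    difference, its t statistic with n − p degrees of freedom, the two-sided
    raw p, and the Bonferroni-adjusted p given ``n_tests``.
    """
    y = np.asarray(thickness, dtype=float)[:, None]
    g = np.asarray(group)
    if set(np.unique(g).tolist()) - {0, 1, 0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    if len(np.unique(g)) < 2:
        raise ValueError("both group levels must be present")
    x = _design(g, covariates)
    beta, t, dof = _group_t_stats(x, y)
    p_raw = float(2 * stats.t.sf(abs(t[0]), dof))
    return RoiComparisonResult(
        roi=roi,
        beta_group=float(beta[0]),
        t_stat=float(t[0]),
        p_raw=p_raw,
        p_adj=min(1.0, p_raw * n_tests),
        n_tests=n_tests,
    )


def compare_all_rois(
    cohort: pd.DataFrame,
    covariate_cols: tuple[str, ...] = COVARIATE_COLUMNS,
    roi_labels: tuple[str, ...] | None = None,
) -> list[RoiComparisonResult]:
    """ANCOVA of every ROI, Bonferroni-corrected over the ROI family.

    Results sorted by adjusted p.  The group indicator codes group "B" (cases)
    as 1, so negative ``beta_group`` means thinner cortex in cases.
    """
    if roi_labels is None:
        roi_labels = atlas.DK_ROI_LABELS
    if len(roi_labels) < 2:
        raise ValueError("at least 2 ROIs required")
    missing = [c for c in covariate_cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    thick_cols = [atlas.thickness_column(r) for r in roi_labels]
    missing_rois = [c for c in thick_cols if c not in cohort.columns]
    if missing_rois:
        raise KeyError(f"missing thickness column(s): {missing_rois}")
    g = (cohort["group"] == "B").to_numpy().astype(float)
    x = _design(g, cohort[list(covariate_cols)].to_numpy(dtype=float))
    y = cohort[thick_cols].to_numpy(dtype=float)
    beta, t, dof = _group_t_stats(x, y)
    p_raw = 2 * stats.t.sf(np.abs(t), dof)
    n_tests = len(roi_labels)
    results = [
        RoiComparisonResult(
            roi=roi,
            beta_group=float(beta[i]),
            t_stat=float(t[i]),
            p_raw=float(p_raw[i]),
            p_adj=float(min(1.0, p_raw[i] * n_tests)),
            n_tests=n_tests,
        )
        for i, roi in enumerate(roi_labels)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw))
    return results


_DEFAULT_CONTINUOUS = (
    "age",
    "education",
    "etiv",
    "bis_ai",
    "bis_mi",
    "bis_npi",
    "bis_total",
    "vas",
)
_DEFAULT_CATEGORICAL = ("smoking", "drinking")


def demographics_table(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] | None = None,
    categorical: tuple[str, ...] | None = None,
    yates_correction: bool = False,
) -> list[DemographicsRow]:
    """Per-variable group comparison in the style of a demographics table.

    Continuous variables: Shapiro–Wilk normality in both groups gates the
    choice between the independent-samples t test and the Mann–Whitney U
    test; summarized as mean ± sd.  Categorical variables: chi-square on the
    2×k contingency table (continuity correction off by default); summarized
    as count (percent).  Constant columns yield a degenerate-test warning and
    a row without a statistic.
    """
    if "group" not in cohort.columns:
        raise KeyError("cohort must have a 'group' column")
    if continuous is None:
        continuous = tuple(c for c in _DEFAULT_CONTINUOUS if c in cohort.columns)
    if categorical is None:
        categorical = tuple(c for c in _DEFAULT_CATEGORICAL if c in cohort.columns)
    a = cohort[cohort["group"] == "A"]
    b = cohort[cohort["group"] == "B"]
    rows: list[DemographicsRow] = []
    for var in continuous:
        xa, xb = a[var].to_numpy(dtype=float), b[var].to_numpy(dtype=float)
        summ_a = f"{xa.mean():.2f} ± {xa.std(ddof=1):.2f}"
        summ_b = f"{xb.mean():.2f} ± {xb.std(ddof=1):.2f}"
        if np.std(xa) == 0 and np.std(xb) == 0:
            warnings.warn(f"variable {var!r} constant in both groups; no test run")
            rows.append(DemographicsRow(var, summ_a, summ_b, "none", None, None))
            continue
        normal = (
            stats.shapiro(xa).pvalue > 0.05 and stats.shapiro(xb).pvalue > 0.05
            if min(len(xa), len(xb)) >= 3
            else False
        )
        if normal:
            res = stats.ttest_ind(xa, xb)
            rows.append(DemographicsRow(var, summ_a, summ_b, "t", float(res.statistic), float(res.pvalue)))
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                DemographicsRow(var, summ_a, summ_b, "Mann-Whitney", float(res.statistic), float(res.pvalue))
            )
    for var in categorical:
        tab = pd.crosstab(cohort["group"], cohort[var])
        counts_a = a[var].value_counts()
        counts_b = b[var].value_counts()
        summ_a = "; ".join(f"{k}: {v} ({100*v/len(a):.0f}%)" for k, v in counts_a.items())
        summ_b = "; ".join(f"{k}: {v} ({100*v/len(b):.0f}%)" for k, v in counts_b.items())
        if tab.shape[1] < 2:
            warnings.warn(f"variable {var!r} constant; chi-square degenerate")
            rows.append(DemographicsRow(var, summ_a, summ_b, "chi-square", None, None))
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=yates_correction)
        rows.append(DemographicsRow(var, summ_a, summ_b, "chi-square", float(chi2), float(p)))
    return rows
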
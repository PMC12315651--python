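"""Behavioral instrument scoring and covariate-adjusted association analyses.

Covers Barratt Impulsiveness Scale (BIS-11) scoring into attentional (AI),
motor (MI) and nonplanning (NPI) subscales, symptom-count severity
classification on the 0-1 / 2-3 / 4-5 / 6+ scheme, visual-analogue craving
validation, and partial correlations between regional thickness, drug-use
parameters and impulsivity with nuisance covariates removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BisScores",
    "SeverityCategory",
    "PartialCorrResult",
    "BIS_SUBSCALE_ITEMS",
    "BIS_REVERSE_ITEMS",
    "score_bis",
    "classify_severity",
    "validate_vas",
    "partial_corr",
    "association_table",
]

# Standard 30-item BIS-11 partition (1-based item numbers).
# AI = attention + cognitive instability (8 items);
# MI = motor + perseverance (11 items);
# NPI = self-control + cognitive complexity (11 items).
BIS_SUBSCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "AI": (5, 6, 9, 11, 20, 24, 26, 28),
    "MI": (2, 3, 4, 16, 17, 19, 21, 22, 23, 25, 30),
    "NPI": (1, 7, 8, 10, 12, 13, 14, 15, 18, 27, 29),
}

# Items reverse-keyed in the standard instrument (optional mode).
BIS_REVERSE_ITEMS: tuple[int, ...] = (1, 7, 8, 9, 10, 12, 13, 15, 20, 29, 30)


@dataclass
class BisScores:
    AI: int
    MI: int
    NPI: int
    total: int


class SeverityCategory(str, Enum):
    NO_PROBLEM = "NoProblem"
    MILD = "Mild"
    MODERATE = "Moderate"
    SEVERE = "Severe"


@dataclass
class PartialCorrResult:
    x: str
    y: str
    r: float
    df: int
    p: float
    covariates: tuple[str, ...] = ()


def score_bis(
    items,
    reverse_score: bool = False,
    subscale_items: dict[str, tuple[int, ...]] | None = None,
) -> BisScores:
    """Score a 30-item BIS-11 response vector into AI/MI/NPI sums and total.

    Items are 1-based in the subscale map and must each be in 1..5.  With
    ``reverse_score`` the standard reverse-keyed items are scored 6 − x
    before summation (off by default).
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (30,):
        raise ValueError(f"expected exactly 30 item responses, got shape {arr.shape}")
    bad = np.flatnonzero(~np.isin(arr, [1, 2, 3, 4, 5]))
    if bad.size:
        raise ValueError(f"item responses out of 1..5 at 1-based positions {(bad + 1).tolist()}")
    scored = arr.copy()
    if reverse_score:
        idx = np.array(BIS_REVERSE_ITEMS) - 1
        scored[idx] = 6 - scored[idx]
    submap = subscale_items or BIS_SUBSCALE_ITEMS
    sums = {name: int(scored[np.array(ix) - 1].sum()) for name, ix in submap.items()}
    return BisScores(AI=sums["AI"], MI=sums["MI"], NPI=sums["NPI"], total=sum(sums.values()))


def classify_severity(symptom_count: int) -> SeverityCategory:
    """Severity category from endorsed symptom count.

    0–1 → NoProblem, 2–3 → Mild, 4–5 → Moderate, ≥6 → Severe.
    """
    if not float(symptom_count).is_integer() or symptom_count < 0:
        raise ValueError(f"symptom count must be a nonnegative integer, got {symptom_count}")
    n = int(symptom_count)
    if n <= 1:
        return SeverityCategory.NO_PROBLEM
    if n <= 3:
        return SeverityCategory.MILD
    if n <= 5:
        return SeverityCategory.MODERATE
    return SeverityCategory.SEVERE


def validate_vas(score: float) -> float:
    """Validate a visual-analogue craving score (0 = none .. 10 = strongest)."""
    s = float(score)
    if not np.isfinite(s) or not 0.0 <= s <= 10.0:
        raise ValueError(f"VAS score must be in [0, 10], got {score}")
    return s


def _residuals(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_corr(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on intercept + covariates by OLS; the
    Pearson correlation of the residuals is tested with
    t = r·sqrt(df / (1 − r²)), df = n − 2 − n_covariates, two-sided.
    With no covariates this is the plain Pearson correlation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = xv.shape[0]
    if yv.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        design = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
    if n <= k + 3:
        raise ValueError(f"need n > n_covariates + 3: n={n}, covariates={k}")
    rx = _residuals(xv, design)
    ry = _residuals(yv, design)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residual vector; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(x=x_name, y=y_name, r=r, df=df, p=p, covariates=covariate_names)


def association_table(
    cohort: pd.DataFrame,
    region_cols: tuple[str, ...],
    variable_cols: tuple[str, ...],
    covariate_cols: tuple[str, ...] = (
        "age",
        "education",
        "smoking",
        "drinking",
        "abstinence_months",
        "etiv",
    ),
    group: str | None = "B",
) -> pd.DataFrame:
    """Partial correlations of each (region, variable) pair with covariates.

    By default restricted to the case group, matching the convention of
    relating regional thickness to drug-use parameters and impulsivity within
    patients.  Emits raw p and Bonferroni-adjusted p across the pair family.
    """
    df = cohort if group is None else cohort[cohort["group"] == group]
    cov = df[list(covariate_cols)].to_numpy(dtype=float)
    rows = []
    n_tests = len(region_cols) * len(variable_cols)
    for rc in region_cols:
        for vc in variable_cols:
            res = partial_corr(
                df[rc], df[vc], cov, x_name=rc, y_name=vc, covariate_names=covariate_cols
            )
            rows.append(
                {
                    "region": rc,
                    "variable": vc,
                    "r": res.r,
                    "df": res.df,
                    "p": res.p,
                    "p_bonferroni": min(1.0, res.p * n_tests),
                }
            )
    return pd.DataFrame(rows)
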
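"""Synthetic cohort generation with planted morphometric and behavioral structure.

Generates subject-level tables with the statistical structure the downstream
analyses assume: two groups (controls "A", cases "B") with covariate
confounding, multivariate-normal ROI thickness whose group-specific
correlation structure follows a small-world (ring-lattice + rewiring)
topology, planted group thickness reductions in chosen ROIs, and a planted
linear chain from target-ROI thickness through motor impulsivity (MI) and
cue-induced craving (VAS) to symptom-count severity.

The generator starts at ROI summaries — no images or surfaces are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import atlas

__all__ = [
    "TopologyParams",
    "CovariateSpec",
    "ChainCoefs",
    "CohortSpec",
    "build_topology_covariance",
    "generate_cohort",
    "write_cohort",
    "COVARIATE_COLUMNS",
    "BEHAVIOR_COLUMNS",
]

#: Nuisance covariates carried by every cohort, in canonical order.
COVARIATE_COLUMNS: tuple[str, ...] = ("age", "education", "smoking", "drinking", "etiv")

BEHAVIOR_COLUMNS: tuple[str, ...] = (
    "bis_ai",
    "bis_mi",
    "bis_npi",
    "bis_total",
    "vas",
    "symptom_count",
    "use_duration_months",
    "abstinence_months",
)


@dataclass(frozen=True)
class TopologyParams:
    """Small-world topology of one group's ROI correlation structure.

    ``k``: even ring-lattice neighbor degree; ``p``: rewiring probability
    (0 = pure lattice, 1 = fully randomized); ``s``: off-diagonal correlation
    strength assigned to each topological edge before the positive-definite
    projection.
    """

    k: int = 12
    p: float = 0.1
    s: float = 0.5

    def validate(self, n_roi: int) -> None:
        if self.k % 2 != 0 or self.k < 2 or self.k >= n_roi:
            raise ValueError(f"k must be even and in [2, n_roi): got k={self.k}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"rewiring probability must be in [0, 1]: got {self.p}")
        if self.s <= 0:
            raise ValueError(f"edge strength must be positive: got {self.s}")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution and thickness effect of one covariate.

    ``dist`` is ``"normal"`` (loc/scale per group) or ``"bernoulli"``
    (success probability per group).  ``coef`` is the linear effect on every
    ROI's thickness in mm per unit of the covariate, applied to the covariate
    centered at ``center`` so that the grand thickness mean stays near the
    cortical baseline.
    """

    name: str
    dist: str
    param_a: float
    param_b: float
    scale: float = 0.0  # sd for normal; unused for bernoulli
    coef: float = 0.0
    center: float = 0.0


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("age", "normal", 33.0, 33.0, scale=7.0, coef=-0.002, center=33.0),
        CovariateSpec("education", "normal", 9.0, 9.0, scale=3.0, coef=0.002, center=9.0),
        CovariateSpec("smoking", "bernoulli", 0.3, 0.9, coef=-0.01, center=0.5),
        CovariateSpec("drinking", "bernoulli", 0.3, 0.7, coef=-0.005, center=0.5),
        CovariateSpec("etiv", "normal", 1.5e6, 1.5e6, scale=1.5e5, coef=5e-8, center=1.5e6),
    )


@dataclass(frozen=True)
class ChainCoefs:
    """Planted thickness → MI → craving → severity chain.

    a1: target-ROI thickness → MI (BIS points per mm); d21: MI → VAS craving;
    b2: VAS → severity; b1: MI → severity (direct of M1); c_prime: direct
    thickness → severity effect.  All on raw scales.
    """

    a1: float = -20.0
    d21: float = 0.4
    b2: float = 0.4
    b1: float = 0.1
    c_prime: float = -2.0


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort.

    Group A is the control group, group B the case (patient) group.  Defaults
    emulate the study conditions: 52 controls vs 103 cases, 68 Desikan–
    Killiany ROIs, thickness reductions of 0.15 mm planted in the left
    fusiform and right pars opercularis of group B, a less regular (more
    rewired) covariance topology in group B, and the behavioral chain rooted
    at the right pars opercularis.
    """

    n_group_a: int = 52
    n_group_b: int = 103
    roi_labels: tuple[str, ...] = atlas.DK_ROI_LABELS
    thinning_effects: dict[str, float] = field(
        default_factory=lambda: {"lh_fusiform": -0.15, "rh_parsopercularis": -0.15}
    )
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    topology_a: TopologyParams = field(default_factory=lambda: TopologyParams(k=12, p=0.1, s=0.5))
    topology_b: TopologyParams = field(default_factory=lambda: TopologyParams(k=12, p=0.8, s=0.5))
    chain_coefs: ChainCoefs = field(default_factory=ChainCoefs)
    chain_target_roi: str = "rh_parsopercularis"
    duration_roi: str = "lh_fusiform"
    duration_effect: float = -60.0  # months of use per mm of duration-ROI thickness
    noise_sd: float = 0.12
    baseline_thickness: float = 2.5
    # behavioral intercepts / residual scales (shared across groups so the
    # planted chain is the only thickness->behavior pathway)
    mi_intercept: float = 20.0
    mi_sd: float = 2.5
    vas_intercept: float = 5.0
    vas_sd: float = 1.0
    severity_intercept: float = 6.0
    severity_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        n_cov = len(self.covariates)
        if self.n_group_a < n_cov + 2 or self.n_group_b < n_cov + 2:
            raise ValueError(
                f"group sizes must be at least {n_cov + 2} (covariates + 2); "
                f"got {self.n_group_a}/{self.n_group_b}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_roi = len(self.roi_labels)
        self.topology_a.validate(n_roi)
        self.topology_b.validate(n_roi)
        for roi in list(self.thinning_effects) + [self.chain_target_roi, self.duration_roi]:
            if roi not in self.roi_labels:
                raise ValueError(f"unknown ROI name: {roi!r}")


def build_topology_covariance(
    topology: TopologyParams,
    n_roi: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Correlation matrix whose strongest entries follow a small-world graph.

    Draws a Watts–Strogatz graph (ring lattice of degree ``k`` rewired with
    probability ``p``), sets ``C = I + s·A`` and projects to the nearest
    positive-definite correlation matrix by eigenvalue clipping at 1e-6
    followed by rescaling to unit diagonal.  The planted edges keep the
    largest off-diagonal magnitudes after projection.
    """
    if n_roi < 4:
        raise ValueError("n_roi must be at least 4")
    topology.validate(n_roi)
    rng = np.random.default_rng(seed)
    g = nx.watts_strogatz_graph(
        n_roi, topology.k, topology.p, seed=int(rng.integers(0, 2**31 - 1))
    )
    a = nx.to_numpy_array(g)
    c = np.eye(n_roi) + topology.s * a
    evals, evecs = np.linalg.eigh(c)
    if evals.min() < 1e-6:
        evals = np.clip(evals, 1e-6, None)
        c = (evecs * evals) @ evecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() <= 0:
        raise RuntimeError("covariance projection failed to produce a PD matrix")
    return c


def _sample_covariates(
    specs: tuple[CovariateSpec, ...], n: int, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for cs in specs:
        p = cs.param_a if group == "A" else cs.param_b
        if cs.dist == "normal":
            cols[cs.name] = rng.normal(p, cs.scale, size=n)
        elif cs.dist == "bernoulli":
            cols[cs.name] = rng.binomial(1, p, size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {cs.dist!r}")
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a subject-level cohort table from a :class:`CohortSpec`.

    Returns a tidy DataFrame: one row per subject with ``subject_id``,
    ``group`` (A=control, B=case), the five covariates, 68 thickness columns
    (``<roi>_thickness``, mm), and the behavioral columns.  Deterministic for
    a fixed ``spec.seed``; the seed fans out into independent substreams for
    topology, covariates, thickness noise and behavior.
    """
    spec.validate()
    n_roi = len(spec.roi_labels)
    ss = np.random.SeedSequence(spec.seed)
    s_topo_a, s_topo_b, s_cov, s_noise, s_behav = ss.spawn(5)

    corr_a = build_topology_covariance(spec.topology_a, n_roi, np.random.default_rng(s_topo_a))
    if spec.topology_a == spec.topology_b:
        # equal-parameter groups are an exact null: share the realized topology
        corr_b = corr_a
    else:
        corr_b = build_topology_covariance(
            spec.topology_b, n_roi, np.random.default_rng(s_topo_b)
        )

    rng_cov = np.random.default_rng(s_cov)
    rng_noise = np.random.default_rng(s_noise)
    rng_behav = np.random.default_rng(s_behav)

    frames = []
    for group, n, corr in (("A", spec.n_group_a, corr_a), ("B", spec.n_group_b, corr_b)):
        cov = _sample_covariates(spec.covariates, n, group, rng_cov)
        mean = np.full(n_roi, spec.baseline_thickness)
        if group == "B":
            for roi, shift in spec.thinning_effects.items():
                mean[spec.roi_labels.index(roi)] += shift
        effect = np.zeros((n, 1))
        for cs in spec.covariates:
            effect = effect + cs.coef * (cov[cs.name].to_numpy()[:, None] - cs.center)
        chol = np.linalg.cholesky(corr)
        noise = rng_noise.standard_normal((n, n_roi)) @ chol.T * spec.noise_sd
        thickness = mean[None, :] + effect + noise
        df = pd.DataFrame(thickness, columns=[atlas.thickness_column(r) for r in spec.roi_labels])
        df.insert(0, "group", group)
        frames.append(pd.concat([df, cov], axis=1))

    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(table))])

    # behavioral chain, shared across groups; planted thinning drives contrasts
    cc = spec.chain_coefs
    th_target = table[atlas.thickness_column(spec.chain_target_roi)].to_numpy()
    th_c = th_target - spec.baseline_thickness
    age_c = table["age"].to_numpy() - 33.0
    n_all = len(table)

    mi = spec.mi_intercept + cc.a1 * th_c - 0.05 * age_c + rng_behav.normal(0, spec.mi_sd, n_all)
    vas = spec.vas_intercept + cc.d21 * (mi - spec.mi_intercept) + rng_behav.normal(
        0, spec.vas_sd, n_all
    )
    vas = np.clip(vas, 0.0, 10.0)
    latent = (
        spec.severity_intercept
        + cc.b2 * (vas - spec.vas_intercept)
        + cc.b1 * (mi - spec.mi_intercept)
        + cc.c_prime * th_c
        + rng_behav.normal(0, spec.severity_sd, n_all)
    )
    symptom_count = np.clip(np.round(latent), 0, 11).astype(int)

    is_b = (table["group"] == "B").to_numpy()
    th_dur = table[atlas.thickness_column(spec.duration_roi)].to_numpy()
    duration = 60.0 + spec.duration_effect * (th_dur - spec.baseline_thickness)
    duration += rng_behav.normal(0, 25.0, n_all)
    duration = np.where(is_b, np.clip(duration, 1.0, None), 0.0)
    abstinence = np.where(
        is_b, np.clip(rng_behav.normal(9.0, 6.0, n_all), 0.5, None), 0.0
    )

    ai = 17.0 + 4.0 * is_b + rng_behav.normal(0, 3.0, n_all)
    npi = 22.0 + 5.0 * is_b + rng_behav.normal(0, 3.5, n_all)

    table["bis_ai"] = ai
    table["bis_mi"] = mi
    table["bis_npi"] = npi
    table["bis_total"] = ai + mi + npi
    table["vas"] = vas
    table["symptom_count"] = symptom_count
    table["use_duration_months"] = duration
    table["abstinence_months"] = abstinence
    return table


def write_cohort(table: pd.DataFrame, path: str | Path, spec: CohortSpec | None = None) -> None:
    """Write a cohort to tidy CSV, with the generating spec as a YAML sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    if spec is not None:
        sidecar = path.with_suffix(".spec.yaml")
        payload = asdict(spec)
        payload["roi_labels"] = list(payload["roi_labels"])
        payload["covariates"] = [asdict(c) if not isinstance(c, dict) else c for c in spec.covariates]
        with open(sidecar, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
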
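"""End-to-end pipeline orchestration: synthesize-or-load → morphometry →
structural covariance networks → permutation inference → associations →
mediation, with seeded determinism and file-based stage outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, behavior, mediation, metrics as gm, morphometry, permutation
from .io import read_cohort_csv, write_network_csv
from .scn import build_graph_set, density_grid, partial_correlation_matrix, residualize
from .synthetic import COVARIATE_COLUMNS, CohortSpec, generate_cohort, write_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "build_group_networks"]

log = logging.getLogger("scnmorph")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str
    input_csv: str | None = None  # if None, a cohort is synthesized
    seed: int = 0
    covariate_cols: tuple[str, ...] = COVARIATE_COLUMNS
    assoc_covariate_cols: tuple[str, ...] = (
        "age", "education", "smoking", "drinking", "abstinence_months", "etiv",
    )
    density_low: float = 0.05
    density_high: float = 0.40
    density_step: float = 0.01
    n_perm: int = 1000
    perm_metric: str = "Cp"
    n_boot: int = 5000
    n_random: int = 100
    transform: str = "abs"
    mediation_x: str = "rh_parsopercularis_thickness"
    mediation_m1: str = "bis_mi"
    mediation_m2: str = "vas"
    mediation_y: str = "symptom_count"

    def validate(self) -> None:
        if not 0 < self.density_low < self.density_high < 1:
            raise ValueError("require 0 < density_low < density_high < 1")
        if self.perm_metric not in gm.GLOBAL_METRICS:
            raise ValueError(f"unknown metric {self.perm_metric!r}")
        if self.transform not in ("abs", "shift"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.n_perm < 100 or self.n_boot < 100 or self.n_random < 1:
            raise ValueError("n_perm/n_boot must be >= 100 and n_random >= 1")

    def densities(self) -> np.ndarray:
        return density_grid(self.density_low, self.density_high, self.density_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("covariate_cols", "assoc_covariate_cols"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["covariate_cols"] = list(self.covariate_cols)
        payload["assoc_covariate_cols"] = list(self.assoc_covariate_cols)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class RunReport:
    config: RunConfig
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {**asdict(self.config)},
            "outputs": self.outputs,
            "warnings": self.warnings,
            "timings_s": self.timings,
        }
        payload["config"]["covariate_cols"] = list(self.config.covariate_cols)
        payload["config"]["assoc_covariate_cols"] = list(self.config.assoc_covariate_cols)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_group_networks(cohort: pd.DataFrame, covariate_cols=COVARIATE_COLUMNS):
    """Per-group residualize → partial-correlation network (groups "A", "B")."""
    thick_cols = list(atlas.THICKNESS_COLUMNS)
    nets = {}
    for group in ("A", "B"):
        sub = cohort[cohort["group"] == group]
        resid = residualize(
            sub[thick_cols].to_numpy(dtype=float),
            sub[list(covariate_cols)].to_numpy(dtype=float),
        )
        nets[group] = partial_correlation_matrix(
            resid, roi_labels=list(atlas.DK_ROI_LABELS), group=group
        )
    return nets


def run_pipeline(config: RunConfig, spec: CohortSpec | None = None) -> RunReport:
    """Execute all stages in order, writing each stage's outputs to disk.

    Deterministic for fixed config seed.  Any stage failure raises with the
    stage name; earlier outputs are left in place for inspection.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    ss = np.random.SeedSequence(config.seed)
    seed_synth, seed_perm, seed_boot, seed_curves = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s started (seed root %d)", name, config.seed)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            report.timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.1fs", name, report.timings[name])
        return wrap

    state: dict = {}

    @stage("cohort")
    def _cohort():
        if config.input_csv is not None:
            state["cohort"] = read_cohort_csv(config.input_csv)
        else:
            cohort_spec = spec if spec is not None else CohortSpec(seed=seed_synth)
            state["cohort"] = generate_cohort(cohort_spec)
            write_cohort(state["cohort"], out / "cohort.csv", cohort_spec)
            report.outputs["cohort"] = str(out / "cohort.csv")

    @stage("morphometry")
    def _morpho():
        results = morphometry.compare_all_rois(state["cohort"], config.covariate_cols)
        df = pd.DataFrame([asdict(r) for r in results])
        df.to_csv(out / "morphometry.csv", index=False)
        report.outputs["morphometry"] = str(out / "morphometry.csv")
        demo = morphometry.demographics_table(state["cohort"])
        pd.DataFrame([asdict(r) for r in demo]).to_csv(out / "demographics.csv", index=False)
        report.outputs["demographics"] = str(out / "demographics.csv")
        state["morphometry"] = results

    @stage("scn")
    def _scn():
        nets = build_group_networks(state["cohort"], config.covariate_cols)
        for group, net in nets.items():
            p = out / f"network_{group}.csv"
            write_network_csv(net.weights, net.roi_labels, p)
            report.outputs[f"network_{group}"] = str(p)
            build_graph_set(net, config.densities(), config.transform)  # validates grid
        state["networks"] = nets

    @stage("curves")
    def _curves():
        curves = permutation.group_metric_curves(
            state["cohort"],
            covariate_cols=config.covariate_cols,
            densities=config.densities(),
            n_random=config.n_random,
            seed=seed_curves,
            transform=config.transform,
        )
        rows = []
        for group, by_metric in curves.curves.items():
            for m, curve in by_metric.items():
                for d, v in zip(curve.densities, curve.values):
                    rows.append({"group": group, "metric": m, "density": d, "value": v,
                                 "auc": curve.auc})
        pd.DataFrame(rows).to_csv(out / "metric_curves.csv", index=False)
        report.outputs["metric_curves"] = str(out / "metric_curves.csv")
        state["curves"] = curves

    @stage("permutation")
    def _perm():
        res = permutation.permutation_test(
            state["cohort"],
            metric=config.perm_metric,
            n_perm=config.n_perm,
            seed=seed_perm,
            covariate_cols=config.covariate_cols,
            densities=config.densities(),
            n_random=config.n_random,
            transform=config.transform,
        )
        payload = {
            "metric": res.metric,
            "observed_auc_diff": res.observed_auc_diff,
            "p_two_sided": res.p_two_sided,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_perm": res.n_perm,
        }
        with open(out / "permutation.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        pd.DataFrame({"null_auc_diff": res.null_diffs}).to_csv(
            out / "permutation_null.csv", index=False
        )
        report.outputs["permutation"] = str(out / "permutation.json")
        state["permutation"] = res

    @stage("associations")
    def _assoc():
        sig_regions = [
            atlas.thickness_column(r.roi)
            for r in state["morphometry"]
            if r.p_adj < 0.05
        ] or [config.mediation_x]
        assoc = behavior.association_table(
            state["cohort"],
            region_cols=tuple(sig_regions),
            variable_cols=("use_duration_months", "bis_ai", "bis_mi", "bis_npi", "vas",
                           "symptom_count"),
            covariate_cols=config.assoc_covariate_cols,
        )
        assoc.to_csv(out / "associations.csv", index=False)
        report.outputs["associations"] = str(out / "associations.csv")
        state["associations"] = assoc

    @stage("mediation")
    def _mediate():
        cases = state["cohort"][state["cohort"]["group"] == "B"]
        cov = cases[list(config.assoc_covariate_cols)].to_numpy(dtype=float)
        res = mediation.mediate_serial(
            cases[config.mediation_x],
            cases[config.mediation_m1],
            cases[config.mediation_m2],
            cases[config.mediation_y],
            covariates=cov,
            n_boot=config.n_boot,
            seed=seed_boot,
        )
        payload = {
            "kind": res.kind,
            "paths": res.paths,
            "indirect": res.indirect,
            "ci": {k: list(v) for k, v in res.ci.items()},
            "proportion_mediated": res.proportion_mediated,
            "n_boot": res.n_boot,
            "n": res.n,
        }
        with open(out / "mediation.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        report.outputs["mediation"] = str(out / "mediation.json")
        state["mediation"] = res

    config.to_yaml(out / "config.yaml")
    report.outputs["config"] = str(out / "config.yaml")
    report.outputs["report"] = str(out / "report.json")
    report.to_json(out / "report.json")
    return report
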
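"""Reading and writing cohort tables and network artifacts.

Two input dialects are supported for thickness tables:

* ``tidy-csv`` — one row per subject with ``subject_id`` plus 68 columns
  named ``<hemi>_<region>_thickness`` (and optionally covariates/behavior).
* ``aparc-stats-tsv`` — the tab-separated tables written by FreeSurfer's
  ``aparcstats2table --meas thickness``, one per hemisphere, merged on the
  subject-id column.  Non-ROI columns (MeanThickness, eTIV, BrainSegVol...)
  are ignored except ``eTIV`` which is carried as the ``etiv`` covariate if
  present.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas

__all__ = ["read_thickness_table", "read_cohort_csv", "write_network_csv", "read_network_csv"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy cohort CSV and validate the thickness schema."""
    df = pd.read_csv(path)
    _validate_subjects(df)
    _validate_thickness_columns(df)
    return df


def _validate_subjects(df: pd.DataFrame) -> None:
    if "subject_id" not in df.columns:
        raise SchemaError("missing required column 'subject_id'")
    dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate subject ids: {sorted(set(dup))}")


def _validate_thickness_columns(df: pd.DataFrame) -> None:
    missing = [c for c in atlas.THICKNESS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing ROI thickness column(s): {missing}")


def read_thickness_table(
    path: str | Path, dialect: str = "tidy-csv", rh_path: str | Path | None = None
) -> pd.DataFrame:
    """Read a thickness table in the given dialect.

    For ``aparc-stats-tsv``, ``path`` is the left-hemisphere table and
    ``rh_path`` the right-hemisphere table; the merged frame carries the 68
    thickness columns in canonical atlas order.
    """
    if dialect == "tidy-csv":
        return read_cohort_csv(path)
    if dialect == "aparc-stats-tsv":
        if rh_path is None:
            raise ValueError("aparc-stats-tsv dialect needs both lh (path) and rh (rh_path) tables")
        lh = _read_aparc_hemi(path, "lh")
        rh = _read_aparc_hemi(rh_path, "rh")
        merged = lh.merge(rh, on="subject_id", how="inner", suffixes=("", "_rh"))
        lost = set(lh["subject_id"]) ^ set(rh["subject_id"])
        if lost:
            import warnings

            warnings.warn(f"subjects missing from one hemisphere table dropped: {sorted(lost)}")
        if "etiv" in lh.columns and "etiv_rh" in merged.columns:
            merged = merged.drop(columns=["etiv_rh"])
        cols = ["subject_id"] + [c for c in ["etiv"] if c in merged.columns]
        merged = merged[cols + list(atlas.THICKNESS_COLUMNS)]
        _validate_subjects(merged)
        _validate_thickness_columns(merged)
        return merged
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_aparc_hemi(path: str | Path, hemi: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]  # e.g. 'lh.aparc.thickness'
    df = df.rename(columns={id_col: "subject_id"})
    expected = [f"{hemi}_{r}_thickness" for r in atlas.DK_REGIONS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{hemi} aparc table missing ROI column(s): {missing}")
    keep = ["subject_id"] + expected
    if "eTIV" in df.columns:
        df = df.rename(columns={"eTIV": "etiv"})
        keep.append("etiv")
    out = df[keep]
    _validate_subjects(out)
    return out


def write_network_csv(weights: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write a ROI-labelled symmetric weight matrix as CSV."""
    pd.DataFrame(weights, index=labels, columns=labels).to_csv(path)


def read_network_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_edge_list(adjacency: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write a binary adjacency as a two-column undirected edge-list CSV."""
    rows, cols = np.nonzero(np.triu(adjacency, k=1))
    pd.DataFrame(
        {"source": [labels[i] for i in rows], "target": [labels[j] for j in cols]}
    ).to_csv(path, index=False)


def read_adjacency(path: str | Path, labels: list[str] | None = None) -> np.ndarray:
    """Read an adjacency from a dense matrix CSV (with label header) or a
    source/target edge-list CSV."""
    df = pd.read_csv(path)
    if set(df.columns[:2]) == {"source", "target"}:
        if labels is None:
            labels = sorted(set(df["source"]) | set(df["target"]))
        idx = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)))
        for s, t in zip(df["source"], df["target"]):
            adj[idx[s], idx[t]] = adj[idx[t], idx[s]] = 1.0
        return adj
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float)
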
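"""Reading and writing the pipeline's CSV/JSON dialects.

``thickness.csv``: subject_id, group, month, region, thickness_mm
(optional ``imputed`` boolean). ``covariates.csv``: subject_id, group,
age_years, sex, lesion_load_ml, tiv_ml (tiv optional). Adjacency
matrices are full symmetric region-labelled CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import WeightedNetwork

__all__ = [
    "read_thickness",
    "write_thickness",
    "read_covariates",
    "write_covariates",
    "write_adjacency",
    "read_adjacency",
    "write_json",
]

_THICKNESS_REQUIRED = ["subject_id", "group", "month", "region", "thickness_mm"]
_COVARIATE_REQUIRED = ["subject_id", "group", "age_years", "sex", "lesion_load_ml"]


def read_thickness(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format thickness table."""
    df = pd.read_csv(path)
    missing = [c for c in _THICKNESS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "month", "region"])
    if dup.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(
            f"{path}: duplicate (subject, month, region) rows at lines {lines[:10]}"
        )
    if not np.isfinite(df["thickness_mm"]).all():
        raise ValueError(f"{path}: non-finite thickness values")
    counts = df.groupby(["subject_id", "month"], observed=True)["region"].nunique()
    if counts.nunique() > 1:
        raise ValueError(
            f"{path}: incomplete region sets — visits have differing region counts"
        )
    if "imputed" not in df.columns:
        df["imputed"] = False
    return df


def write_thickness(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COVARIATE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicated subjects {dup}")
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_adjacency(net: WeightedNetwork, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    net.to_frame().to_csv(path, index_label="region")


def read_adjacency(path: str | Path, group: str = "", month: int = 0) -> WeightedNetwork:
    df = pd.read_csv(path, index_col="region")
    return WeightedNetwork(df.to_numpy(), list(df.columns), group, month)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
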
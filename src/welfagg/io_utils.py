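"""CSV/JSON/YAML artifact readers and writers with validation.

All CSVs are UTF-8 with a header row and '.' decimal separator.  Readers
validate column names and value domains and report the offending file, line
(1-based, counting the header) and column on failure.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArtifactError",
    "read_herds_csv",
    "write_herds_csv",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_measures_csv",
    "write_measures_csv",
    "read_scores_csv",
    "write_scores_csv",
    "write_json",
    "read_json",
    "load_config_file",
]

_FLOAT_FORMAT = "%.10g"


class ArtifactError(ValueError):
    """A malformed on-disk artifact (file, line and column in the message)."""


def _read_csv(path, required: Mapping[str, type]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise ArtifactError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ArtifactError(f"{path}: missing column(s) {missing}")
    return df


def _check_int_domain(df: pd.DataFrame, path, column: str, allowed=None) -> None:
    values = df[column]
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0.5)))
    if allowed is not None:
        bad |= ~numeric.isin(list(allowed))
    if bad.any():
        idx = int(bad.idxmax())
        raise ArtifactError(
            f"{path}: line {idx + 2}, column '{column}': invalid value "
            f"{values.iloc[idx]!r}"
            + (f" (allowed: {sorted(allowed)})" if allowed is not None else "")
        )


def read_herds_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"farm_id": str, "cow_id": int, "gait_score": int})
    _check_int_domain(df, path, "gait_score", allowed={0, 1, 2})
    df["gait_score"] = df["gait_score"].astype(int)
    return df


def write_herds_csv(df: pd.DataFrame, path) -> None:
    df[["farm_id", "cow_id", "gait_score"]].to_csv(path, index=False)


def read_ratings_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"respondent_id": str, "mild_pct": float,
                          "severe_pct": float, "rating": int})
    _check_int_domain(df, path, "rating", allowed=set(range(11)))
    df["rating"] = df["rating"].astype(int)
    return df


def write_ratings_csv(df: pd.DataFrame, path) -> None:
    df[["respondent_id", "mild_pct", "severe_pct", "rating"]].to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def read_measures_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"respondent_id": str, "measure": str, "rating": int})
    _check_int_domain(df, path, "rating", allowed=set(range(11)))
    df["rating"] = df["rating"].astype(int)
    return df


def write_measures_csv(df: pd.DataFrame, path) -> None:
    df[["respondent_id", "measure", "rating"]].to_csv(path, index=False)


_SCORE_COLUMNS = [
    "farm_id",
    "mild_pct",
    "severe_pct",
    "index",
    "welfare_score",
    "category",
    "profile",
]


def read_scores_csv(path) -> pd.DataFrame:
    return _read_csv(path, dict.fromkeys(_SCORE_COLUMNS))


def write_scores_csv(df: pd.DataFrame, path) -> None:
    df[_SCORE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_config_file(path) -> dict:
    """Load a YAML config, falling back to JSON."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ArtifactError(f"{path}: config must be a mapping")
    return data
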
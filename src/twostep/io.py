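"""Delimited-text I/O with schema validation.

All tables are plain CSV. Missed trials serialize with empty choice,
transition and reward fields and round-trip losslessly through pandas
nullable dtypes. Validation errors name the offending column and, for
value errors, the 1-based data row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .coding import DESIGN_COLUMNS
from .task import TRIAL_COLUMNS

__all__ = [
    "SchemaError",
    "read_trials",
    "write_trials",
    "read_covariates",
    "write_covariates",
    "read_design",
    "write_design",
    "read_config",
    "write_config",
]

#: Deterministic float rendering for all emitted tables.
FLOAT_FORMAT = "%.10g"

COVARIATE_REQUIRED = ["subject_id", "extraversion_raw", "subsample"]

_TRIAL_DTYPES = {
    "trial": "int64",
    "choice1": "Int64",
    "pair": "Int64",
    "common": "boolean",
    "choice2": "Int64",
    "reward": "Int64",
    "missed": "bool",
}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table: missing required column '{col}'")


def _check_values(df: pd.DataFrame, col: str, allowed: set, what: str) -> None:
    bad = df[col].dropna()
    bad = bad[~bad.isin(allowed)]
    if len(bad):
        row = int(bad.index[0]) + 1
        raise SchemaError(
            f"{what} table: column '{col}' row {row}: "
            f"invalid value {bad.iloc[0]!r} (allowed: {sorted(allowed)})"
        )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    _require_columns(trials, TRIAL_COLUMNS, "trial")
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, "trial")
    try:
        df = df.astype(_TRIAL_DTYPES)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"trial table: dtype coercion failed: {exc}") from exc
    for col in ("choice1", "pair", "choice2", "reward"):
        _check_values(df, col, {0, 1}, "trial")
    completed = ~df["missed"]
    for col in ("choice1", "pair", "common", "choice2", "reward"):
        holes = df.loc[completed, col].isna()
        if holes.any():
            row = int(holes[holes].index[0]) + 1
            raise SchemaError(
                f"trial table: column '{col}' row {row}: null on a completed trial"
            )
    return df[TRIAL_COLUMNS]


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    _require_columns(covariates, COVARIATE_REQUIRED, "covariate")
    covariates.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COVARIATE_REQUIRED, "covariate")
    _check_values(df, "subsample", {1, 2}, "covariate")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise SchemaError(f"covariate table: duplicate subject_id {dup!r}")
    return df


def write_design(rows: pd.DataFrame, path: str | Path) -> None:
    _require_columns(rows, DESIGN_COLUMNS, "design")
    rows.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DESIGN_COLUMNS, "design")
    for col in ("rew", "trans", "rewXtrans"):
        _check_values(df, col, {-1, 1}, "design")
    _check_values(df, "stay", {0, 1}, "design")
    return df


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
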
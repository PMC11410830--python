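"""CSV/YAML file contracts for every pipeline table.

All tables are plain tidy CSV. Schemas are validated on read with an error
that lists missing columns. Distance matrices are square labeled CSVs;
dendrograms are serialized as Newick; configs round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_yaml",
    "write_yaml",
    "write_newick",
]

SCHEMAS: dict[str, list[str]] = {
    "design": ["treatment_id", "kind", "level", "factors", "n_replicates"],
    "responses": ["unit_id", "treatment_id", "response", "value"],
    "effects": ["treatment_id", "response", "effect", "ci_low", "ci_high", "p_raw", "p_adj"],
    "nullpred": [
        "treatment_id",
        "response",
        "model",
        "pred_mean",
        "pred_sd",
        "ci_low",
        "ci_high",
        "n_draws",
    ],
    "calls": ["treatment_id", "response", "model", "observed", "dn", "label"],
    "di": ["treatment_id", "level", "di_raw", "di_norm"],
}


def _check_schema(df: pd.DataFrame, schema: str, path) -> pd.DataFrame:
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        extra = [c for c in df.columns if c not in required]
        raise ValueError(
            f"{path}: not a valid {schema!r} table — missing columns {missing}"
            + (f", extra columns {extra}" if extra else "")
        )
    return df


def read_table(path, schema: str) -> pd.DataFrame:
    """Read one of the typed CSV tables, validating its schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if schema == "design":
        df["factors"] = df["factors"].fillna("").astype(str)
    return _check_schema(df, schema, path)


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    if schema is not None:
        _check_schema(df, schema, path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_distance_matrix(path) -> pd.DataFrame:
    dm = pd.read_csv(path, index_col=0)
    if dm.shape[0] != dm.shape[1] or list(dm.index) != list(dm.columns):
        raise ValueError(f"{path}: distance matrix must be square with matching labels")
    return dm


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dm.to_csv(path)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: Mapping, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=False)


def write_newick(newick: str, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
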
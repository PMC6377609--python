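"""Dataset and species-table I/O.

The dataset format is comma-delimited with a header row:
sample_id, age_dpf, arm, time_min, amount_pmole, pool_size — one row per
pooled larval sample, dot decimal separator.  Species tables for the
allometric comparison declare their clearance units in a comment line
(``# clearance_units: mL/min``); values are harmonised to nL/h on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .models import ARMS, DATASET_COLUMNS

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_species_table",
    "CLEARANCE_UNIT_TO_NL_PER_H",
]

#: conversion factors from declared clearance units to nL/h
CLEARANCE_UNIT_TO_NL_PER_H = {
    "nL/h": 1.0,
    "uL/h": 1e3,
    "mL/h": 1e6,
    "L/h": 1e9,
    "uL/min": 6e4,
    "mL/min": 6e7,
    "L/min": 6e10,
}


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a dataset file; errors name the offending row/column.

    Row numbers in messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path.name}: dataset has a header but no data rows")
    out = pd.DataFrame(index=df.index)
    out["sample_id"] = df["sample_id"].astype(str)
    for col, caster, constraint in (
        ("age_dpf", int, lambda v: v > 0),
        ("time_min", float, lambda v: v >= 0 and np.isfinite(v)),
        ("amount_pmole", float, lambda v: v >= 0 and np.isfinite(v)),
        ("pool_size", int, lambda v: v >= 1),
    ):
        vals = []
        for i, raw in enumerate(df[col]):
            try:
                v = caster(float(raw)) if caster is int else caster(raw)
                if caster is int and float(raw) != v:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}: row {i + 1}, column {col!r}: "
                    f"cannot parse value {raw!r}"
                ) from None
            if not constraint(v):
                raise ValueError(
                    f"{path.name}: row {i + 1}, column {col!r}: "
                    f"value {raw!r} violates constraints"
                )
            vals.append(v)
        out[col] = vals
    arms = []
    for i, raw in enumerate(df["arm"]):
        arm = str(raw).strip()
        if arm not in ARMS:
            raise ValueError(
                f"{path.name}: row {i + 1}, column 'arm': unknown arm {arm!r} "
                f"(expected one of {ARMS})"
            )
        arms.append(arm)
    out["arm"] = arms
    return out[list(DATASET_COLUMNS)]


def write_dataset(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a dataset in the canonical column order; round-trips losslessly
    through :func:`read_dataset` (full float precision)."""
    path = Path(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing column(s) {missing}")
    df.loc[:, list(DATASET_COLUMNS)].to_csv(path, index=False, float_format="%.17g")
    return path


def read_species_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a species clearance table and convert clearances to nL/h.

    Format: CSV with columns species, bodyweight_g, clearance, mature
    (true/false), preceded by a ``# clearance_units: <unit>`` comment line.
    """
    path = Path(path)
    units = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("clearance_units:"):
                    units = body.split(":", 1)[1].strip()
            elif line.strip():
                break
    if units is None:
        raise ValueError(
            f"{path.name}: no '# clearance_units: <unit>' header; "
            f"declare one of {sorted(CLEARANCE_UNIT_TO_NL_PER_H)}"
        )
    if units not in CLEARANCE_UNIT_TO_NL_PER_H:
        raise ValueError(
            f"{path.name}: unknown clearance unit {units!r}; "
            f"expected one of {sorted(CLEARANCE_UNIT_TO_NL_PER_H)}"
        )
    df = pd.read_csv(path, comment="#")
    req = {"species", "bodyweight_g", "clearance", "mature"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {sorted(missing)}")
    df["bodyweight_g"] = df["bodyweight_g"].astype(float)
    df["clearance"] = df["clearance"].astype(float) * CLEARANCE_UNIT_TO_NL_PER_H[units]
    df["mature"] = (
        df["mature"].astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
    )
    if df["mature"].isna().any():
        bad = int(df["mature"].isna().idxmax()) + 1
        raise ValueError(f"{path.name}: row {bad}, column 'mature': expected true/false")
    df.attrs["clearance_units"] = "nL/h"
    return df
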
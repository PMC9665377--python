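"""Long-format CSV schemas for the questionnaire and SCR tables.

Questionnaire: ``participant,condition,statement,value`` with S1-S6
integer-valued in [-3, 3] and S7 real in [0, 10].
SCR: ``participant,trial,condition,threat_id,raw,normalized`` with one
of each threat id per participant and every condition four times.
Violations are reported with the offending row index.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .bci import CONDITION_KEYS
from .synth import STATEMENTS

__all__ = ["SchemaError", "validate_questionnaire", "validate_scr", "write_dataset", "read_dataset"]

QUESTIONNAIRE_COLUMNS = ["participant", "condition", "statement", "value"]
SCR_COLUMNS = ["participant", "trial", "condition", "threat_id", "raw", "normalized"]


class SchemaError(ValueError):
    """A dataset row violates the documented schema."""


def _bad_rows(mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:10]]
        raise SchemaError(f"{message} (rows {rows})")


def validate_questionnaire(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != QUESTIONNAIRE_COLUMNS:
        raise SchemaError(f"expected columns {QUESTIONNAIRE_COLUMNS}, got {list(df.columns)}")
    if len(df) == 0:
        return df
    _bad_rows(~df["condition"].isin(CONDITION_KEYS), "unknown condition key")
    _bad_rows(~df["statement"].isin(STATEMENTS), "unknown statement")
    value = pd.to_numeric(df["value"], errors="coerce")
    _bad_rows(value.isna(), "non-numeric value")
    likert = df["statement"] != "S7"
    _bad_rows(likert & (value.round() != value), "non-integer Likert value")
    _bad_rows(likert & ((value < -3) | (value > 3)), "Likert value outside [-3, 3]")
    _bad_rows(~likert & ((value < 0) | (value > 10)), "VAS value outside [0, 10]")
    return df


def validate_scr(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != SCR_COLUMNS:
        raise SchemaError(f"expected columns {SCR_COLUMNS}, got {list(df.columns)}")
    if len(df) == 0:
        return df
    _bad_rows(~df["condition"].isin(CONDITION_KEYS), "unknown condition key")
    raw = pd.to_numeric(df["raw"], errors="coerce")
    _bad_rows(raw.isna() | (raw < 0), "raw magnitude must be numeric and >= 0")
    n_trials = df.groupby("participant")["trial"].nunique().max()
    for pid, grp in df.groupby("participant"):
        threat = sorted(grp["threat_id"].tolist())
        if threat != list(range(1, len(grp) + 1)):
            raise SchemaError(f"participant {pid}: threat ids are not a permutation of 1..{len(grp)}")
        counts = grp["condition"].value_counts()
        if set(counts.index) != set(CONDITION_KEYS) or counts.nunique() != 1:
            raise SchemaError(f"participant {pid}: conditions are not balanced across trials")
    del n_trials
    return df


def write_dataset(table: pd.DataFrame, path) -> None:
    """Write a validated long-format table as UTF-8 CSV with header."""
    if list(table.columns) == QUESTIONNAIRE_COLUMNS:
        validate_questionnaire(table)
    elif list(table.columns) == SCR_COLUMNS:
        validate_scr(table)
    else:
        raise SchemaError(f"unrecognized schema: {list(table.columns)}")
    table.to_csv(path, index=False, encoding="utf-8")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format CSV written by :func:`write_dataset`."""
    head = pd.read_csv(path, nrows=0)
    if list(head.columns) == QUESTIONNAIRE_COLUMNS:
        df = pd.read_csv(
            path,
            dtype={"participant": str, "condition": str, "statement": str, "value": float},
        )
        return validate_questionnaire(df)
    if list(head.columns) == SCR_COLUMNS:
        df = pd.read_csv(
            path,
            dtype={
                "participant": str, "trial": int, "condition": str,
                "threat_id": int, "raw": float, "normalized": float,
            },
        )
        return validate_scr(df)
    raise SchemaError(f"unrecognized schema: {list(head.columns)}")
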
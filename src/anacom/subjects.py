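"""Subject table handling.

The subject table is a plain :class:`pandas.DataFrame` with one row per
subject: a ``subject_id`` column, a ``group`` column taking values
``patient`` or ``control``, and one column per behavioural measure (missing
entries are NaN and are excluded from any test that needs them).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("patient", "control")


def validate_subject_table(df: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("subject table needs 'subject_id' and 'group' columns")
    bad = set(df["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    return df


def read_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_subject_table(df)


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_subject_table(df).to_csv(path, index=False)


def measure_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ("subject_id", "group")]


def patient_scores(df: pd.DataFrame, measure: str) -> dict[str, float]:
    """Per-patient scores for one measure; subjects with NaN are omitted."""
    sub = df[df["group"] == "patient"][["subject_id", measure]].dropna()
    return dict(zip(sub["subject_id"], sub[measure].astype(float)))


def control_scores(df: pd.DataFrame, measure: str) -> np.ndarray:
    vals = df.loc[df["group"] == "control", measure].dropna().to_numpy(float)
    return vals
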
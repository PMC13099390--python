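"""Reading and writing the canonical delimited-text schemas.

Two comma-separated UTF-8 files carry a study:

* ``choices.csv`` — one row per binary intertemporal choice:
  participant_id,timepoint,task_tag,trial_index,r_immediate,R_delayed,
  delay_days,choice
* ``cohort.csv`` — one row per participant:
  participant_id,site,group,arm,relapsed,days_to_event,dropped_out,
  hamd_ma1,hamd_ma2,<rating-scale columns>

Missing values are empty fields.  Missingness is permitted in clinical
scales but never in a recorded choice.  Unknown columns are preserved on
round-trip and ignored by the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_choices",
    "write_choices",
    "load_cohort",
    "write_cohort",
    "CHOICE_COLUMNS",
    "COHORT_COLUMNS",
    "SchemaError",
]

CHOICE_COLUMNS = (
    "participant_id",
    "timepoint",
    "task_tag",
    "trial_index",
    "r_immediate",
    "R_delayed",
    "delay_days",
    "choice",
)
COHORT_COLUMNS = (
    "participant_id",
    "site",
    "group",
    "arm",
    "relapsed",
    "days_to_event",
    "dropped_out",
    "hamd_ma1",
    "hamd_ma2",
)

TIMEPOINTS = ("MA1", "MA2")
TASK_TAGS = ("mcq", "adaptive")
CHOICES = ("immediate", "delayed")
GROUPS = ("patient", "control")
ARMS = ("MA1-D-MA2", "MA1-MA2-D", "none")
SITES = ("A", "B")


class SchemaError(ValueError):
    """A file does not conform to the canonical schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_categorical(df, column, allowed, path) -> None:
    values = df[column].dropna()
    bad = ~values.isin(allowed)
    if bad.any():
        row = int(values.index[bad][0]) + 2  # header is line 1
        raise SchemaError(
            f"{path}: row {row}, column {column!r}: "
            f"{values[bad].iloc[0]!r} not in {tuple(allowed)}"
        )


def _check_numeric(df, column, path, *, integer=False, minimum=None):
    try:
        values = pd.to_numeric(df[column])
    except (ValueError, TypeError) as exc:
        raise SchemaError(
            f"{path}: column {column!r} has an unparseable value: {exc}"
        ) from None
    if values.isna().any():
        row = int(values.index[values.isna()][0]) + 2
        raise SchemaError(f"{path}: row {row}, column {column!r}: missing value")
    if minimum is not None and (values < minimum).any():
        row = int(values.index[values < minimum][0]) + 2
        raise SchemaError(
            f"{path}: row {row}, column {column!r}: value below {minimum}"
        )
    return values.astype(int) if integer else values.astype(float)


def load_choices(path) -> pd.DataFrame:
    """Read a choices.csv into a validated DataFrame (row order preserved)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, CHOICE_COLUMNS, path)
    if len(df) == 0:
        return df
    _check_categorical(df, "timepoint", TIMEPOINTS, path)
    _check_categorical(df, "task_tag", TASK_TAGS, path)
    if df["choice"].isna().any():
        row = int(df.index[df["choice"].isna()][0]) + 2
        raise SchemaError(f"{path}: row {row}, column 'choice': missing value")
    _check_categorical(df, "choice", CHOICES, path)
    df["trial_index"] = _check_numeric(df, "trial_index", path, integer=True,
                                       minimum=1)
    df["r_immediate"] = _check_numeric(df, "r_immediate", path, minimum=0)
    df["R_delayed"] = _check_numeric(df, "R_delayed", path, minimum=0)
    df["delay_days"] = _check_numeric(df, "delay_days", path, integer=True,
                                      minimum=1)
    bad_geom = ~(df["R_delayed"] > df["r_immediate"])
    if bad_geom.any():
        row = int(df.index[bad_geom][0]) + 2
        raise SchemaError(
            f"{path}: row {row}: R_delayed must exceed r_immediate"
        )
    key = ["participant_id", "timepoint", "task_tag", "trial_index"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(
            f"{path}: row {row}: duplicate (participant, timepoint, task, "
            "trial_index) key"
        )
    return df


def write_choices(df: pd.DataFrame, path) -> None:
    """Write choice trials in the canonical column order."""
    _require_columns(df, CHOICE_COLUMNS, path)
    extra = [c for c in df.columns if c not in CHOICE_COLUMNS]
    df.to_csv(path, index=False, columns=list(CHOICE_COLUMNS) + extra)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort.csv into a validated DataFrame.

    Booleans are parsed from {True, False, empty}; empty relapse fields
    (controls, dropouts) become missing, as do absent scale entries.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, COHORT_COLUMNS, path)
    if len(df) == 0:
        return df
    dup = df.duplicated(subset=["participant_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: row {row}: duplicate participant_id")
    _check_categorical(df, "site", SITES, path)
    _check_categorical(df, "group", GROUPS, path)
    _check_categorical(df, "arm", ARMS, path)
    for col in ("relapsed", "dropped_out"):
        vals = df[col].dropna()
        ok = vals.astype(str).isin(["True", "False"])
        if not ok.all():
            row = int(vals.index[~ok][0]) + 2
            raise SchemaError(
                f"{path}: row {row}, column {col!r}: expected True/False"
            )
    df["relapsed"] = df["relapsed"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype("boolean")
    df["dropped_out"] = df["dropped_out"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype("boolean").fillna(False)
    # controls carry no randomization arm or relapse outcome
    controls = df["group"] == "control"
    if (df.loc[controls, "arm"] != "none").any():
        raise SchemaError(f"{path}: controls must have arm='none'")
    if df.loc[controls, "relapsed"].notna().any():
        raise SchemaError(f"{path}: controls must have relapsed missing")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write participant records; scale columns follow the fixed columns."""
    _require_columns(df, COHORT_COLUMNS, path)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    df.to_csv(path, index=False, columns=list(COHORT_COLUMNS) + extra)
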
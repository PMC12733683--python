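"""Reading and writing time-course tables.

The on-disk format is a tidy UTF-8 CSV with header
``condition,replicate,time_h,biomass,product`` — one row per replicate-time
observation, product left empty where not assayed.  Writing is canonical:
fixed column order, rows sorted by (condition, replicate, time), numbers
rendered with 6 significant digits — so write/read/write round trips are
byte-identical and fixture hashes are stable.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import TIMECOURSE_COLUMNS, TimeCourse

__all__ = [
    "TimeCourseParseError",
    "read_timecourse_csv",
    "read_study_csv",
    "write_timecourse_csv",
    "write_study_csv",
]

CSV_COLUMNS = ("condition",) + TIMECOURSE_COLUMNS


class TimeCourseParseError(ValueError):
    """A time-course CSV violated the documented format or its invariants."""


def _validated(df: pd.DataFrame, path: str) -> dict[str, TimeCourse]:
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TimeCourseParseError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    for col in ("replicate", "time_h", "biomass", "product"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TimeCourseParseError(
                f"{path}: non-numeric value in column '{col}': {exc}"
            ) from None
    if df.duplicated(["condition", "replicate", "time_h"]).any():
        raise TimeCourseParseError(
            f"{path}: duplicate (condition, replicate, time) observation"
        )
    for col in ("time_h", "biomass", "product"):
        vals = df[col].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise TimeCourseParseError(f"{path}: negative value in column '{col}'")
    if df["biomass"].isna().any():
        raise TimeCourseParseError(f"{path}: biomass missing in some rows")
    out = {}
    for cond, sub in df.groupby("condition", sort=True):
        try:
            out[str(cond)] = TimeCourse(
                condition=str(cond), data=sub.drop(columns="condition")
            )
        except ValueError as exc:
            raise TimeCourseParseError(f"{path}: condition '{cond}': {exc}") from None
    return out


def read_study_csv(path: str | os.PathLike) -> dict[str, TimeCourse]:
    """Read a CSV that may hold several conditions; one TimeCourse per label."""
    try:
        df = pd.read_csv(path, dtype={"condition": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TimeCourseParseError(f"{path}: unreadable CSV: {exc}") from None
    if df.empty:
        raise TimeCourseParseError(f"{path}: no observations")
    return _validated(df, str(path))


def read_timecourse_csv(path: str | os.PathLike) -> TimeCourse:
    """Read a single-condition time-course CSV."""
    study = read_study_csv(path)
    if len(study) != 1:
        raise TimeCourseParseError(
            f"{path}: expected one condition, found {sorted(study)}; "
            "use read_study_csv for multi-condition files"
        )
    return next(iter(study.values()))


def _fmt(v: float) -> str:
    if not np.isfinite(v):
        return ""
    return f"{v:.6g}"


def _frame_for(tc: TimeCourse) -> pd.DataFrame:
    df = tc.data.copy()
    df.insert(0, "condition", tc.condition)
    return df


def _write(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df = df.sort_values(["condition", "replicate", "time_h"], kind="mergesort")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.condition},{int(row.replicate)},{_fmt(row.time_h)},"
                f"{_fmt(row.biomass)},{_fmt(row.product)}\n"
            )


def write_timecourse_csv(tc: TimeCourse, path: str | os.PathLike) -> None:
    """Write one TimeCourse in canonical CSV form (empty field = not assayed)."""
    _write(_frame_for(tc), path)


def write_study_csv(study: dict[str, TimeCourse], path: str | os.PathLike) -> None:
    """Write several conditions into one canonical CSV."""
    if not study:
        raise ValueError("study is empty")
    _write(pd.concat([_frame_for(tc) for tc in study.values()]), path)
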
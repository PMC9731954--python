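"""Readers and writers for the released CSV schemas and for session logs.

Score tables are exchanged as 11-column CSV files (one file per battery in
the released data); normative tables as 13-column CSV files.  Numbers are
written at full precision with a period decimal separator and no thousands
separators, so a write-then-read round trip is lossless on every field.

Session logs travel as JSON lines (one assessment per line).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .records import NORMS_COLUMNS, SCORE_COLUMNS, NormRow, ScoreRecord, SessionLog
from .registry import EDUCATION_LEVELS, get_battery, UnknownBatteryError

__all__ = [
    "SchemaError",
    "load_score_frame",
    "load_score_table",
    "write_score_frame",
    "write_score_table",
    "records_to_frame",
    "frame_to_records",
    "write_norms_table",
    "load_norms_table",
    "write_session_logs",
    "read_session_logs",
]

Source = Union[str, Path, IO]


class SchemaError(ValueError):
    """A score file violates the released schema; names the row and column."""


def _fail(row, column, msg) -> "SchemaError":
    where = f"row {row}" if row is not None else "header"
    return SchemaError(f"{where}, column {column!r}: {msg}")


def _to_int(frame: pd.DataFrame, column: str, allow_missing: bool = False) -> pd.Series:
    raw = frame[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(bad.idxmax())
        raise _fail(i, column, f"malformed number {raw[i]!r}")
    if not allow_missing and out.isna().any():
        i = int(out.isna().idxmax())
        raise _fail(i, column, "missing value in a required field")
    frac = out.dropna() % 1
    if (frac != 0).any():
        i = int((out % 1 != 0).idxmax())
        raise _fail(i, column, f"expected an integer, got {raw[i]!r}")
    return out.astype("Int64")


def _to_float(frame: pd.DataFrame, column: str, allow_missing: bool = False) -> pd.Series:
    raw = frame[column].astype("string").str.strip()
    missing = raw.isna() | (raw == "")
    out = np.full(len(raw), np.nan)
    present = (~missing).to_numpy()
    try:
        # numpy's parser is correctly rounded, so written values read back
        # bit-exactly; pandas' fast to_numeric path is not
        out[present] = np.asarray(raw[~missing], dtype=float)
    except ValueError:
        for i, v in zip(np.flatnonzero(present), raw[~missing]):
            try:
                float(v)
            except ValueError:
                raise _fail(int(i), column, f"malformed number {v!r}") from None
        raise
    if not allow_missing and missing.any():
        i = int(missing.to_numpy().argmax())
        raise _fail(i, column, "missing value in a required field")
    return pd.Series(out, index=frame.index)


def load_score_frame(source: Source) -> pd.DataFrame:
    """Read a released-schema score table into a validated DataFrame.

    The header must match the 11 released column names exactly (order
    included).  Empty ``gender``/``education_level``/``grand_index`` fields
    become missing values.  Row order — administration order within each test
    run — is preserved.

    Raises
    ------
    SchemaError
        On an unknown or out-of-order column, a malformed number, an
        education code outside the published coding, or a
        (battery, subtest) pair absent from the battery registry.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if tuple(df.columns) != SCORE_COLUMNS:
        raise _fail(None, tuple(df.columns), f"expected columns {list(SCORE_COLUMNS)}")
    out = pd.DataFrame(index=df.index)
    out["user_id"] = df["user_id"].astype(str)
    out["age"] = _to_int(df, "age")
    gender = df["gender"].astype("string").str.strip().str.lower()
    out["gender"] = gender.where(gender.notna() & (gender != ""), None)
    out["education_level"] = _to_int(df, "education_level", allow_missing=True)
    out["country"] = df["country"].astype(str)
    out["test_run_id"] = df["test_run_id"].astype(str)
    out["battery_id"] = _to_int(df, "battery_id")
    out["specific_subtest_id"] = _to_int(df, "specific_subtest_id")
    out["time_of_day"] = _to_int(df, "time_of_day")
    out["raw_score"] = _to_float(df, "raw_score")
    out["grand_index"] = _to_float(df, "grand_index", allow_missing=True)

    bad_edu = out["education_level"].notna() & ~out["education_level"].isin(
        list(EDUCATION_LEVELS)
    )
    if bad_edu.any():
        i = int(bad_edu.idxmax())
        raise _fail(i, "education_level", f"unknown education code {out['education_level'][i]}")

    for i, (bid, sid) in enumerate(zip(out["battery_id"], out["specific_subtest_id"])):
        try:
            battery = get_battery(int(bid))
        except UnknownBatteryError:
            raise _fail(i, "battery_id", f"unknown battery {bid}") from None
        if int(sid) not in battery:
            raise _fail(i, "specific_subtest_id", f"subtest {sid} is not in battery {bid}")

    # Grand Index is a per-run constant: every row of a test run repeats it.
    for run_id, grp in out.groupby("test_run_id")["grand_index"]:
        vals = grp.dropna().unique()
        if len(vals) > 1:
            raise _fail(int(grp.index[0]), "grand_index",
                        f"inconsistent grand_index within test run {run_id!r}")
    return out


def frame_to_records(frame: pd.DataFrame) -> list[ScoreRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ScoreRecord(
                user_id=str(row.user_id),
                age=int(row.age),
                gender=None if pd.isna(row.gender) else str(row.gender),
                education_level=None if pd.isna(row.education_level) else int(row.education_level),
                country=str(row.country),
                test_run_id=str(row.test_run_id),
                battery_id=int(row.battery_id),
                specific_subtest_id=int(row.specific_subtest_id),
                time_of_day=int(row.time_of_day),
                raw_score=float(row.raw_score),
                grand_index=None if pd.isna(row.grand_index) else float(row.grand_index),
            )
        )
    return records


def records_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "user_id": r.user_id,
                "age": r.age,
                "gender": r.gender,
                "education_level": r.education_level,
                "country": r.country,
                "test_run_id": r.test_run_id,
                "battery_id": r.battery_id,
                "specific_subtest_id": r.specific_subtest_id,
                "time_of_day": r.time_of_day,
                "raw_score": r.raw_score,
                "grand_index": r.grand_index,
            }
        )
    df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    df["age"] = df["age"].astype("Int64")
    df["education_level"] = df["education_level"].astype("Int64")
    for c in ("battery_id", "specific_subtest_id", "time_of_day"):
        df[c] = df[c].astype("Int64")
    return df


def load_score_table(source: Source) -> list[ScoreRecord]:
    """Read a released-schema score table as a list of :class:`ScoreRecord`."""
    return frame_to_records(load_score_frame(source))


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if pd.isna(x):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        f = float(x)
        return str(int(f)) if f.is_integer() and abs(f) < 1e15 else repr(f)
    return str(x)


def write_score_frame(frame: pd.DataFrame, sink: Source) -> None:
    """Write a score DataFrame in the released 11-column schema."""
    out = frame.loc[:, list(SCORE_COLUMNS)].copy()
    _write_csv(out, sink)


def write_score_table(records: Iterable[ScoreRecord], sink: Source) -> None:
    write_score_frame(records_to_frame(records), sink)


def _write_csv(df: pd.DataFrame, sink: Source) -> None:
    text = ",".join(df.columns) + "\n"
    for row in df.itertuples(index=False):
        text += ",".join(_fmt(v) for v in row) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def write_norms_table(rows: Iterable[NormRow], sink: Source) -> None:
    """Write normative rows in the released 13-column schema.

    All rows are expected to belong to a single battery (the released data
    ships one norms file per battery).
    """
    df = pd.DataFrame([r.as_row() for r in rows], columns=list(NORMS_COLUMNS))
    _write_csv(df, sink)


def load_norms_table(source: Source) -> list[NormRow]:
    """Read a 13-column norms file back into :class:`NormRow` objects."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if tuple(df.columns) != NORMS_COLUMNS:
        raise _fail(None, tuple(df.columns), f"expected columns {list(NORMS_COLUMNS)}")
    rows = []
    for t in df.to_numpy(dtype=object):
        sid = str(t[1])
        rows.append(
            NormRow(
                subtest_name=str(t[0]),
                specific_subtest_id=None if sid.strip() == "" else int(float(sid)),
                age=str(t[2]),
                education_level=str(t[3]),
                gender=str(t[4]),
                N=int(t[5]),
                mean=float(t[6]),
                SD=float(t[7]),
                perc_10=float(t[8]),
                perc_25=float(t[9]),
                perc_50=float(t[10]),
                perc_75=float(t[11]),
                perc_90=float(t[12]),
            )
        )
    return rows


def write_session_logs(logs: Iterable[SessionLog], sink: Source,
                       with_trials: bool = False) -> None:
    """Write session logs as JSON lines (one assessment per line)."""
    text = "".join(json.dumps(log.to_dict(with_trials=with_trials)) + "\n" for log in logs)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def read_session_logs(source: Source) -> list[SessionLog]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    return [SessionLog.from_dict(json.loads(line)) for line in text.splitlines() if line.strip()]
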
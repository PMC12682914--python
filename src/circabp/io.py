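"""CSV input/output for BP series and cohort tables.

Series files are long-format with columns ``patient_id, timestamp (ISO-8601,
local clock), sbp_mmhg, dbp_mmhg, source`` plus optional ``flag`` and
``artifact_truth`` columns. The first reading of a patient anchors the
admission time when reading back.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FormatError
from .series import FLAG_VALID, BPSeries

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "timestamp", "sbp_mmhg", "dbp_mmhg", "source")


def write_bp_series(series_list, path) -> None:
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_bp_series(path) -> list[BPSeries]:
    """Read a long-format series CSV into one BPSeries per patient.

    Rows with unparseable timestamps are rejected (count logged); rows out of
    time order are re-sorted with a warning; exact duplicate timestamps keep
    the first row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        logger.warning("rejected %d rows with unparseable timestamps", int(bad.sum()))
        df, ts = df[~bad], ts[~bad]
    df = df.assign(_ts=ts)

    out: list[BPSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        if not grp["_ts"].is_monotonic_increasing:
            logger.warning("patient %s: rows out of time order, re-sorting", pid)
            grp = grp.sort_values("_ts", kind="mergesort")
        dup = grp["_ts"].duplicated()
        if dup.any():
            logger.warning("patient %s: dropping %d duplicate timestamps",
                           pid, int(dup.sum()))
            grp = grp[~dup]
        start = grp["_ts"].iloc[0]
        t_hours = (grp["_ts"] - start).dt.total_seconds().to_numpy() / 3600.0
        flags = (
            grp["flag"].to_numpy(dtype=object)
            if "flag" in grp.columns
            else np.full(len(grp), FLAG_VALID, dtype=object)
        )
        truth = (
            grp["artifact_truth"].to_numpy(dtype=int)
            if "artifact_truth" in grp.columns
            else None
        )
        out.append(
            BPSeries(
                patient_id=str(pid),
                start=start,
                t_hours=t_hours,
                sbp=grp["sbp_mmhg"].to_numpy(dtype=float),
                dbp=grp["dbp_mmhg"].to_numpy(dtype=float),
                source=str(grp["source"].iloc[0]),
                flags=flags,
                artifact_truth=truth,
            )
        )
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise FormatError("missing mandatory column: 'patient_id'")
    return df
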
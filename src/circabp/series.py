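"""In-memory container for one patient's blood-pressure time series.

Readings are stored on an admission-anchored hour axis (``t_hours``) together
with the admission timestamp, so both admission-aligned 24-h cycles and
wall-clock quantities (cosinor phase, day/night windows) are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: per-reading status codes
FLAG_VALID = "valid"
FLAG_ARTIFACT = "artifact"
FLAG_IMPUTED = "imputed"

SOURCE_INVASIVE = "invasive"
SOURCE_CUFF = "cuff"


@dataclass
class BPSeries:
    """One patient's timestamped systolic/diastolic readings.

    Parameters
    ----------
    patient_id : str
    start : pd.Timestamp
        Admission time (local clock); ``t_hours`` is measured from here.
    t_hours : np.ndarray
        Hours since admission, strictly increasing.
    sbp, dbp : np.ndarray
        Systolic / diastolic pressure, mmHg.
    source : str
        ``"invasive"`` (1-min averages) or ``"cuff"`` (scheduled cuff).
    flags : np.ndarray
        Per-reading status: ``valid`` | ``artifact`` | ``imputed``.
    artifact_truth : np.ndarray or None
        Generator ground truth (1 = injected artifact); absent for real data.
    meta : dict
        Free-form provenance (e.g. the generator's true rhythm parameters).
    """

    patient_id: str
    start: pd.Timestamp
    t_hours: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    source: str = SOURCE_CUFF
    flags: np.ndarray | None = None
    artifact_truth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.t_hours.shape, FLAG_VALID, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if np.any(np.diff(self.t_hours) <= 0):
            raise ValueError(
                f"{self.patient_id}: reading times must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.t_hours)

    @property
    def clock_hours(self) -> np.ndarray:
        """Wall-clock hour of each reading in [0, 24)."""
        start_clock = (
            self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        )
        return (start_clock + self.t_hours) % 24.0

    @property
    def span_hours(self) -> float:
        return float(self.t_hours[-1] - self.t_hours[0]) if len(self) else 0.0

    def mask(self, *, include_imputed: bool = True) -> np.ndarray:
        """Boolean mask of analysable readings (valid, optionally imputed)."""
        ok = self.flags == FLAG_VALID
        if include_imputed:
            ok |= self.flags == FLAG_IMPUTED
        return ok

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(self.t_hours, unit="h")

    def with_flags(self, flags: np.ndarray) -> "BPSeries":
        return replace(self, flags=np.asarray(flags, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timestamp": self.timestamps(),
                "sbp_mmhg": self.sbp,
                "dbp_mmhg": self.dbp,
                "source": self.source,
                "flag": self.flags,
            }
        )
        if self.artifact_truth is not None:
            df["artifact_truth"] = self.artifact_truth.astype(int)
        return df
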
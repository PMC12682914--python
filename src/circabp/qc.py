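"""Quality control: artifact flagging, measurement density, eligibility rules.

Artifact editing follows standard ambulatory-monitoring criteria (the source
study removed artifacts "a priori" without stating rules): physiologic bounds,
systolic > diastolic, and an isolated-spike rule against both close-in-time
neighbours. Eligibility requires >= 48 h of monitoring, adequate nightly
coverage, and post-imputation missingness <= 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Schedule
from .errors import DomainError
from .series import FLAG_ARTIFACT, FLAG_IMPUTED, FLAG_VALID, BPSeries


@dataclass
class QCThresholds:
    sbp_bounds: tuple[float, float] = (60.0, 260.0)
    dbp_bounds: tuple[float, float] = (30.0, 150.0)
    max_step: float = 60.0  # mmHg, spike vs both neighbours
    step_window_minutes: float = 5.0
    min_span_hours: float = 48.0
    night_window: tuple[float, float] = (21.0, 9.0)
    min_night_hours: float = 12.0
    max_missing: float = 0.20
    n_nights: int = 3
    schedule: Schedule = field(default_factory=Schedule)


@dataclass
class QCReport:
    patient_id: str
    density_per_cycle: list[float]
    density_overall: float
    density_raw: float  # valid readings only, before imputation credit
    hours_per_night: list[float]
    span_hours: float
    n_valid: int
    n_artifact: int
    eligible: bool
    exclusion_reasons: list[str]


def flag_artifacts(
    series: BPSeries,
    sbp_bounds: tuple[float, float] = (60.0, 260.0),
    dbp_bounds: tuple[float, float] = (30.0, 150.0),
    max_step: float = 60.0,
    step_window_minutes: float = 5.0,
) -> BPSeries:
    """Return a copy with out-of-bounds / inverted / spiking readings flagged.

    A reading is an artifact if SBP or DBP falls outside physiologic bounds,
    DBP >= SBP, or |delta SBP| > max_step against *both* time-adjacent
    neighbours within ``step_window_minutes``. Flags are a pure function of
    the values, so flagging is idempotent; imputed readings are never
    re-flagged.
    """
    sbp, dbp, t = series.sbp, series.dbp, series.t_hours
    bad = (
        (sbp < sbp_bounds[0])
        | (sbp > sbp_bounds[1])
        | (dbp < dbp_bounds[0])
        | (dbp > dbp_bounds[1])
        | (dbp >= sbp)
    )
    if len(series) >= 3 and max_step > 0:
        w = step_window_minutes / 60.0
        d_prev = np.abs(np.diff(sbp, prepend=sbp[0]))
        d_next = np.abs(np.diff(sbp, append=sbp[-1]))
        dt_prev = np.diff(t, prepend=t[0])
        dt_next = np.diff(t, append=t[-1])
        spike = (
            (d_prev > max_step)
            & (d_next > max_step)
            & (dt_prev <= w)
            & (dt_next <= w)
        )
        spike[0] = spike[-1] = False
        bad |= spike
    flags = series.flags.copy()
    keep_imputed = flags == FLAG_IMPUTED
    flags[~keep_imputed] = np.where(bad[~keep_imputed], FLAG_ARTIFACT, FLAG_VALID)
    return series.with_flags(flags)


def expected_readings(
    schedule: Schedule, source: str, window: tuple[float, float]
) -> int:
    """Nominal number of scheduled readings in [t0, t1) hours since admission."""
    t0, t1 = window
    grid = schedule.grid(source, t1)
    return int(np.sum((grid >= t0) & (grid < t1)))


def measurement_density(
    series: BPSeries,
    window: tuple[float, float],
    schedule: Schedule | None = None,
    include_imputed: bool = False,
) -> float:
    """Fraction of expected scheduled readings present and valid in the window."""
    schedule = schedule or Schedule()
    expected = expected_readings(schedule, series.source, window)
    if expected == 0:
        raise DomainError("no expected readings in window: density undefined")
    ok = series.mask(include_imputed=include_imputed)
    inside = (series.t_hours >= window[0]) & (series.t_hours < window[1])
    return min(1.0, float(np.sum(ok & inside)) / expected)


def night_coverage_hours(series: BPSeries, night_index: int) -> float:
    """Monitored span (h) within the n-th 24-h period after admission.

    The eligibility rule asks for >= 12 h of monitoring per night of stay;
    with overnight monitoring the operational unit is the admission-aligned
    24-h period containing that night. Coverage is the span from first to
    last analysable reading inside the period — continuous monitoring with
    interior gaps still covers the night; interior missingness is accounted
    for by the density criterion.
    """
    w0 = 24.0 * (night_index - 1)
    w1 = w0 + 24.0
    ok = series.mask(include_imputed=True)
    inside = ok & (series.t_hours >= w0) & (series.t_hours <= w1)
    if not inside.any():
        return 0.0
    t = series.t_hours[inside]
    return float(t[-1] - t[0])


def check_eligibility(
    series: BPSeries, thresholds: QCThresholds | None = None
) -> QCReport:
    """Apply the study eligibility rules to a flagged (and imputed) series.

    Exclusion reasons: ``span`` (< 48 h monitored), ``night_coverage`` (any
    night with < 12 h), ``missingness`` (> 20% of expected readings missing
    despite imputation). Decisions depend only on flags and coverage, never on
    the BP values themselves.
    """
    th = thresholds or QCThresholds()
    reasons: list[str] = []
    span = series.span_hours
    if span < th.min_span_hours:
        reasons.append("span")
    hours = [
        night_coverage_hours(series, n) for n in range(1, th.n_nights + 1)
    ]
    if any(h < th.min_night_hours for h in hours):
        reasons.append("night_coverage")
    densities = []
    for c in range(th.n_nights):
        w = (24.0 * c, 24.0 * (c + 1))
        if w[0] >= span:
            break
        densities.append(
            measurement_density(series, w, th.schedule, include_imputed=True)
        )
    full_window = (0.0, float(series.t_hours[-1]) + 1e-9)
    overall = measurement_density(series, full_window, th.schedule,
                                  include_imputed=True)
    raw = measurement_density(series, full_window, th.schedule,
                              include_imputed=False)
    if 1.0 - overall > th.max_missing:
        reasons.append("missingness")
    ok = series.mask(include_imputed=False)
    return QCReport(
        patient_id=series.patient_id,
        density_per_cycle=densities,
        density_overall=overall,
        density_raw=raw,
        hours_per_night=hours,
        span_hours=span,
        n_valid=int(ok.sum()),
        n_artifact=int(np.sum(series.flags == FLAG_ARTIFACT)),
        eligible=not reasons,
        exclusion_reasons=reasons,
    )
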
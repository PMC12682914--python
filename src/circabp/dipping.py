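"""Nocturnal dipping: day/night means, percent decline, and dipper categories.

Nocturnal decline (%) = 100 * (daytime mean SBP - nighttime mean SBP) / daytime
mean SBP, computed by default from the cosinor-fitted curve (analytic window
integrals of the fitted cosine) rather than raw readings, to reduce the
influence of short-term variability. Categories follow ambulatory-monitoring
convention: reverse-dipper (nocturnal rise), non-dipper (< 10% decline),
dipper (>= 10% and < 20%), extreme-dipper (>= 20%, collapsible into dipper).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

OMEGA = 2.0 * np.pi / 24.0

REVERSE = "reverse-dipper"
NON_DIPPER = "non-dipper"
DIPPER = "dipper"
EXTREME = "extreme-dipper"
CATEGORIES = (REVERSE, NON_DIPPER, DIPPER, EXTREME)

DEFAULT_DAY = (9.0, 21.0)
DEFAULT_NIGHT = (21.0, 9.0)


def unwrap_window(window: tuple[float, float]) -> tuple[float, float]:
    """Return (w0, w1) with w1 > w0, unwrapping windows that cross midnight."""
    w0, w1 = float(window[0]), float(window[1])
    if w1 <= w0:
        w1 += 24.0
    return w0, w1


def cosine_window_mean(
    mesor: float, amplitude: float, acrophase: float, window: tuple[float, float]
) -> float:
    """Exact mean of M + A*cos(omega*(t - phi)) over a clock window.

    The antiderivative gives mean = M + A * (sin(w*(t1-phi)) - sin(w*(t0-phi)))
    / (w * (t1 - t0)); windows crossing midnight are unwrapped.
    """
    w0, w1 = unwrap_window(window)
    span = w1 - w0
    if span <= 0:
        raise DomainError("window must have positive length")
    s = np.sin(OMEGA * (w1 - acrophase)) - np.sin(OMEGA * (w0 - acrophase))
    return float(mesor + amplitude * s / (OMEGA * span))


def in_clock_window(clock_hours: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of clock hours lying in a (possibly wrapping) window."""
    w0, w1 = float(window[0]), float(window[1])
    h = np.asarray(clock_hours, dtype=float) % 24.0
    if w1 > w0:
        return (h >= w0) & (h < w1)
    return (h >= w0) | (h < w1)


def day_night_means(
    fit_or_series,
    day_window: tuple[float, float] = DEFAULT_DAY,
    night_window: tuple[float, float] = DEFAULT_NIGHT,
    basis: str = "cosinor-fitted",
    cycle_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Daytime and nighttime mean SBP for one 24-h cycle.

    ``basis="cosinor-fitted"`` expects a fitted cosinor result (anything with
    ``mesor``, ``amplitude`` and ``acrophase`` attributes) and evaluates the
    closed-form window integrals of the fitted curve. ``basis="raw-means"``
    expects a :class:`~circabp.series.BPSeries` and averages valid + imputed
    readings falling in each clock window (restricted to ``cycle_window``
    hours since admission when given).
    """
    _check_windows(day_window, night_window)
    if basis == "cosinor-fitted":
        fit = fit_or_series
        amp = fit.amplitude
        # a zero-amplitude fit has undefined acrophase; the window mean is M
        phi = fit.acrophase if amp > 0 and fit.acrophase is not None else 0.0
        if phi is None or (isinstance(phi, float) and np.isnan(phi)):
            phi = 0.0
        day = cosine_window_mean(fit.mesor, amp, phi, day_window)
        night = cosine_window_mean(fit.mesor, amp, phi, night_window)
        return day, night
    if basis == "raw-means":
        series = fit_or_series
        ok = series.mask(include_imputed=True)
        if cycle_window is not None:
            ok &= (series.t_hours >= cycle_window[0]) & (
                series.t_hours < cycle_window[1]
            )
        clock = series.clock_hours
        day_mask = ok & in_clock_window(clock, day_window)
        night_mask = ok & in_clock_window(clock, night_window)
        if night_mask.sum() == 0:
            raise InsufficientDataError("no night readings for raw-means basis")
        if day_mask.sum() == 0:
            raise InsufficientDataError("no day readings for raw-means basis")
        return float(series.sbp[day_mask].mean()), float(series.sbp[night_mask].mean())
    raise DomainError(f"unknown basis {basis!r}")


def _check_windows(day_window, night_window) -> None:
    d0, d1 = unwrap_window(day_window)
    n0, n1 = unwrap_window(night_window)
    if (d1 - d0) + (n1 - n0) > 24.0 + 1e-9:
        raise DomainError("day and night windows must jointly cover <= 24 h")


def nocturnal_decline(day_mean: float, night_mean: float) -> float:
    """Percent nocturnal decline; negative when night exceeds day."""
    if day_mean <= 0:
        raise DomainError("daytime mean must be positive")
    return 100.0 * (day_mean - night_mean) / day_mean


def classify_dipping(decline_pct: float, collapse_extreme: bool = False) -> str:
    """Map percent decline to a dipping category (breakpoints 0, 10, 20)."""
    d = float(decline_pct)
    if np.isnan(d):
        raise DomainError("decline is NaN")
    if d < 0:
        return REVERSE
    if d < 10:
        return NON_DIPPER
    if d < 20 or collapse_extreme:
        return DIPPER
    return EXTREME


@dataclass
class DippingResult:
    """Dipping classification for one patient-night."""

    patient_id: str
    night_index: int
    daytime_mean_sbp: float
    nighttime_mean_sbp: float
    decline_pct: float
    category: str
    basis: str = "cosinor-fitted"


def dipping_result(
    fit_or_series,
    patient_id: str,
    night_index: int,
    day_window=DEFAULT_DAY,
    night_window=DEFAULT_NIGHT,
    basis: str = "cosinor-fitted",
    cycle_window=None,
    collapse_extreme: bool = False,
) -> DippingResult:
    day, night = day_night_means(
        fit_or_series, day_window, night_window, basis, cycle_window
    )
    decline = nocturnal_decline(day, night)
    return DippingResult(
        patient_id=patient_id,
        night_index=night_index,
        daytime_mean_sbp=day,
        nighttime_mean_sbp=night,
        decline_pct=decline,
        category=classify_dipping(decline, collapse_extreme),
        basis=basis,
    )


def dipping_prevalence(
    categories,
    night_index: int | None = None,
    denominator: int | None = None,
    ndigits: int = 1,
) -> pd.DataFrame:
    """Counts and percentages per dipping category for one night.

    ``categories`` is either a sequence of category labels or a mapping
    ``{category: count}``. The default denominator is the number of classified
    patients; published tables occasionally use the cohort denominator
    instead, so an explicit ``denominator`` may be supplied.
    """
    if isinstance(categories, dict):
        counts = {c: int(categories.get(c, 0)) for c in categories}
    else:
        labels = pd.Series(list(categories))
        if labels.empty:
            raise InsufficientDataError("no classified patients")
        counts = labels.value_counts().to_dict()
    total = denominator if denominator is not None else sum(counts.values())
    if total <= 0:
        raise InsufficientDataError("prevalence denominator must be positive")
    rows = []
    for cat, n in counts.items():
        pct = 100.0 * n / total
        rows.append(
            {
                "night_index": night_index,
                "category": cat,
                "count": n,
                "pct": pct,
                "pct_rounded": round(pct, ndigits),
            }
        )
    return pd.DataFrame(rows)
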
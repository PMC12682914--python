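"""Single-component 24-h cosinor regression and cohort rhythm summaries.

The model is ordinary least squares on the linearised cosinor,

    y = M + beta * cos(omega t) + gamma * sin(omega t),   omega = 2*pi/24,

with t the wall-clock hour, so the derived acrophase is directly a clock time:
amplitude A = sqrt(beta^2 + gamma^2) and acrophase = atan2(gamma, beta)/omega
(mod 24), the clock time at which the fitted curve peaks. MESOR is the
rhythm-adjusted mean M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitRefusedError, InsufficientDataError
from .series import BPSeries

OMEGA = 2.0 * np.pi / 24.0
#: amplitudes below this are treated as zero (acrophase undefined)
AMPLITUDE_TOL = 1e-9


class Cosinor:
    """24-h cosinor model for one series of (clock hour, value) pairs.

    Weighted least squares when ``weights`` is given (used to down-weight
    imputed readings in sensitivity analyses).
    """

    def __init__(self, y, t_clock, weights=None):
        self.y = np.asarray(y, dtype=float)
        self.t = np.asarray(t_clock, dtype=float)
        if self.y.shape != self.t.shape:
            raise ValueError("y and t_clock must have equal length")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def design(self) -> np.ndarray:
        return np.column_stack(
            [np.ones_like(self.t), np.cos(OMEGA * self.t), np.sin(OMEGA * self.t)]
        )

    def fit(self) -> "CosinorResults":
        if self.y.size < 4:
            raise InsufficientDataError("cosinor needs >= 4 points")
        X = self.design()
        y = self.y
        if self.weights is not None:
            sw = np.sqrt(self.weights)
            Xw, yw = X * sw[:, None], y * sw
        else:
            Xw, yw = X, y
        coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < 3:
            raise FitRefusedError(
                "collinear_design", "cosinor design matrix is rank deficient"
            )
        resid = y - X @ coef
        dof = y.size - 3
        if self.weights is not None:
            sse = float(np.sum(self.weights * resid**2))
        else:
            sse = float(np.sum(resid**2))
        sigma2 = sse / dof if dof > 0 else np.nan
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        cov = sigma2 * XtX_inv
        return CosinorResults(self, coef, cov, resid, sse)


class CosinorResults:
    """Fitted cosinor: MESOR, amplitude, acrophase and OLS diagnostics."""

    def __init__(self, model: Cosinor, coef, cov, resid, sse):
        self.model = model
        self.mesor, self.beta, self.gamma = (float(c) for c in coef)
        self.cov_params = cov
        self.resid = resid
        self.sse = sse
        self.nobs = int(model.y.size)

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta, self.gamma))

    @property
    def acrophase(self) -> float:
        """Clock time of the fitted peak in [0, 24); NaN when amplitude ~ 0."""
        if self.amplitude < AMPLITUDE_TOL:
            return float("nan")
        return float((np.arctan2(self.gamma, self.beta) / OMEGA) % 24.0)

    @property
    def r2(self) -> float:
        sst = float(np.sum((self.model.y - self.model.y.mean()) ** 2))
        if sst <= 0:
            return 0.0
        return max(0.0, 1.0 - self.sse / sst)

    @property
    def se_mesor(self) -> float:
        return float(np.sqrt(self.cov_params[0, 0]))

    @property
    def se_amplitude(self) -> float:
        """Delta-method SE of sqrt(beta^2 + gamma^2)."""
        a = self.amplitude
        if a < AMPLITUDE_TOL:
            return float(np.sqrt(0.5 * (self.cov_params[1, 1] + self.cov_params[2, 2])))
        g = np.array([0.0, self.beta / a, self.gamma / a])
        return float(np.sqrt(g @ self.cov_params @ g))

    def predict(self, t_clock) -> np.ndarray:
        t = np.asarray(t_clock, dtype=float)
        return self.mesor + self.beta * np.cos(OMEGA * t) + self.gamma * np.sin(
            OMEGA * t
        )

    def plot(self, ax=None):
        """Readings and fitted curve over the 24-h clock."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.t % 24.0, self.model.y, s=8, alpha=0.5, label="readings")
        tt = np.linspace(0, 24, 241)
        ax.plot(tt, self.predict(tt), color="C1", label="cosinor fit")
        ax.set_xlabel("clock hour")
        ax.set_ylabel("SBP (mmHg)")
        ax.legend()
        return ax

    def summary(self) -> str:
        acro = self.acrophase
        return (
            "24-h cosinor (OLS)\n"
            f"  n points   : {self.nobs}\n"
            f"  MESOR      : {self.mesor:8.3f} mmHg (SE {self.se_mesor:.3f})\n"
            f"  amplitude  : {self.amplitude:8.3f} mmHg (SE {self.se_amplitude:.3f})\n"
            f"  acrophase  : "
            + ("undefined\n" if np.isnan(acro) else f"{acro:8.3f} h clock\n")
            + f"  R^2        : {self.r2:8.4f}"
        )


@dataclass
class CosinorFit:
    """One patient-by-cycle cosinor fit with window bookkeeping."""

    patient_id: str
    cycle_index: int
    mesor: float
    amplitude: float
    acrophase: float  # NaN when amplitude ~ 0
    beta: float
    gamma: float
    r2: float
    se_mesor: float
    se_amplitude: float
    n_points: int
    coverage_hours: float


def fit_cosinor(
    series: BPSeries,
    cycle_window: tuple[float, float],
    cycle_index: int = 1,
    min_points: int = 24,
    min_span_hours: float = 18.0,
    include_imputed: bool = True,
    imputed_weight: float = 1.0,
) -> CosinorFit:
    """Fit the 24-h cosinor to one admission-aligned 24-h window.

    Raises :class:`FitRefusedError` (reason ``n_points`` or ``coverage``) when
    the window holds too few analysable readings or spans too little time.
    """
    w0, w1 = cycle_window
    if not np.isclose(w1 - w0, 24.0):
        raise ValueError("cycle window must span 24 h")
    ok = series.mask(include_imputed=include_imputed)
    inside = ok & (series.t_hours >= w0) & (series.t_hours < w1)
    n = int(inside.sum())
    if n < min_points:
        raise FitRefusedError("n_points", f"{n} points < minimum {min_points}")
    t_in = series.t_hours[inside]
    coverage = float(t_in[-1] - t_in[0])
    if coverage < min_span_hours:
        raise FitRefusedError(
            "coverage", f"window coverage {coverage:.1f} h < {min_span_hours} h"
        )
    weights = None
    if include_imputed and imputed_weight != 1.0:
        weights = np.where(
            series.flags[inside] == "imputed", imputed_weight, 1.0
        )
    res = Cosinor(series.sbp[inside], series.clock_hours[inside], weights).fit()
    return CosinorFit(
        patient_id=series.patient_id,
        cycle_index=cycle_index,
        mesor=res.mesor,
        amplitude=res.amplitude,
        acrophase=res.acrophase,
        beta=res.beta,
        gamma=res.gamma,
        r2=res.r2,
        se_mesor=res.se_mesor,
        se_amplitude=res.se_amplitude,
        n_points=res.nobs,
        coverage_hours=coverage,
    )


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def circular_mean_hours(hours, period: float = 24.0) -> float:
    """Circular mean of clock hours (NaN-aware)."""
    h = np.asarray(hours, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    ang = 2.0 * np.pi * h / period
    mean = (
        np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        * period
        / (2.0 * np.pi)
    ) % period
    # a tiny negative angle wraps to exactly `period` in floating point
    return 0.0 if mean >= period else float(mean)


def _t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    if x.size < 2:
        return m, float("nan"), float("nan")
    se = float(np.std(x, ddof=1) / np.sqrt(x.size))
    tcrit = stats.t.ppf(0.5 + level / 2.0, x.size - 1)
    return m, m - tcrit * se, m + tcrit * se


@dataclass
class CohortRhythmSummary:
    """Cohort-level rhythm parameters (means and 95% CIs), per group."""

    table: pd.DataFrame

    def __str__(self):
        return self.table.to_string(index=False)


def summarize_cohort_rhythm(
    fits_df: pd.DataFrame,
    grouping: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> CohortRhythmSummary:
    """Arithmetic means + t CIs for MESOR/amplitude and circular mean +
    patient-bootstrap CI for acrophase, per-cycle and pooled per group.

    ``fits_df`` is the frame from :func:`fits_to_frame`; per-patient values
    are first averaged over cycles so each patient contributes once.
    """
    rng = np.random.default_rng(seed)
    groups = (
        [("all", fits_df)]
        if grouping is None
        else list(fits_df.groupby(grouping, sort=True))
    )
    rows = []
    for gname, gdf in groups:
        per_pat = gdf.groupby("patient_id").agg(
            mesor=("mesor", "mean"),
            amplitude=("amplitude", "mean"),
            acrophase=("acrophase", circular_mean_hours),
        )
        n_pat = len(per_pat)
        if n_pat < 2:
            rows.append({"group": gname, "cycle": "pooled", "n": n_pat,
                         "mean_mesor": per_pat["mesor"].mean() if n_pat else np.nan})
            continue
        m_mesor = _t_ci(per_pat["mesor"].to_numpy(), level)
        m_amp = _t_ci(per_pat["amplitude"].to_numpy(), level)
        acro = per_pat["acrophase"].to_numpy()
        acro_mean = circular_mean_hours(acro)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = circular_mean_hours(rng.choice(acro, size=n_pat))
        # CI of circular mean via quantiles of centred angular deviations
        dev = (boots - acro_mean + 12.0) % 24.0 - 12.0
        lo, hi = np.nanquantile(dev, [(1 - level) / 2, 0.5 + level / 2])
        rows.append(
            {
                "group": gname,
                "cycle": "pooled",
                "n": n_pat,
                "mean_mesor": m_mesor[0],
                "mesor_ci_low": m_mesor[1],
                "mesor_ci_high": m_mesor[2],
                "mean_amplitude": m_amp[0],
                "amplitude_ci_low": m_amp[1],
                "amplitude_ci_high": m_amp[2],
                "mean_acrophase": acro_mean,
                "acrophase_ci_low": (acro_mean + lo) % 24.0,
                "acrophase_ci_high": (acro_mean + hi) % 24.0,
            }
        )
        for cyc, cdf in gdf.groupby("cycle_index"):
            m_me = _t_ci(cdf["mesor"].to_numpy(), level)
            m_am = _t_ci(cdf["amplitude"].to_numpy(), level)
            rows.append(
                {
                    "group": gname,
                    "cycle": str(cyc),
                    "n": len(cdf),
                    "mean_mesor": m_me[0],
                    "mesor_ci_low": m_me[1],
                    "mesor_ci_high": m_me[2],
                    "mean_amplitude": m_am[0],
                    "amplitude_ci_low": m_am[1],
                    "amplitude_ci_high": m_am[2],
                    "mean_acrophase": circular_mean_hours(cdf["acrophase"]),
                }
            )
    return CohortRhythmSummary(pd.DataFrame(rows))
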
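"""Local-level state-space model and Kalman gap imputation.

The model is a random-walk level observed with noise,

    level_t = level_{t-dt} + eta,   eta ~ N(0, q * dt)
    y_t     = level_t + eps,        eps ~ N(0, r),

i.e. the innovation variance scales with the (possibly irregular) inter-reading
interval. Variances are estimated by maximum likelihood via the prediction
error decomposition with exact diffuse initialisation (the first observation
is not scored). The fixed-interval (RTS) smoother run on the source's nominal
slot grid supplies interpolants; only interior gaps no longer than
``max_gap_minutes`` are filled, longer gaps stay missing, and observed
readings are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .config import Schedule
from .errors import InsufficientDataError
from .series import FLAG_IMPUTED, FLAG_VALID, BPSeries

VAR_FLOOR = 1e-8  # mmHg^2, keeps the filter non-singular
_LOG2PI = float(np.log(2.0 * np.pi))


def _filter_core(y, dt, q, r):
    """Kalman filter for the local level model; NaN marks a missing slot.

    Returns filtered/predicted means and variances plus the diffuse
    log-likelihood (first observed point excluded).
    """
    n = y.shape[0]
    apred = np.zeros(n)
    Ppred = np.zeros(n)
    att = np.zeros(n)
    Ptt = np.zeros(n)
    loglik = 0.0
    a = 0.0
    P = 0.0
    seen = False
    for i in range(n):
        if seen:
            a_pr = a
            P_pr = P + q * dt[i]
        else:
            a_pr = 0.0
            P_pr = 1e12
        apred[i] = a_pr
        Ppred[i] = P_pr
        yi = y[i]
        if not np.isnan(yi):
            if seen:
                F = P_pr + r
                v = yi - a_pr
                loglik += -0.5 * (_LOG2PI + np.log(F) + v * v / F)
                K = P_pr / F
                a = a_pr + K * v
                P = P_pr * (1.0 - K)
            else:
                # diffuse limit: first observation pins the level
                a = yi
                P = r
                seen = True
        else:
            a = a_pr
            P = P_pr
        att[i] = a
        Ptt[i] = P
    return att, Ptt, apred, Ppred, loglik


def _rts_core(att, Ptt, apred, Ppred):
    """Rauch-Tung-Striebel backward pass (identity transition)."""
    n = att.shape[0]
    ahat = att.copy()
    Vhat = Ptt.copy()
    for i in range(n - 2, -1, -1):
        if Ppred[i + 1] > 0:
            C = Ptt[i] / Ppred[i + 1]
            ahat[i] = att[i] + C * (ahat[i + 1] - apred[i + 1])
            Vhat[i] = Ptt[i] + C * C * (Vhat[i + 1] - Ppred[i + 1])
    return ahat, Vhat


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _filter_core = njit(cache=True)(_filter_core)
    _rts_core = njit(cache=True)(_rts_core)
except Exception:  # pragma: no cover
    pass


@dataclass
class StateSpaceParams:
    """ML variances of the local-level model."""

    level_variance: float  # q, mmHg^2 per hour
    obs_variance: float  # r, mmHg^2
    loglik: float

    def __post_init__(self):
        if self.level_variance < 0 or self.obs_variance < 0:
            raise ValueError("variances must be non-negative")


class LocalLevel:
    """Local-level model on an irregular time grid.

    Parameters
    ----------
    y : array
        Observations; NaN marks missing slots.
    times : array, optional
        Observation times in hours (defaults to a unit grid).
    """

    def __init__(self, y, times=None):
        self.y = np.asarray(y, dtype=float)
        self.times = (
            np.arange(self.y.size, dtype=float)
            if times is None
            else np.asarray(times, dtype=float)
        )
        if self.times.shape != self.y.shape:
            raise ValueError("times and y must have equal length")
        self.dt = np.diff(self.times, prepend=self.times[0] - 1.0)
        self.nobs = int(np.sum(~np.isnan(self.y)))

    def loglike(self, q: float, r: float) -> float:
        return float(
            _filter_core(self.y, self.dt, max(q, VAR_FLOOR), max(r, VAR_FLOOR))[4]
        )

    def fit(self, maxiter: int = 300) -> "LocalLevelResults":
        """Maximum-likelihood fit of (q, r) by Nelder-Mead on the log scale."""
        if self.nobs < 10:
            raise InsufficientDataError(
                f"local-level fit needs >= 10 valid readings, got {self.nobs}"
            )
        obs = self.y[~np.isnan(self.y)]
        d = np.diff(obs)
        v = float(np.var(d)) if d.size else 1.0
        mean_dt = float(np.mean(self.dt[1:])) if self.dt.size > 1 else 1.0
        # var(diff) = 2r + q*dt under the model: split it for the start values
        x0 = np.log(
            [max(v / (3.0 * max(mean_dt, 1e-6)), 1e-6), max(v / 3.0, 1e-6)]
        )

        def nll(x):
            x = np.clip(x, np.log(VAR_FLOOR), np.log(1e8))
            return -self.loglike(np.exp(x[0]), np.exp(x[1]))

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
        x = np.clip(res.x, np.log(VAR_FLOOR), np.log(1e8))
        q, r = float(np.exp(x[0])), float(np.exp(x[1]))
        params = StateSpaceParams(q, r, float(-res.fun))
        return LocalLevelResults(self, params)


class LocalLevelResults:
    """Fitted local-level model; exposes the smoothed state trajectory."""

    def __init__(self, model: LocalLevel, params: StateSpaceParams):
        self.model = model
        self.params = params

    @property
    def loglik(self) -> float:
        return self.params.loglik

    def smooth(self, times=None, y=None) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed level mean and variance, optionally on another grid."""
        if times is None:
            times, y = self.model.times, self.model.y
        else:
            times = np.asarray(times, dtype=float)
            y = np.asarray(y, dtype=float)
        dt = np.diff(times, prepend=times[0] - 1.0)
        att, Ptt, apred, Ppred, _ = _filter_core(
            y, dt, max(self.params.level_variance, VAR_FLOOR),
            max(self.params.obs_variance, VAR_FLOOR),
        )
        return _rts_core(att, Ptt, apred, Ppred)

    def summary(self) -> str:
        p = self.params
        return (
            "Local-level model (random-walk level + observation noise)\n"
            f"  n obs            : {self.model.nobs}\n"
            f"  level variance q : {p.level_variance:.6g} mmHg^2/h\n"
            f"  obs variance r   : {p.obs_variance:.6g} mmHg^2\n"
            f"  log-likelihood   : {p.loglik:.4f}"
        )


def fit_local_level(
    series: BPSeries, field: str = "sbp", max_fit_points: int = 400
) -> StateSpaceParams:
    """ML variances for one patient's valid readings.

    For long invasive traces the fit uses an evenly strided subsample (the
    local-level model is closed under subsampling because the innovation
    variance scales with the interval), capped at ``max_fit_points``.
    """
    ok = series.mask(include_imputed=False)
    y = getattr(series, field)[ok]
    t = series.t_hours[ok]
    if y.size < 10:
        raise InsufficientDataError(
            f"{series.patient_id}: need >= 10 valid readings, got {y.size}"
        )
    if y.size > max_fit_points:
        stride = int(np.ceil(y.size / max_fit_points))
        y, t = y[::stride], t[::stride]
    return LocalLevel(y, t).fit().params


def _slot_observations(series: BPSeries, schedule: Schedule, field: str):
    """Map valid readings onto the nominal slot grid (NaN where absent)."""
    grid = schedule.grid(series.source, float(series.t_hours[-1]) + 1e-9)
    ok = series.mask(include_imputed=False)
    t_obs = series.t_hours[ok]
    v_obs = getattr(series, field)[ok]
    y = np.full(grid.size, np.nan)
    idx = np.clip(np.searchsorted(grid, t_obs), 0, grid.size - 1)
    left = np.clip(idx - 1, 0, grid.size - 1)
    idx = np.where(
        np.abs(grid[left] - t_obs) < np.abs(grid[idx] - t_obs), left, idx
    )
    for j, (slot, val, tt) in enumerate(zip(idx, v_obs, t_obs)):
        half = schedule.interval_hours(series.source, tt) / 2.0
        if abs(grid[slot] - tt) <= half and np.isnan(y[slot]):
            y[slot] = val
    return grid, y


def kalman_impute(
    series: BPSeries,
    params: StateSpaceParams | None = None,
    max_gap_minutes: float = 30.0,
    schedule: Schedule | None = None,
    params_dbp: StateSpaceParams | None = None,
) -> BPSeries:
    """Fill interior gaps <= ``max_gap_minutes`` with RTS-smoothed means.

    Systolic and diastolic series get independently fitted local-level models
    (``params``/``params_dbp``; fitted here when omitted). Artifact-flagged
    readings are treated as missing and dropped from the output; valid
    readings pass through bit-identical with flag ``valid``; imputed slots
    carry flag ``imputed``.
    """
    schedule = schedule or Schedule()
    if params is None:
        params = fit_local_level(series, "sbp")
    if params_dbp is None:
        params_dbp = fit_local_level(series, "dbp")

    grid, y_s = _slot_observations(series, schedule, "sbp")
    _, y_d = _slot_observations(series, schedule, "dbp")
    res_s = LocalLevelResults(LocalLevel(y_s, grid), params)
    res_d = LocalLevelResults(LocalLevel(y_d, grid), params_dbp)
    smooth_s, _ = res_s.smooth()
    smooth_d, _ = res_d.smooth()

    observed = ~np.isnan(y_s)
    obs_idx = np.flatnonzero(observed)
    impute_slots: list[int] = []
    max_gap_h = max_gap_minutes / 60.0
    for a, b in zip(obs_idx[:-1], obs_idx[1:]):
        if b == a + 1:
            continue
        step = schedule.interval_hours(series.source, float(grid[a]))
        gap = float(grid[b] - grid[a]) - step
        if gap <= max_gap_h + 1e-9:
            impute_slots.extend(range(a + 1, b))

    ok = series.mask(include_imputed=False)
    t_new = np.concatenate([series.t_hours[ok], grid[impute_slots]])
    sbp_new = np.concatenate([series.sbp[ok], smooth_s[impute_slots]])
    dbp_new = np.concatenate([series.dbp[ok], smooth_d[impute_slots]])
    flags_new = np.concatenate(
        [
            np.full(int(ok.sum()), FLAG_VALID, dtype=object),
            np.full(len(impute_slots), FLAG_IMPUTED, dtype=object),
        ]
    )
    truth_new = None
    if series.artifact_truth is not None:
        truth_new = np.concatenate(
            [series.artifact_truth[ok], np.zeros(len(impute_slots), dtype=int)]
        )
    order = np.argsort(t_new, kind="mergesort")
    meta = dict(series.meta)
    meta["imputation"] = {
        "sbp": (params.level_variance, params.obs_variance),
        "dbp": (params_dbp.level_variance, params_dbp.obs_variance),
        "n_imputed": len(impute_slots),
    }
    return replace(
        series,
        t_hours=t_new[order],
        sbp=sbp_new[order],
        dbp=dbp_new[order],
        flags=flags_new[order],
        artifact_truth=None if truth_new is None else truth_new[order],
        meta=meta,
    )
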
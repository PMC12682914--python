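"""Multiscale BP feature matrix feeding the phenotype clustering.

Per patient: cosinor parameters for each of the three 24-h cycles (acrophase
entered as a sin/cos pair to respect circularity), nightly nocturnal declines,
dispersion metrics per cycle (SD, CV, average real variability, range), sample
entropy on a common 15-min grid, and a recovery slope
(decline_night3 - decline_night1)/2. Columns are standardised to z-scores
before clustering; the scaler is retained so new patients can be projected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .errors import InsufficientDataError
from .series import BPSeries

logger = logging.getLogger(__name__)

OMEGA = 2.0 * np.pi / 24.0

#: declared column order of the assembled matrix
FEATURE_COLUMNS = tuple(
    [f"mesor_c{c}" for c in (1, 2, 3)]
    + [f"amplitude_c{c}" for c in (1, 2, 3)]
    + [f"acro_sin_c{c}" for c in (1, 2, 3)]
    + [f"acro_cos_c{c}" for c in (1, 2, 3)]
    + [f"decline_n{n}" for n in (1, 2, 3)]
    + [f"sd_sbp_c{c}" for c in (1, 2, 3)]
    + [f"cv_sbp_c{c}" for c in (1, 2, 3)]
    + [f"arv_sbp_c{c}" for c in (1, 2, 3)]
    + [f"range_sbp_c{c}" for c in (1, 2, 3)]
    + ["sample_entropy", "recovery_slope"]
)


def variability_metrics(
    series: BPSeries, window: tuple[float, float], min_points: int = 5
) -> dict:
    """Dispersion metrics of valid+imputed SBP readings in a window.

    SD is the sample standard deviation (n-1); CV = SD/mean; ARV is the mean
    absolute successive difference (order-sensitive); range = max - min.
    """
    ok = series.mask(include_imputed=True)
    inside = ok & (series.t_hours >= window[0]) & (series.t_hours < window[1])
    x = series.sbp[inside]
    if x.size < min_points:
        raise InsufficientDataError(
            f"{series.patient_id}: {x.size} readings < {min_points} in window"
        )
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    return {
        "sd": sd,
        "cv": sd / mean if mean != 0 else np.nan,
        "arv": float(np.mean(np.abs(np.diff(x)))),
        "range": float(np.ptp(x)),
        "n": int(x.size),
    }


def sample_entropy(x, m: int = 2, r: float | None = None, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance, self-matches excluded.

    ``r`` defaults to ``r_frac * SD(x)``. Returns 0.0 for a constant series
    (every template matches) and NaN when no template pairs match.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"sample entropy needs > {m + 1} points")
    sd = float(np.std(x, ddof=1))
    if r is None:
        r = r_frac * sd
    if sd == 0.0:
        return 0.0

    def _count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        iu = np.triu_indices(emb.shape[0], k=1)
        return int(np.sum(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def resample_to_grid(series: BPSeries, step_minutes: float = 15.0) -> np.ndarray:
    """Mean of valid+imputed SBP per fixed-width bin (NaN bins dropped).

    Used so sample entropy is computed at a common effective sampling rate for
    invasive (1-min) and cuff (15/30-min) sources.
    """
    ok = series.mask(include_imputed=True)
    t, v = series.t_hours[ok], series.sbp[ok]
    step = step_minutes / 60.0
    bins = np.floor(t / step).astype(int)
    df = pd.DataFrame({"bin": bins, "v": v}).groupby("bin")["v"].mean()
    return df.to_numpy()


def patient_features(
    series: BPSeries,
    fits: dict[int, "object"],
    declines: dict[int, float],
    n_cycles: int = 3,
) -> dict:
    """Assemble one patient's feature dict from per-cycle fits and declines."""
    row: dict = {"patient_id": series.patient_id}
    for c in range(1, n_cycles + 1):
        f = fits.get(c)
        if f is None:
            raise InsufficientDataError(f"{series.patient_id}: missing cycle {c}")
        row[f"mesor_c{c}"] = f.mesor
        row[f"amplitude_c{c}"] = f.amplitude
        phase = 0.0 if np.isnan(f.acrophase) else f.acrophase
        row[f"acro_sin_c{c}"] = np.sin(OMEGA * phase)
        row[f"acro_cos_c{c}"] = np.cos(OMEGA * phase)
        row[f"decline_n{c}"] = declines[c]
        vm = variability_metrics(series, (24.0 * (c - 1), 24.0 * c))
        row[f"sd_sbp_c{c}"] = vm["sd"]
        row[f"cv_sbp_c{c}"] = vm["cv"]
        row[f"arv_sbp_c{c}"] = vm["arv"]
        row[f"range_sbp_c{c}"] = vm["range"]
    row["sample_entropy"] = sample_entropy(resample_to_grid(series))
    row["recovery_slope"] = (row["decline_n3"] - row["decline_n1"]) / 2.0
    return row


def assemble_features(
    fits_df: pd.DataFrame,
    dipping_df: pd.DataFrame,
    series_list,
    n_cycles: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the patient-by-feature matrix; patients missing any cycle are
    excluded and listed.

    ``fits_df`` carries one row per patient-cycle (from ``fits_to_frame``),
    ``dipping_df`` one row per patient-night with ``decline_pct``.
    """
    by_id = {s.patient_id: s for s in series_list}
    rows, excluded = [], []
    for pid, g in fits_df.groupby("patient_id", sort=True):
        cycles = set(g["cycle_index"])
        nights = dipping_df[dipping_df["patient_id"] == pid]
        have_nights = set(nights["night_index"])
        if (
            cycles < set(range(1, n_cycles + 1))
            or have_nights < set(range(1, n_cycles + 1))
            or pid not in by_id
        ):
            excluded.append(pid)
            continue
        fits = {
            int(r.cycle_index): r for r in g.itertuples(index=False)
        }
        declines = dict(zip(nights["night_index"], nights["decline_pct"]))
        try:
            rows.append(patient_features(by_id[pid], fits, declines, n_cycles))
        except InsufficientDataError:
            excluded.append(pid)
    if not rows:
        raise InsufficientDataError("no patient has all cycles: empty feature matrix")
    mat = pd.DataFrame(rows).set_index("patient_id")[list(FEATURE_COLUMNS)]
    # completeness filter: entropy can be NaN on degenerate series
    bad = mat.index[mat.isna().any(axis=1)].tolist()
    if bad:
        excluded.extend(bad)
        mat = mat.dropna()
    return mat, excluded


@dataclass
class Scaler:
    """Stored per-column standardisation (population SD, zero-variance dropped)."""

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.columns].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.mean) / self.scale, index=df.index, columns=self.columns
        )

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.mean


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Z-score every column; zero-variance columns are dropped with a warning."""
    if len(matrix) < 2:
        raise InsufficientDataError("standardization needs >= 2 rows")
    variances = matrix.var(axis=0, ddof=0)
    keep = variances[variances > 0].index.tolist()
    dropped = [c for c in matrix.columns if c not in keep]
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
    sc = StandardScaler().fit(matrix[keep].to_numpy(dtype=float))
    scaler = Scaler(columns=keep, mean=sc.mean_, scale=sc.scale_)
    return scaler.transform(matrix), scaler
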
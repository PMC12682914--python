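"""Synthetic acute-stroke BP cohort generator.

Each patient draws rhythm parameters (MESOR, amplitude, acrophase) from one of
three circadian phenotype archetypes and emits a >= 72 h systolic/diastolic
trace on an invasive (1-min) or cuff (15-min, then 30-min) schedule:

    SBP(t) = MESOR + A * cos(2*pi*(clock(t) - acrophase)/24)
             + offset_c * 1[night]  + AR(1) residual,

where ``offset_c`` is a per-cycle night-window shift that encodes the
archetype's dipping target and its night-1 -> night-3 trajectory drift.
Missing runs come from a renewal gap process (so runs never overlap and never
exceed the configured maximum) and artifacts replace readings with values
outside physiologic bounds, tagged in the ground truth. Covariates and binary
outcomes are drawn from configurable per-phenotype logistic models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    OUTCOMES,
    PHENOTYPES,
    ArchetypeSpec,
    CohortConfig,
    GapProcess,
    Schedule,
)
from .dipping import cosine_window_mean, in_clock_window, unwrap_window
from .errors import ConfigurationError
from .series import SOURCE_CUFF, SOURCE_INVASIVE, BPSeries

_BASE_ADMISSION = pd.Timestamp("2024-01-01 00:00:00")

# artifact draws fall outside these (QC-detectable by construction)
_ARTIFACT_HIGH = (265.0, 320.0)
_ARTIFACT_LOW = (25.0, 55.0)


def solve_night_offset(
    archetype: ArchetypeSpec,
    day_window=(9.0, 21.0),
    night_window=(21.0, 9.0),
) -> float:
    """Night-window offset making the archetype-mean trace hit dipping_target.

    With day mean D = M + A*c_day and night mean N = M + A*c_night + offset,
    decline == target requires offset = D*(1 - target/100) - M - A*c_night.
    """
    if archetype.dipping_target is None:
        return 0.0
    m, a, phi = archetype.mesor_mean, archetype.amplitude_mean, archetype.acrophase_mean
    day = cosine_window_mean(m, a, phi, day_window)
    night_cos = cosine_window_mean(m, a, phi, night_window)
    return day * (1.0 - archetype.dipping_target / 100.0) - night_cos


def cycle_night_offsets(
    archetype: ArchetypeSpec, n_cycles: int = 3, day_window=(9.0, 21.0),
    night_window=(21.0, 9.0),
) -> np.ndarray:
    """Per-cycle night offsets: base (from dipping_target) plus recovery drift."""
    base = solve_night_offset(archetype, day_window, night_window)
    mid = (n_cycles - 1) / 2.0
    drift = -(np.arange(n_cycles) - mid) * archetype.night_delta_per_cycle
    return base + drift


def expected_decline(
    archetype: ArchetypeSpec, cycle: int = 1, day_window=(9.0, 21.0),
    night_window=(21.0, 9.0), n_cycles: int = 3,
) -> float:
    """Closed-form nocturnal decline (%) of the archetype-mean trace, cycle 1..n."""
    m, a, phi = archetype.mesor_mean, archetype.amplitude_mean, archetype.acrophase_mean
    offsets = cycle_night_offsets(archetype, n_cycles, day_window, night_window)
    day = cosine_window_mean(m, a, phi, day_window)
    night = cosine_window_mean(m, a, phi, night_window) + offsets[cycle - 1]
    return 100.0 * (day - night) / day


def _draw_gaps(
    rng, duration: float, gp: GapProcess, rate: float, guard: float = 0.0
) -> list[tuple[float, float]]:
    """Renewal gap process: exponential waits between non-overlapping runs.

    ``guard`` (hours) keeps at least one scheduled reading between successive
    runs, so no injected missing run ever exceeds the configured maximum.
    """
    gaps = []
    if rate <= 0:
        return gaps
    t = float(rng.exponential(1.0 / rate))
    while t < duration:
        dur = float(
            np.clip(
                rng.exponential(gp.mean_minutes / 60.0),
                gp.min_minutes / 60.0,
                gp.max_minutes / 60.0,
            )
        )
        gaps.append((t, min(t + dur, duration)))
        t = t + dur + guard + float(rng.exponential(1.0 / rate))
    return gaps


def _ar1_noise(rng, n: int, sd: float, ar: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = sd * z[0]
    scale = sd * np.sqrt(1.0 - ar * ar)
    for i in range(1, n):
        e[i] = ar * e[i - 1] + scale * z[i]
    return e


def draw_patient_params(archetype: ArchetypeSpec, rng) -> dict:
    """Per-patient rhythm parameters drawn around the archetype centres."""
    mesor = float(rng.normal(archetype.mesor_mean, archetype.mesor_sd))
    amplitude = float(
        max(0.0, rng.normal(archetype.amplitude_mean, archetype.amplitude_sd))
    )
    acrophase = float(
        (rng.normal(archetype.acrophase_mean, archetype.acrophase_sd)) % 24.0
    )
    return {"mesor": mesor, "amplitude": amplitude, "acrophase": acrophase}


def generate_bp_trace(
    archetype: ArchetypeSpec,
    schedule: Schedule,
    seed,
    *,
    source: str = SOURCE_CUFF,
    patient_id: str = "P0000",
    admission: pd.Timestamp | None = None,
    duration_hours: float = 72.0,
    gap_process: GapProcess | None = None,
    gap_rate: float | None = None,
    artifact_rate: float = 0.0,
    day_window=(9.0, 21.0),
    night_window=(21.0, 9.0),
    n_cycles: int = 3,
    params: dict | None = None,
) -> BPSeries:
    """Simulate one patient's BP series from an archetype on a schedule.

    ``seed`` may be an int or an already-constructed numpy Generator. The
    drawn rhythm parameters and per-cycle night offsets are recorded in
    ``series.meta``.
    """
    archetype.validate()
    if source not in (SOURCE_CUFF, SOURCE_INVASIVE):
        raise ConfigurationError(f"unknown source {source!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if admission is None:
        admission = _BASE_ADMISSION
    grid = schedule.grid(source, duration_hours)
    if grid.size == 0:
        raise ConfigurationError("empty sampling schedule")

    p = params if params is not None else draw_patient_params(archetype, rng)
    offsets = cycle_night_offsets(archetype, n_cycles, day_window, night_window)

    start_clock = admission.hour + admission.minute / 60.0 + admission.second / 3600.0
    clock = (start_clock + grid) % 24.0
    cycle_idx = np.minimum((grid // 24.0).astype(int), n_cycles - 1)
    night = in_clock_window(clock, night_window)
    signal = (
        p["mesor"]
        + p["amplitude"] * np.cos(2.0 * np.pi / 24.0 * (clock - p["acrophase"]))
        + np.where(night, offsets[cycle_idx], 0.0)
    )
    sbp = signal + _ar1_noise(rng, grid.size, archetype.noise_sd, archetype.ar_coef)
    # diastolic: proportional waveform with its own residual, kept below SBP
    dbp = 0.62 * signal + _ar1_noise(rng, grid.size, 0.6 * archetype.noise_sd,
                                     archetype.ar_coef)
    dbp = np.minimum(dbp, sbp - 5.0)

    # gap process: drop readings inside missing runs (first reading always kept,
    # anchoring the admission time in the written file)
    keep = np.ones(grid.size, dtype=bool)
    if gap_process is not None:
        rate = gap_rate if gap_rate is not None else gap_process.rate_per_hour
        guard = (
            schedule.invasive_interval_min
            if source == SOURCE_INVASIVE
            else max(schedule.cuff_interval_first24_min,
                     schedule.cuff_interval_late_min)
        ) / 60.0 + 1e-3
        for g0, g1 in _draw_gaps(rng, duration_hours, gap_process, rate, guard):
            keep &= ~((grid > g0) & (grid < g1))
        keep[0] = True

    t = grid[keep]
    sbp, dbp = sbp[keep], dbp[keep]
    truth = np.zeros(t.size, dtype=int)
    if artifact_rate > 0:
        hit = rng.uniform(size=t.size) < artifact_rate
        side_high = rng.uniform(size=t.size) < 0.5
        lo = rng.uniform(*_ARTIFACT_LOW, size=t.size)
        hi = rng.uniform(*_ARTIFACT_HIGH, size=t.size)
        sbp = np.where(hit, np.where(side_high, hi, lo), sbp)
        dbp = np.where(hit, 0.65 * sbp, dbp)
        truth = hit.astype(int)

    return BPSeries(
        patient_id=patient_id,
        start=admission,
        t_hours=t,
        sbp=sbp,
        dbp=dbp,
        source=source,
        artifact_truth=truth,
        meta={
            **p,
            "archetype": archetype.name,
            "night_offsets": offsets.tolist(),
            "noise_sd": archetype.noise_sd,
        },
    )


def _trace_duration(start_clock: float, night_window, n_cycles: int) -> float:
    """Span long enough to cover n_cycles full clock-nights after admission."""
    n0, n1 = unwrap_window(night_window)
    first_night_start = (n0 - start_clock) % 24.0
    night_len = n1 - n0
    return max(24.0 * n_cycles, first_night_start + 24.0 * (n_cycles - 1) + night_len)


def _covariates(rng, pheno_idx: np.ndarray) -> pd.DataFrame:
    """Per-phenotype covariate distributions (Steady-High, Disrupted, Partial)."""
    n = pheno_idx.size
    age_mu = np.array([76.0, 70.0, 68.0])[pheno_idx]
    age = np.clip(rng.normal(age_mu, 9.5), 20, 99).round(1)
    female = rng.uniform(size=n) < np.array([0.46, 0.40, 0.44])[pheno_idx]
    hyper = rng.uniform(size=n) < np.array([0.81, 0.71, 0.69])[pheno_idx]
    diab = rng.uniform(size=n) < np.array([0.33, 0.26, 0.22])[pheno_idx]
    af = rng.uniform(size=n) < np.array([0.27, 0.21, 0.20])[pheno_idx]
    ckd = rng.uniform(size=n) < np.array([0.35, 0.31, 0.15])[pheno_idx]
    nihss_med = np.array([10.0, 8.0, 6.0])[pheno_idx]
    nihss = np.clip(
        np.round(np.exp(rng.normal(np.log(nihss_med), 0.55))), 0, 42
    ).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "sex_female": female.astype(int),
            "hypertension": hyper.astype(int),
            "diabetes": diab.astype(int),
            "af": af.astype(int),
            "ckd": ckd.astype(int),
            "nihss0": nihss,
        }
    )


def simulate_cohort_table(
    config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Covariate/outcome table only (no BP traces); for outcome-model studies.

    Uses its own random stream, so it is not row-identical to the table from
    :func:`generate_cohort` at the same seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    k = len(config.archetypes)
    pheno_idx = rng.choice(k, size=n, p=np.asarray(config.mixture_weights))
    cov = _covariates(rng, pheno_idx)
    cov.insert(0, "patient_id", [f"P{i:04d}" for i in range(n)])
    cov["true_phenotype"] = [config.archetypes[j].name for j in pheno_idx]
    for outcome in OUTCOMES:
        eta = config.outcome_model.linear_predictor(outcome, pheno_idx, cov)
        cov[outcome] = (rng.uniform(size=n) < expit(eta)).astype(int)
    mace = cov["mace12"].to_numpy(dtype=bool)
    cov["mace_months"] = np.round(
        np.where(mace, rng.uniform(0.5, 12.0, size=n), 12.0), 3
    )
    return cov


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[BPSeries], pd.DataFrame, pd.DataFrame]:
    """Generate BP series, a covariate/outcome table and a truth table.

    Returns ``(series_list, cohort, truth)`` where ``cohort`` holds covariates
    and outcomes (one row per patient) and ``truth`` the hidden phenotype and
    rhythm parameters. Identical ``(config, seed)`` give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    k = len(config.archetypes)
    if n < k + 1:
        raise ConfigurationError("n_patients must exceed the number of archetypes")

    pheno_idx = rng.choice(k, size=n, p=np.asarray(config.mixture_weights))
    invasive = rng.uniform(size=n) < config.invasive_fraction
    admit_offset_h = rng.uniform(0.0, 24.0 * 30.0, size=n)
    gap_rates = rng.gamma(
        config.gap_process.rate_shape,
        config.gap_process.rate_per_hour / config.gap_process.rate_shape,
        size=n,
    )

    series_list: list[BPSeries] = []
    truth_rows = []
    for i in range(n):
        arch = config.archetypes[pheno_idx[i]]
        pid = f"P{i:04d}"
        admission = _BASE_ADMISSION + pd.to_timedelta(
            round(admit_offset_h[i] * 60.0), unit="min"
        )
        start_clock = admission.hour + admission.minute / 60.0
        duration = _trace_duration(start_clock, config.night_window, config.n_cycles)
        source = SOURCE_INVASIVE if invasive[i] else SOURCE_CUFF
        series = generate_bp_trace(
            arch,
            config.schedule,
            rng,
            source=source,
            patient_id=pid,
            admission=admission,
            duration_hours=duration,
            gap_process=config.gap_process,
            gap_rate=float(gap_rates[i]),
            artifact_rate=config.artifact_rate,
            day_window=config.day_window,
            night_window=config.night_window,
            n_cycles=config.n_cycles,
        )
        series_list.append(series)
        truth_rows.append(
            {
                "patient_id": pid,
                "true_phenotype": arch.name,
                "mesor": series.meta["mesor"],
                "amplitude": series.meta["amplitude"],
                "acrophase": series.meta["acrophase"],
                "night_offsets": series.meta["night_offsets"],
                "source": source,
                "n_artifacts": int(series.artifact_truth.sum()),
                "gap_rate": float(gap_rates[i]),
            }
        )
    truth = pd.DataFrame(truth_rows)

    cov = _covariates(rng, pheno_idx)
    cov.insert(0, "patient_id", truth["patient_id"])
    outcomes = {}
    for outcome in OUTCOMES:
        eta = config.outcome_model.linear_predictor(outcome, pheno_idx, cov)
        outcomes[outcome] = (rng.uniform(size=n) < expit(eta)).astype(int)
    cohort = cov.copy()
    cohort["true_phenotype"] = truth["true_phenotype"]
    for outcome in OUTCOMES:
        cohort[outcome] = outcomes[outcome]
    # MACE event time in months: events uniform over follow-up, else censored at 12
    mace = outcomes["mace12"].astype(bool)
    t_mace = np.where(mace, rng.uniform(0.5, 12.0, size=n), 12.0)
    cohort["mace_months"] = np.round(t_mace, 3)
    return series_list, cohort, truth
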
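import numpy as np
import pandas as pd
import pytest

from circabp.config import ArchetypeSpec, CohortConfig, Schedule
from circabp.pipeline import process_series
from circabp.simulate import generate_bp_trace, generate_cohort


def noiseless_archetype(
    mesor=120.0, amplitude=10.0, acrophase=4.0, dipping_target=None, delta=0.0
) -> ArchetypeSpec:
    """Archetype with all dispersion and noise switched off."""
    return ArchetypeSpec(
        name="Steady-High",
        mesor_mean=mesor,
        mesor_sd=0.0,
        amplitude_mean=amplitude,
        amplitude_sd=0.0,
        acrophase_mean=acrophase,
        acrophase_sd=0.0,
        noise_sd=0.0,
        night_delta_per_cycle=delta,
        dipping_target=dipping_target,
        ar_coef=0.0,
    )


def make_series(t_hours, sbp, dbp=None, source="cuff", start="2024-01-01 00:00"):
    from circabp.series import BPSeries

    sbp = np.asarray(sbp, dtype=float)
    if dbp is None:
        dbp = sbp * 0.6
    return BPSeries(
        patient_id="T001",
        start=pd.Timestamp(start),
        t_hours=np.asarray(t_hours, dtype=float),
        sbp=sbp,
        dbp=np.asarray(dbp, dtype=float),
        source=source,
    )


@pytest.fixture(scope="session")
def schedule():
    return Schedule()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=80, seed=11)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    series, cohort, truth = small_cohort
    return process_series(series)


@pytest.fixture(scope="session")
def clean_trace(schedule):
    """Noiseless, gap-free 72-h cuff trace (admitted at midnight)."""
    return generate_bp_trace(
        noiseless_archetype(), schedule, seed=0, duration_hours=72.0
    )
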
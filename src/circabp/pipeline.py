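"""End-to-end orchestration: QC -> imputation -> cosinor -> dipping ->
features -> phenotyping, plus helpers to join phenotypes onto a cohort table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dipping as dip
from .cosinor import fit_cosinor, fits_to_frame
from .errors import FitRefusedError, InsufficientDataError
from .features import Scaler, assemble_features, standardize
from .kalman import kalman_impute
from .phenotyping import (
    PhenotypeLabeling,
    PhenotypeResults,
    StabilityReport,
    assign_labels,
    bootstrap_stability,
    fit_mixture,
    select_k,
)
from .qc import QCThresholds, check_eligibility, flag_artifacts

logger = logging.getLogger(__name__)


@dataclass
class ProcessedCohort:
    """Per-patient products of the measurement pipeline."""

    series: list
    qc: pd.DataFrame
    fits: pd.DataFrame
    dipping: pd.DataFrame
    features: pd.DataFrame
    features_std: pd.DataFrame
    scaler: Scaler
    excluded: dict[str, list] = field(default_factory=dict)


def process_series(
    series_list,
    thresholds: QCThresholds | None = None,
    impute: bool = True,
    max_gap_minutes: float = 30.0,
    day_window=(9.0, 21.0),
    night_window=(21.0, 9.0),
    n_cycles: int = 3,
    min_points: int = 24,
    min_span_hours: float = 18.0,
) -> ProcessedCohort:
    """Run QC, gap imputation, cosinor fits and dipping classification.

    Patients failing eligibility, or missing any complete cycle, are excluded
    (and listed). Returns the standardized feature matrix ready to cluster.
    """
    th = thresholds or QCThresholds(night_window=night_window)
    processed = []
    qc_rows = []
    excluded: dict[str, list] = {"ineligible": [], "incomplete": []}
    for s in series_list:
        s = flag_artifacts(
            s, th.sbp_bounds, th.dbp_bounds, th.max_step, th.step_window_minutes
        )
        if impute:
            try:
                s = kalman_impute(
                    s, max_gap_minutes=max_gap_minutes, schedule=th.schedule
                )
            except InsufficientDataError:
                pass  # too few readings to fit; eligibility will reject below
        report = check_eligibility(s, th)
        qc_rows.append(
            {
                "patient_id": s.patient_id,
                "density_overall": report.density_overall,
                "density_raw": report.density_raw,
                "hours_night_min": min(report.hours_per_night)
                if report.hours_per_night
                else 0.0,
                "span_hours": report.span_hours,
                "n_valid": report.n_valid,
                "n_artifact": report.n_artifact,
                "eligible": report.eligible,
                "exclusion_reasons": ";".join(report.exclusion_reasons),
            }
        )
        if not report.eligible:
            excluded["ineligible"].append(s.patient_id)
            continue
        processed.append(s)
    qc_df = pd.DataFrame(qc_rows)

    fit_rows = []
    dip_rows = []
    for s in processed:
        for c in range(1, n_cycles + 1):
            window = (24.0 * (c - 1), 24.0 * c)
            try:
                f = fit_cosinor(
                    s, window, cycle_index=c, min_points=min_points,
                    min_span_hours=min_span_hours,
                )
            except (FitRefusedError, InsufficientDataError) as exc:
                logger.debug("%s cycle %d refused: %s", s.patient_id, c, exc)
                continue
            fit_rows.append(f)
            dip_rows.append(
                dip.dipping_result(
                    f, s.patient_id, night_index=c, day_window=day_window,
                    night_window=night_window,
                )
            )
    fits_df = fits_to_frame(fit_rows) if fit_rows else pd.DataFrame(
        columns=["patient_id", "cycle_index"]
    )
    dip_df = (
        pd.DataFrame([vars(d) for d in dip_rows])
        if dip_rows
        else pd.DataFrame(columns=["patient_id", "night_index", "decline_pct"])
    )
    matrix, incomplete = assemble_features(fits_df, dip_df, processed, n_cycles)
    excluded["incomplete"] = incomplete
    z, scaler = standardize(matrix)
    return ProcessedCohort(
        series=processed,
        qc=qc_df,
        fits=fits_df,
        dipping=dip_df,
        features=matrix,
        features_std=z,
        scaler=scaler,
        excluded=excluded,
    )


@dataclass
class PhenotypeAnalysis:
    """Clustering products: selected k, fitted mixture, stability, labels."""

    k: int
    k_table: pd.DataFrame
    result: PhenotypeResults
    labeling: PhenotypeLabeling
    stability: StabilityReport | None
    assignments: pd.DataFrame  # patient_id, cluster, phenotype


def phenotype_cohort(
    processed: ProcessedCohort,
    k: int | None = None,
    k_range=range(2, 7),
    seed: int = 0,
    n_init: int = 10,
    n_bootstrap: int = 0,
) -> PhenotypeAnalysis:
    """Select k (unless fixed), fit the mixture, label clusters, assess stability."""
    z = processed.features_std
    if k is None:
        k, k_table = select_k(z, k_range=k_range, seed=seed, n_init=n_init)
    else:
        k_table = pd.DataFrame({"k": [k], "chosen": [True]})
    result = fit_mixture(z, k, seed=seed, n_init=n_init)
    labeling = assign_labels(result, processed.scaler)
    stability = None
    if n_bootstrap > 0:
        stability = bootstrap_stability(z, result, n_bootstrap=n_bootstrap,
                                        seed=seed + 1)
    assignments = pd.DataFrame(
        {
            "patient_id": result.patient_ids,
            "cluster": result.assignments,
            "phenotype": labeling.apply(result.assignments),
        }
    )
    return PhenotypeAnalysis(
        k=k, k_table=k_table, result=result, labeling=labeling,
        stability=stability, assignments=assignments,
    )


def join_phenotypes(cohort: pd.DataFrame, analysis: PhenotypeAnalysis) -> pd.DataFrame:
    """Inner-join derived phenotypes onto the covariate/outcome table."""
    return cohort.merge(analysis.assignments, on="patient_id", how="inner")


def run_default_study(
    n_patients: int = 500, seed: int = 17, impute: bool = True
) -> tuple[ProcessedCohort, pd.DataFrame, pd.DataFrame]:
    """Generate a default synthetic cohort and run the measurement pipeline.

    Returns (processed, cohort_table, truth_table).
    """
    from .config import CohortConfig
    from .simulate import generate_cohort

    cfg = CohortConfig(n_patients=n_patients, seed=seed)
    series, cohort, truth = generate_cohort(cfg, seed=seed)
    return process_series(series, impute=impute), cohort, truth


def truth_agreement(analysis: PhenotypeAnalysis, truth: pd.DataFrame) -> float:
    """Fraction of patients whose derived label matches the generator truth."""
    merged = analysis.assignments.merge(
        truth[["patient_id", "true_phenotype"]], on="patient_id"
    )
    if merged.empty:
        return float("nan")
    return float((merged["phenotype"] == merged["true_phenotype"]).mean())
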
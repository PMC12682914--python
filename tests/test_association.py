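"""Group tests, corrections, diagnostics, effect sizes, survival, models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circabp.association import (
    adjusted_models,
    bh_fdr,
    bonferroni,
    cohens_h,
    group_test,
    hosmer_lemeshow,
    km_logrank,
    proportion_summary,
    two_prop_ztest,
    vif,
)
from circabp.config import CohortConfig, OutcomeModel, _logit
from circabp.errors import DomainError
from circabp.simulate import simulate_cohort_table


def test_chi2_null_table():
    res = group_test([[10, 10], [10, 10]])
    assert res.method == "chi2"
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_triggered_by_small_expected_counts():
    res = group_test([[1, 9], [8, 2]])  # min expected cell = 4.5
    assert res.method == "fisher"
    assert 0 < res.p_value < 0.05


def test_chi2_matches_hand_formula():
    """Sigma (O-E)^2/E computed directly (in-hospital mortality by phenotype)."""
    table = np.array([[17, 184], [2, 146]])
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    hand = ((table - exp) ** 2 / exp).sum()
    res = group_test(table)
    assert res.method == "chi2"
    assert res.statistic == pytest.approx(hand, rel=1e-12)
    assert res.dof == 1


def test_fisher_mc_for_larger_tables_is_seeded():
    table = [[1, 5, 2], [6, 1, 1], [2, 2, 7]]
    a = group_test(table, mc_draws=2000, seed=3)
    b = group_test(table, mc_draws=2000, seed=3)
    assert a.method == "fisher-mc"
    assert a.p_value == b.p_value
    assert 0 < a.p_value < 1


def test_continuous_paths():
    rng = np.random.default_rng(0)
    groups = [rng.normal(0, 1, 40), rng.normal(2, 1, 40)]
    assert group_test(groups, kind="continuous", normal=True).method == "anova"
    res = group_test(groups, kind="continuous")
    assert res.method == "kruskal" and res.p_value < 1e-6


def test_degenerate_table_rejected():
    with pytest.raises(DomainError):
        group_test([[0, 0], [3, 4]])


def test_bonferroni_examples():
    np.testing.assert_allclose(bonferroni([0.01], m=3), [0.03])
    np.testing.assert_allclose(bonferroni([0.5], m=3), [1.0])
    np.testing.assert_allclose(bonferroni([0.2], m=1), [0.2])


def test_bh_hand_computation():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_fdr([0.33]), [0.33])
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_correction_orderings(pvals):
    bh = bh_fdr(pvals)
    bonf = bonferroni(pvals)
    assert np.all(bh >= np.asarray(pvals) - 1e-12)  # BH never decreases a p
    assert np.all(bonf >= bh - 1e-12)  # Bonferroni dominates BH


def test_hosmer_lemeshow_null_calibration():
    """Under a correctly specified fitted model the HL p-value is ~uniform.

    The chi2(g-2) reference applies to predictions from a fitted logistic
    model (the two lost degrees of freedom come from the fitted parameters),
    so each replicate fits the true model family before testing.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    pvals = []
    n = 5000
    for _ in range(200):
        x = rng.normal(size=n)
        eta = -0.5 + 1.2 * x
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        p = np.clip(fit.fittedvalues, 1e-9, 1 - 1e-9)
        _, pv, dof = hosmer_lemeshow(np.asarray(p), y, g=10)
        assert dof == 8
        pvals.append(pv)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_hosmer_lemeshow_constant_prediction_matches_binomial_chi2():
    rng = np.random.default_rng(2)
    n, rate = 2000, 0.3
    y = rng.uniform(size=n) < rate
    p = np.full(n, rate)
    stat, _, _ = hosmer_lemeshow(p, y, g=10)
    # every group has the same expected rate: statistic is the sum of the
    # per-group binomial chi-squares
    order = np.argsort(p, kind="mergesort")
    expected = 0.0
    for ix in np.array_split(np.arange(n), 10):
        o1 = y[order][ix].sum()
        e1 = rate * len(ix)
        expected += (o1 - e1) ** 2 / e1 + ((len(ix) - o1) - (len(ix) - e1)) ** 2 / (
            len(ix) - e1
        )
    assert stat == pytest.approx(expected, rel=1e-12)


def test_hosmer_lemeshow_degenerate_g2():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.2, 0.8, 50)
    y = rng.uniform(size=50) < p
    stat, pv, dof = hosmer_lemeshow(p, y, g=2)
    assert dof == 0 and np.isnan(pv)


def test_vif_orthogonal_columns():
    X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
    assert np.allclose(vif(X), 1.0)


def test_vif_correlated_pair():
    rng = np.random.default_rng(4)
    n = 4000
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    z -= z @ x / (x @ x) * x  # exactly orthogonal residual
    x = (x - x.mean()) / x.std()
    z = (z - z.mean()) / z.std()
    y = 0.9 * x + np.sqrt(1 - 0.81) * z
    out = vif(pd.DataFrame({"x": x, "y": y}))
    assert out["x"] == pytest.approx(1 / (1 - 0.81), rel=1e-2)


def test_vif_duplicate_column_rejected():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
    with pytest.raises(DomainError, match="collinear"):
        vif(X)


def test_cohens_h_closed_form_values():
    assert cohens_h(0.3, 0.3) == 0.0
    assert cohens_h(1.0, 0.0) == pytest.approx(np.pi)
    assert cohens_h(0.724, 0.336) == pytest.approx(0.799, abs=0.002)
    with pytest.raises(DomainError):
        cohens_h(1.2, 0.5)


@given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_cohens_h_antisymmetric(p1, p2):
    assert cohens_h(p1, p2) == pytest.approx(-cohens_h(p2, p1), abs=1e-12)


def test_two_prop_ztest_hand_formula():
    z, p = two_prop_ztest(50, 100, 25, 100)
    pooled = 75 / 200
    se = np.sqrt(pooled * (1 - pooled) * (1 / 100 + 1 / 100))
    assert z == pytest.approx((0.5 - 0.25) / se, rel=1e-12)
    z2, _ = two_prop_ztest(25, 100, 50, 100)
    assert z2 == pytest.approx(-z)
    assert two_prop_ztest(30, 100, 30, 100)[0] == 0.0
    with pytest.raises(DomainError):
        two_prop_ztest(0, 10, 0, 10)


def test_proportion_summary_rounding():
    assert proportion_summary(17, 201) == 8.5
    assert proportion_summary(94, 148) == 63.5
    assert proportion_summary(0, 10) == 0.0
    with pytest.raises(DomainError):
        proportion_summary(11, 10)


def test_km_no_events_survival_one():
    tab, _, _ = km_logrank([5.0, 7.0, 12.0], [0, 0, 0], ["a", "a", "a"])
    assert tab["survival"].iloc[0] == pytest.approx(1.0)


def test_km_no_censoring_equals_empirical_survivor():
    rng = np.random.default_rng(5)
    times = rng.uniform(0.5, 12, 200)
    events = np.ones(200, dtype=int)
    tab, _, _ = km_logrank(times, events, ["g"] * 200, horizons=(3.0, 6.0, 9.0))
    for _, row in tab.iterrows():
        emp = (times > row["horizon"]).mean()
        assert row["survival"] == pytest.approx(emp, abs=1e-12)


def _null_cohort(n, seed):
    om = OutcomeModel()
    om.intercepts["end72"] = (_logit(0.25),) * 3  # no phenotype effect
    cfg = CohortConfig(n_patients=n, seed=seed, outcome_model=om)
    tab = simulate_cohort_table(cfg, seed=seed)
    return tab.rename(columns={"true_phenotype": "phenotype"})


def test_adjusted_or_coverage_under_null():
    """Wald 95% CIs for a null phenotype effect cover OR=1 ~95% of the time."""
    cover = np.zeros(2)
    reps = 200
    for r in range(reps):
        tab = _null_cohort(2000, seed=1000 + r)
        res = adjusted_models(
            tab, "end72", ["age", "sex_female", "nihss0"],
            group_col="phenotype",
        )
        phen = res[res["term"].str.startswith("phenotype_")]
        cover += ((phen["ci_low"] <= 1.0) & (phen["ci_high"] >= 1.0)).to_numpy()
    rate = cover.sum() / (2 * reps)
    assert 0.92 <= rate <= 0.98


def test_adjusted_or_recovers_configured_effect():
    om = OutcomeModel()
    base = _logit(0.15)
    om.intercepts["end72"] = (base + 0.9, base, base)  # log-OR 0.9 vs reference
    cfg = CohortConfig(n_patients=4000, seed=21, outcome_model=om)
    tab = simulate_cohort_table(cfg, seed=21).rename(
        columns={"true_phenotype": "phenotype"}
    )
    res = adjusted_models(tab, "end72", ["age", "sex_female"])
    row = res[res["term"] == "phenotype_Steady-High"].iloc[0]
    assert np.log(row["estimate"]) == pytest.approx(0.9, abs=0.25)
    assert not row["flagged"]


def test_relabelling_reference_inverts_or():
    tab = _null_cohort(1500, seed=77)
    a = adjusted_models(tab, "end72", ["age"], reference="Partial-Recovery")
    b = adjusted_models(tab, "end72", ["age"], reference="Steady-High")
    or_ab = a.loc[a["term"] == "phenotype_Steady-High", "estimate"].iloc[0]
    or_ba = b.loc[b["term"] == "phenotype_Partial-Recovery", "estimate"].iloc[0]
    assert or_ab == pytest.approx(1 / or_ba, rel=1e-6)


def test_cox_model_contract():
    tab = _null_cohort(800, seed=9)
    res = adjusted_models(
        tab, "mace12", ["age"], group_col="phenotype", model="cox",
        time_col="mace_months",
    )
    assert set(res["measure"]) == {"HR"}
    assert len(res[res["term"].str.startswith("phenotype_")]) == 2


def test_fisher_chi2_agree_on_large_balanced_tables():
    table = [[220, 205], [210, 230]]  # n per cell >= 50, balanced
    res_f = stats.fisher_exact(table)[1]
    res_c = group_test(table)
    assert res_c.method == "chi2"
    assert abs(res_c.p_value - res_f) < 0.02
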
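"""Statistical layer: group tests, corrections, diagnostics, effect sizes,
survival estimates, and adjusted regression contracts.

Test selection follows the usual clinical-table conventions: chi-square for
categorical comparisons unless any expected cell count falls below 5 (then
Fisher's exact; Monte-Carlo for tables larger than 2x2), ANOVA or
Kruskal-Wallis for continuous variables. Bonferroni guards post hoc pairwise
comparisons; Benjamini-Hochberg FDR guards interaction screens. Calibration
and collinearity diagnostics (Hosmer-Lemeshow, VIF) are provided for the
adjusted logistic models, and Kaplan-Meier/log-rank and Cox fits delegate to
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass
class AssociationResult:
    statistic: float
    dof: int | None
    p_value: float
    method: str
    table: np.ndarray | None = None
    posthoc: pd.DataFrame | None = field(repr=False, default=None)


def expected_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def _fisher_mc(table: np.ndarray, n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo Fisher p for r x c tables: chi-square orderings of tables
    drawn with fixed margins (via label permutation)."""
    t = np.asarray(table, dtype=int)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.concatenate(
        [np.repeat(np.arange(t.shape[1]), t[i]) for i in range(t.shape[0])]
    )
    obs = stats.chi2_contingency(t, correction=False)[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = expected_counts(sim)
            stat = np.nansum((sim - e) ** 2 / e)
        if stat >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def group_test(
    table_or_samples,
    kind: str = "categorical",
    normal: bool = False,
    posthoc: bool = False,
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> AssociationResult:
    """Omnibus group comparison with the study's test-selection rule.

    ``kind="categorical"``: pass a contingency table (groups x levels); the
    chi-square test is used unless any expected cell count is < 5, in which
    case Fisher's exact test applies (2x2 exact; Monte-Carlo with a fixed seed
    for larger tables). ``kind="continuous"``: pass a sequence of per-group
    samples; ANOVA when ``normal`` else Kruskal-Wallis. Optional Bonferroni-
    corrected pairwise post hoc tests are attached when the omnibus test is
    significant.
    """
    if kind == "categorical":
        t = np.asarray(table_or_samples, dtype=int)
        if t.ndim != 2 or t.shape[0] < 2:
            raise DomainError("need a 2-D table with >= 2 groups")
        if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
            raise DomainError("degenerate table: zero margin")
        exp = expected_counts(t)
        if np.any(exp < 5):
            if t.shape == (2, 2):
                odds, p = stats.fisher_exact(t)
                result = AssociationResult(float(odds), None, float(p),
                                           "fisher", t)
            else:
                p = _fisher_mc(t, n_draws=mc_draws, seed=seed)
                result = AssociationResult(float("nan"), None, float(p),
                                           "fisher-mc", t)
        else:
            chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
            result = AssociationResult(float(chi2), int(dof), float(p), "chi2", t)
        if posthoc and result.p_value < alpha and t.shape[0] > 2:
            result.posthoc = _pairwise_posthoc(t, seed=seed)
        return result
    samples = [np.asarray(s, dtype=float) for s in table_or_samples]
    if len(samples) < 2:
        raise DomainError("need >= 2 groups")
    if normal:
        stat, p = stats.f_oneway(*samples)
        return AssociationResult(float(stat), None, float(p), "anova")
    stat, p = stats.kruskal(*samples)
    return AssociationResult(float(stat), None, float(p), "kruskal")


def _pairwise_posthoc(table: np.ndarray, seed: int = 0) -> pd.DataFrame:
    t = np.asarray(table, dtype=int)
    pairs = [(i, j) for i in range(t.shape[0]) for j in range(i + 1, t.shape[0])]
    rows = []
    raw = []
    for i, j in pairs:
        sub = t[[i, j]]
        res = group_test(sub, seed=seed)
        raw.append(res.p_value)
        rows.append({"group_a": i, "group_b": j, "method": res.method,
                     "p_raw": res.p_value})
    adj = bonferroni(raw, m=len(raw))
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = adj
    out["correction"] = "bonferroni"
    return out


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the family size."""
    p = np.asarray(pvalues, dtype=float)
    mm = len(p) if m is None else m
    if mm < len(p):
        raise DomainError("m must be >= number of p-values")
    return np.minimum(1.0, mm * p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def hosmer_lemeshow(
    predicted_probs, outcomes, g: int = 10
) -> tuple[float, float, int]:
    """Hosmer-Lemeshow decile-of-risk calibration test.

    Groups with zero expected events (or non-events) are merged with their
    neighbour. Returns (statistic, p, dof) with dof = groups - 2; a dof of 0
    is returned with p = NaN (flagged unusable by the caller).
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("predicted probabilities must lie in (0, 1)")
    if p.size < 2 * g:
        raise InsufficientDataError("need n >= 2g observations")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    groups = np.array_split(np.arange(p.size), g)
    bins = [(p[ix], y[ix]) for ix in groups if ix.size]
    # merge bins with zero expected events/non-events into the neighbour
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for pb, yb in bins:
        if merged and (pb.sum() == 0 or (1 - pb).sum() == 0):
            pp, yy = merged[-1]
            merged[-1] = (np.concatenate([pp, pb]), np.concatenate([yy, yb]))
        else:
            merged.append((pb, yb))
    stat = 0.0
    for pb, yb in merged:
        e1 = pb.sum()
        e0 = (1 - pb).sum()
        o1 = yb.sum()
        stat += (o1 - e1) ** 2 / e1 + ((len(yb) - o1) - e0) ** 2 / e0
    dof = len(merged) - 2
    pval = float(stats.chi2.sf(stat, dof)) if dof > 0 else float("nan")
    return float(stat), pval, dof


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j), intercept added.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise DomainError("need >= 2 covariates")
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify a minimal offending set by dropping columns one at a time
        bad = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(Xc, i + 1, axis=1)) == np.linalg.matrix_rank(Xc)
        ]
        raise DomainError(f"design is rank deficient; collinear set: {bad}")
    out = {}
    for i, c in enumerate(design.columns):
        yj = X[:, i]
        Xj = np.column_stack(
            [np.ones(X.shape[0]), np.delete(X, i, axis=1)]
        )
        coef, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ coef
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
        out[c] = 1.0 / (1.0 - r2) if r2 < 1 else np.inf
    return pd.Series(out, name="vif")


def cohens_h(p1: float, p2: float) -> float:
    """Effect size for two proportions: h = 2 asin(sqrt p1) - 2 asin(sqrt p2)."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise DomainError("proportions must lie in [0, 1]")
    return float(2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2)))


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample Z test for proportions; two-sided p."""
    if n1 <= 0 or n2 <= 0 or not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise DomainError("need 0 <= x_i <= n_i and n_i > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DomainError("pooled proportion 0 or 1: Z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def proportion_summary(count: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage at the table's rounding (default 1 d.p.)."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    if count > denominator:
        raise DomainError("count exceeds denominator")
    return round(100.0 * count / denominator, ndigits)


def km_logrank(
    times, events, groups, horizons=(12.0,)
) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier survival per group at requested horizons plus log-rank p.

    Returns (table, logrank statistic, p). Delegates the product-limit
    estimate and the log-rank test to lifelines.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": np.asarray(groups),
    })
    if df["event"].sum() < 1:
        pass  # no events: survival is 1 everywhere, log-rank undefined
    rows = []
    for gname, g in df.groupby("group", sort=True):
        if len(g) == 0:
            raise DomainError(f"empty group {gname!r}")
        km = KaplanMeierFitter().fit(g["time"], g["event"])
        for h in horizons:
            rows.append(
                {
                    "group": gname,
                    "horizon": h,
                    "survival": float(km.survival_function_at_times(h).iloc[0]),
                    "n": len(g),
                    "events": int(g["event"].sum()),
                }
            )
    if df["event"].sum() >= 1 and df["group"].nunique() >= 2:
        lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
        stat, p = float(lr.test_statistic), float(lr.p_value)
    else:
        stat, p = float("nan"), float("nan")
    return pd.DataFrame(rows), stat, p


def adjusted_models(
    cohort: pd.DataFrame,
    outcome: str,
    covariates,
    group_col: str = "phenotype",
    reference: str = "Partial-Recovery",
    model: str = "logistic",
    time_col: str | None = None,
    interactions=(),
) -> pd.DataFrame:
    """Adjusted odds/hazard ratios with 95% Wald CIs, reference-coded.

    Assembles the design (group dummies against ``reference``, covariates,
    optional ``group x covariate`` interaction terms) and delegates the fit to
    statsmodels (logistic) or lifelines (Cox). Complete-case only; separation
    or non-convergence is flagged per row rather than raised.
    """
    import statsmodels.api as sm

    covariates = list(covariates)
    cols = [outcome, group_col, *covariates] + ([time_col] if time_col else [])
    data = cohort[cols].dropna().copy()
    levels = sorted(data[group_col].unique())
    if reference not in levels:
        raise DomainError(f"reference level {reference!r} absent from {group_col}")
    dummies = pd.get_dummies(data[group_col], prefix=group_col, dtype=float)
    keep = [c for c in dummies.columns if c != f"{group_col}_{reference}"]
    X = pd.concat([dummies[keep], data[covariates].astype(float)], axis=1)
    for g, cov in interactions:
        col = f"{group_col}_{g}"
        if col in X.columns:
            X[f"{col}:{cov}"] = X[col] * data[cov].astype(float)

    if model == "logistic":
        Xc = sm.add_constant(X, has_constant="add")
        try:
            fit = sm.GLM(data[outcome].astype(float), Xc,
                         family=sm.families.Binomial()).fit(maxiter=200)
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
        except Exception:
            return pd.DataFrame(
                {"term": X.columns, "flagged": True}
            )
        rows = []
        for term in X.columns:
            coef, se = params[term], bse[term]
            flagged = bool(abs(coef) > 15 or se > 50 or not np.isfinite(se))
            lo = np.clip(coef - 1.96 * se, -700, 700)
            hi = np.clip(coef + 1.96 * se, -700, 700)
            rows.append(
                {
                    "term": term,
                    "estimate": float(np.exp(np.clip(coef, -700, 700))),
                    "ci_low": float(np.exp(lo)),
                    "ci_high": float(np.exp(hi)),
                    "p": float(pvals[term]),
                    "measure": "OR",
                    "flagged": flagged,
                }
            )
        return pd.DataFrame(rows)
    if model == "cox":
        from lifelines import CoxPHFitter

        if time_col is None:
            raise DomainError("cox model needs a time column")
        df = pd.concat(
            [X, data[[time_col, outcome]].astype(float)], axis=1
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=outcome)
        out = cph.summary.reset_index()
        return pd.DataFrame(
            {
                "term": out["covariate"],
                "estimate": np.exp(out["coef"]),
                "ci_low": np.exp(out["coef"] - 1.96 * out["se(coef)"]),
                "ci_high": np.exp(out["coef"] + 1.96 * out["se(coef)"]),
                "p": out["p"],
                "measure": "HR",
                "flagged": (out["se(coef)"] > 50) | (out["coef"].abs() > 15),
            }
        )
    raise DomainError(f"unknown model {model!r}")
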
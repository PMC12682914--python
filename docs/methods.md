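# Methods

`circabp` re-implements, as a reusable pipeline, a circadian blood-pressure
(BP) phenotyping analysis for the first 72 h after acute ischemic stroke:
quality control and state-space gap imputation of high-frequency BP series,
per-patient 24-h cosinor rhythmometry, nocturnal dipping classification,
multiscale variability features, data-driven phenotype clustering with
bootstrap stability assessment, and an outcome-association layer. Because no
patient-level registry is distributable, a first-class synthetic-cohort
generator supplies inputs that carry the statistical structure the analysis
assumes.

## Synthetic cohort generator

Each patient belongs to one of three latent circadian phenotypes, drawn with
mixture weights (0.38, 0.34, 0.28). The systolic trace is

    SBP(t) = M + A cos(2π (clock(t) − φ)/24) + δ_c · 1[night] + ε(t),

with per-patient parameters drawn around archetype centres:

| archetype              | MESOR M (sd) | amplitude A (sd) | acrophase φ (sd) | night drift |
|------------------------|--------------|------------------|------------------|-------------|
| Steady-High            | 148 (6) mmHg | 5.1 (1.2) mmHg   | 15.5 h (1.5 h)   | none        |
| Disrupted-Rhythmicity  | 135 (6) mmHg | 4.3 (1.0) mmHg   | 03:00 (2.0 h)    | none        |
| Partial-Recovery       | 134 (6) mmHg | 10.7 (1.5) mmHg  | 15.0 h (1.5 h)   | +2.5 mmHg/night |

Steady-High and Disrupted-Rhythmicity MESOR/amplitude centres follow the
cluster centroids the analysis is expected to find; the Partial-Recovery
amplitude (10.7 mmHg) is set so the mixture mean amplitude equals the cohort
mean of 6.4 mmHg that the rhythm summary should recover. Disrupted-
Rhythmicity is modelled as a phase-inverted rhythm (nocturnal acrophase),
which produces its hallmark reverse-dipping excess; Partial-Recovery's night
offsets drift by ±2.5 mmHg across the three cycles (night means fall from
night 1 to night 3), expressing recovering dipping. `dipping_target`
(percent) is honoured by solving the closed-form day/night window integrals
of the cosine for a constant night-window offset; the shipped targets equal
the declines the cosine geometry itself produces, so shipped offsets are ≈ 0.

Residuals are AR(1) (coefficient 0.3 at the reading-to-reading lag) with
stationary SD 6 mmHg — consistent with short-term BP variability (average
real variability of ~5 mmHg) after the circadian component is removed; the
AR(1) choice exercises the smoother on autocorrelated data and is a stand-in,
not a claim about any real registry. Diastolic traces are a proportional
waveform (0.62 × systolic signal) with their own residual, kept below SBP.

Monitoring design: 9.9% of patients are invasive (1-min averages over the
whole span), the rest cuff (15-min grid for the first 24 h, then 30-min).
Missing runs follow a renewal process — exponential waits (patient-specific
rates, Gamma-heterogeneous, mean 0.67/h), exponential durations with mean
25 min clipped to [5, 120] min, and a one-slot guard so no injected run ever
exceeds the configured maximum. The rate is calibrated so the cohort median
measurement density is ≈ 0.82 (IQR ≈ 0.77–0.87), matching the monitoring
density the pipeline is designed for. Artifacts replace 2% of readings with
uniform draws outside physiologic bounds (detectable by construction) and are
tagged in the ground truth. Each trace spans at least 72 h and always covers
three full clock-nights.

Covariates (age, sex, hypertension, diabetes, AF, CKD, NIHSS) are drawn from
per-phenotype distributions; binary outcomes (END ≤ 72 h, sICH, mRS 0–2 at
90 d, 90-day mortality, 12-month MACE) come from per-phenotype logistic
models with configurable covariate log-odds; defaults are intercept-only with
event probabilities such as MACE = (0.273, 0.198, 0.115). MACE event times
are uniform over follow-up for events and censored at 12 months otherwise.

What the generator does *not* emulate: medication effects and dosing-time
structure, baroreflex dynamics, measurement-mode biases between invasive and
cuff readings, missingness that is informative about BP level, and within-
phenotype correlation between rhythm parameters and covariates beyond the
phenotype label itself. Passing tests therefore demonstrate that the pipeline
recovers structure of this generative family at realistic noise and
missingness — not that the clinical findings themselves replicate. One known
overshoot: with a phase-inverted archetype nearly all Disrupted-Rhythmicity
patients reverse-dip on the fitted basis, more than the minority share a real
cohort shows; the alternative (a widely dispersed acrophase) destroys the
clean three-cluster geometry the analysis is specified to find, and the
cluster structure takes precedence here.

## QC and eligibility

Artifact editing uses standard ambulatory-monitoring criteria (the editing
rules behind "removed a priori" are not published, so these are explicit,
configurable reconstructions): SBP within [60, 260] mmHg, DBP within
[30, 150] mmHg, DBP < SBP, and an isolated-spike rule (|ΔSBP| > 60 mmHg
against both neighbours within 5 min — effectively an invasive-line rule,
since cuff readings are never that close). Flags are a pure function of the
values, so flagging is idempotent and never depends on previous flags.

Measurement density is the fraction of the source's nominal scheduled
readings that are present and valid in a window; the nominal schedule is
reconstructed from the source label. Eligibility requires ≥ 48 h monitored
span, ≥ 12 h of monitored span in each 24-h period of stay, and ≤ 20%
missingness despite imputation. The "12 h per night" rule is operationalised
per 24-h period because a literal 12-h floor inside a 12-h night window would
exclude every series with any nocturnal gap; coverage is span-based (first to
last reading), with interior missingness handled by the density criterion.

## Gap imputation

The smoothing model is a local level (random-walk level + observation noise)
with the innovation variance scaled by the inter-reading interval, the
simplest state-space model that admits a Kalman/RTS smoother on an irregular
grid. Variances are estimated per patient and channel (SBP and DBP
independently) by maximum likelihood (Nelder–Mead on log-variances,
prediction-error decomposition, exact diffuse start: the first observation
pins the level and is not scored). A numerical floor of 1e-8 mmHg² keeps the
filter non-singular on constant series. Long invasive traces are fitted on an
evenly strided subsample (≤ 400 points); the local-level model is closed
under subsampling because the innovation variance scales with the interval,
so this changes cost, not the estimand.

The smoother runs on the source's nominal slot grid (missing slots as NaN
observations). Interior missing runs whose duration (next valid reading minus
previous, less one nominal interval) is ≤ 30 min receive the smoothed mean
with flag `imputed`; longer runs and edge runs stay missing; observed valid
readings pass through bit-identical. Artifact readings are treated as missing
and dropped from the imputed series.

## Cosinor rhythmometry

The single-component 24-h cosinor is ordinary least squares on
y = M + β cos(ωt) + γ sin(ωt), ω = 2π/24, with t the wall-clock hour so the
acrophase (atan2(γ, β)/ω mod 24) is directly a clock time; amplitude is
√(β² + γ²) with a delta-method SE. Fits are per admission-aligned 24-h cycle
(cycles 1–3) and require ≥ 24 valid+imputed points spanning ≥ 18 h — loose
enough for the sparsest cuff regime (48 scheduled points/cycle), tight enough
to keep the three parameters identifiable. Imputed points enter with equal
weight by default (configurable for sensitivity analyses). A zero-amplitude
fit reports an undefined (NaN) acrophase rather than 0. Cohort summaries use
arithmetic means with t-based 95% CIs for MESOR/amplitude (each patient
contributing once via its cycle average) and a circular mean with a
1,000-resample patient bootstrap CI for acrophase, avoiding linearisation at
the 0/24 boundary.

## Dipping

Nocturnal decline (%) = 100 × (day mean − night mean)/day mean, computed by
default from the fitted cosinor curve via exact window integrals of the
cosine (raw-means mode is retained for sensitivity). Default windows are day
09:00–21:00 and night 21:00–09:00, both configurable (21:00–09:00 matches the
nocturnal segments used for display; alternative night definitions are
supported because several are in circulation). Categories: reverse-dipper
(< 0), non-dipper [0, 10), dipper [10, 20), extreme-dipper (≥ 20), with the
extreme category collapsible into dipper for three-way reporting. Prevalence
tables default to the number of classified patients as denominator; an
explicit denominator is accepted because published tables sometimes use the
cohort denominator instead.

## Features and clustering

Per patient: MESOR, amplitude and acrophase (as a sin/cos pair, respecting
circularity) for each cycle; nightly declines; SD, CV, average real
variability and range per cycle; sample entropy (m = 2, r = 0.2·SD — the
field-standard parameters) computed on a common 15-min grid so invasive and
cuff sources are compared at the same effective sampling rate; and a recovery
slope (decline₃ − decline₁)/2. Patients missing any cycle are excluded and
listed. Columns are z-scored (population SD; zero-variance columns dropped
with a warning), and the scaler is stored for projecting new patients. The
exact published feature list is unavailable, so this set is a documented,
configurable reconstruction.

Clustering is a Gaussian mixture (EM, best of 10 restarts, tolerance 1e-6,
≤ 500 iterations), the likelihood-based family that makes AIC/BIC meaningful;
full covariance when n ≥ k·d(d+3)/2, else diagonal (the 29-feature default at
n ≈ 500 uses diagonal). k is chosen over 2–6 by an auditable precedence rule:
among candidates whose mean silhouette width is within 95% of the maximum,
the smallest BIC wins, and the full per-k table is always emitted. Stability
is clusterwise bootstrap Jaccard (Hennig-style): refit at the reference k on
each resample, give each reference cluster its best Jaccard match over the
unique patients present, and average; degenerate resamples are skipped and
counted. Semantic labels come from centroid geometry: highest centroid MESOR
→ Steady-High; of the rest, lowest centroid amplitude → Disrupted-
Rhythmicity (amplitude ties broken by recovery slope, the higher slope going
to Partial-Recovery); remainder → Partial-Recovery. With k ≠ 3 labels are
withheld and clusters stay numeric.

## Association layer

Categorical comparisons use χ² unless any expected cell count is below 5,
then Fisher's exact (2×2 exact; larger tables by seeded Monte-Carlo
permutation, 100,000 draws by default, since exact enumeration is
infeasible); continuous comparisons use ANOVA or Kruskal–Wallis. Bonferroni
(p·m capped at 1) guards post hoc pairwise tests, Benjamini–Hochberg guards
interaction screens. Hosmer–Lemeshow uses deciles of risk with χ²(g−2)
(groups with zero expected events merged, dof 0 flagged unusable); VIFs are
1/(1−R²) from auxiliary regressions, with rank deficiency reported by naming
the collinear set. Effect sizes: Cohen's h = 2 asin√p₁ − 2 asin√p₂ and the
pooled two-proportion Z test. Kaplan–Meier estimates, the log-rank test and
Cox proportional-hazards fits delegate to lifelines; adjusted logistic models
delegate to statsmodels GLM. This package's own logic there is design-matrix
assembly (Partial-Recovery as the reference phenotype, optional group ×
covariate interactions) and separation detection (|coef| > 15 or SE > 50
flags the row instead of crashing). Percentages are reported at 1 d.p. and
odds ratios at 2 d.p. in formatted outputs. Multiple imputation and
propensity weighting are deliberately out of scope: the pipeline is
complete-case with an explicit missingness report, and synthetic cohorts are
complete by construction.

## Problem sizes and numerical choices

Study-level checks run at n = 500 patients (the three-archetype default),
200 bootstrap resamples for stability (scaled from the 1,000 a full analysis
would use; the Jaccard mean is insensitive to resample count at this
separation), and n = 2,000 per group for the survival contract. Variance
floors (1e-8 mmHg²), the EM regularisation (1e-6 on covariance diagonals),
and the silhouette slack (5% of the maximum) are the only tie-breaking
constants; all are configurable. Known limitations: the smoother is
univariate (no joint SBP/DBP state), sample entropy is undefined (NaN) when
no template pairs match and such patients are excluded from clustering, and
the acrophase bootstrap CI assumes the per-patient circular means are not
uniformly dispersed.
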
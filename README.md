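# circabp

Circadian blood-pressure (BP) phenotyping for acute-stroke monitoring data.

In the first 72 hours after an ischemic stroke, the normal day–night BP rhythm
is often disturbed: the nocturnal decline flattens or inverts, the circadian
amplitude is blunted, and patients follow distinct trajectories that carry
prognostic information. `circabp` is a pipeline for stroke-unit BP series
(invasive 1-min averages or scheduled cuff readings) that:

1. **QCs** the series — physiologic-bounds and spike artifact editing,
   measurement density, and eligibility rules (≥ 48 h monitored, ≥ 12 h per
   night of stay, ≤ 20% missing despite imputation);
2. **imputes** short gaps (≤ 30 min) with the fixed-interval Kalman (RTS)
   smoother of a local-level state-space model fitted per patient on an
   irregular time grid, leaving longer gaps missing;
3. fits the **24-h cosinor** per admission-aligned cycle by least squares,
   `y = M + β cos(ωt) + γ sin(ωt)` with `ω = 2π/24` and `t` the clock hour,
   reporting MESOR `M`, amplitude `A = √(β²+γ²)` and acrophase (clock time of
   the fitted peak);
4. classifies **nocturnal dipping** from the fitted curve's day/night window
   integrals: decline (%) = 100·(day − night)/day, with reverse-dipper (< 0),
   non-dipper (< 10), dipper (10–20) and extreme-dipper (≥ 20) categories;
5. builds a standardized **multiscale feature matrix** (cosinor parameters per
   cycle, nightly declines, SD/CV/average-real-variability/range, sample
   entropy, recovery slope);
6. derives **phenotypes** with a Gaussian mixture: k selected over 2–6 by
   silhouette + BIC, clusterwise bootstrap Jaccard stability, and semantic
   labels (Steady-High / Disrupted-Rhythmicity / Partial-Recovery) from
   centroid geometry;
7. runs the **association layer**: χ²/Fisher/Kruskal–Wallis with the
   expected-count selection rule, Bonferroni and Benjamini–Hochberg
   corrections, Hosmer–Lemeshow calibration, VIFs, Cohen's h, two-proportion
   Z tests, Kaplan–Meier/log-rank, and adjusted logistic/Cox models with
   Partial-Recovery as the reference phenotype.

Because stroke-unit registries are not distributable, the package ships a
first-class **synthetic-cohort generator** (`circabp.simulate`) that emulates
the monitoring design (sampling schedules, gap and artifact processes
calibrated to ~82% median measurement density) and the effect structure
(three circadian archetypes, dipping trajectories, per-phenotype outcome
models). Every study-level claim in the test suite is exercised against it.

## Worked example

```python
from circabp.pipeline import run_default_study, phenotype_cohort
from circabp.cosinor import summarize_cohort_rhythm

processed, cohort, truth = run_default_study(n_patients=200, seed=42)
analysis = phenotype_cohort(processed, seed=42, n_bootstrap=100)
print("selected k:", analysis.k)
print(analysis.result.summary())
print("stability:", round(analysis.stability.overall_mean_jaccard, 3))
```

prints

```
selected k: 3
Gaussian mixture, k=3 (diag covariance)
  log-likelihood : -5312.09  (p=176)
  AIC 10976.2 | BIC 11549.5 | silhouette 0.318
  cluster sizes  : 74, 64, 54
stability: 0.975
```

— the three-cluster solution is selected (smallest BIC among near-max
silhouette candidates), and cluster membership is highly reproducible under
bootstrap resampling (mean Jaccard 0.975, well above the 0.85 reproducibility
bar). The cohort rhythm summary on the same run,

```python
summ = summarize_cohort_rhythm(processed.fits, n_boot=200, seed=42)
pooled = summ.table[summ.table.cycle == "pooled"].iloc[0]
```

gives a mean amplitude of 6.66 mmHg (95% CI 6.24–7.08) and mean MESOR
139.6 mmHg (95% CI 138.3–140.9): a blunted rhythm riding on an elevated
pressure level, the expected acute-stroke picture. Phenotype labels match the
generator's hidden truth for 97% of patients at the default separation.

## Command line

Each stage is also a CLI subcommand over CSV files:

```bash
circabp simulate --seed 17 --n 500 --out sim/
circabp qc       --in sim/series.csv --out qc.csv
circabp impute   --in sim/series.csv --max-gap 30 --out imputed.csv
circabp cosinor  --in imputed.csv --out cosinor.csv
circabp dip      --in cosinor.csv --night 21:00-09:00 --out dipping.csv
circabp features --in sim/series.csv --out features.csv
circabp cluster  --in sim/series.csv --kmin 2 --kmax 6 --bootstrap 200 \
                 --seed 17 --out model
circabp associate --cohort sim/cohort.csv --phenotypes model.phenotypes.csv \
                  --out tables/
```

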
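# Methods

This note documents the statistical procedure, the numerical choices, and
the synthetic-cohort generator, in the package's own terms.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Inputs and aggregation

The analysis unit is the tumor **sample**.  Each sample is pyrosequenced in
replicate (normally two runs) over a fixed CpG panel; each run reports a
percentage methylation per site on the 0–100 scale.  A run that failed to
report one or more sites is excluded outright — no imputation — and a sample
survives as long as at least one complete run remains.  Aggregation is
mean-of-means: per-site mean across a sample's kept runs, then the sample's
average methylation as the mean of those per-site means.  Replicate
variability is the sample standard deviation (denominator n−1) of the
per-run mean-across-sites values; it is undefined for single-run samples and
those samples are excluded from replicate-SD summaries.

Percentages stay on the 0–100 scale everywhere.  The CpG panel is a runtime
parameter (`site_ids`), not a constant, because different assays interrogate
different site ranges (12 sites 72–83 vs 6 sites 74–79 are both in use).

## QC

* **Per-site distributions and correlation** — five-number summary plus
  mean/SD per site, and the site-by-site Pearson correlation of per-site
  means across samples.  Correlations involving a zero-variance site are
  reported as undefined (NaN), never coerced to 0.
* **Discordance** — a sample is discordant under a classification when its
  per-run mean-across-sites values do not all fall in the same category.
  Refining the binary split with a gray zone can only add discordant samples
  (the methylated boundary is kept), and the report lists discordance under
  both the binary and the selected three-category classification.
* **Multivariate outliers** — squared Mahalanobis distance of each sample's
  per-site profile from the cohort mean profile, with the unbiased (n−1)
  sample covariance.  That convention makes Σd² = (n−1)·p exactly, which the
  tests use as a self-check.  The cutoff is the χ² quantile with df = number
  of sites at probability `outlier_quantile` (default 0.975; the flagging
  probability under exact multivariate normality would be 2.5%, but bimodal
  mixture-shaped cohorts flag considerably more — these are review
  candidates, not rejections).  The default action is **flag only**: flagged
  samples stay in the analysis.  `exclude_and_rerun` repeats the entire
  downstream analysis without the flagged samples and reports both results
  side by side, as a sensitivity check.  A singular covariance raises an
  error that names the `pseudo_inverse` escape hatch; with the flag set the
  Moore–Penrose pseudo-inverse is used and distances are computed within the
  support of the data.

## Threshold and candidate sweep

The binary methylated threshold M is either supplied (`meth_threshold: 12`)
or derived by the **50/50 split rule**: over integer candidates t ∈ 1..99,
classify methylated as average methylation ≥ t and return the t minimizing
|#methylated − n/2|, breaking ties to the smallest t (the choice labelling
more samples methylated).  With a sparse band between the unmethylated and
methylated modes, many thresholds tie and the rule lands at the low edge of
the gap; laboratories with a validated historical threshold should supply it
and treat the derived value as a cross-check.

Candidates are all integer gray-zone lower bounds g with 1 ≤ g < M.
Category boundaries are inclusive-lower / exclusive-upper
(unmethylated < g ≤ gray zone < M ≤ methylated), with no rounding before
comparison.

Each candidate model's covariates are the age-group indicator
(1[age ≥ `age_cutoff`], default 65 years) and two category indicators with
the **gray zone as reference**; this coding yields both clinically reported
contrasts (methylated:gray, unmethylated:gray) from one fit.  Sex
(male indicator, female reference) is available behind `include_sex` as a
sensitivity analysis; subjects with unknown sex are dropped (with a logged
count) only in that mode.  The primary model excludes sex.

The binary reference model uses the same age term plus an unmethylated
indicator (methylated reference).  Its maximized log partial likelihood is
invariant to which indicator coding is used, and merging the gray zone into
the unmethylated category reproduces it exactly — hence each candidate-vs-
binary comparison is a nested LRT with df = 1.

**Qualification** is conjunctive at α = 0.05: HR(methylated:gray) < 1 with
p < α, HR(unmethylated:gray) > 1 with p < α, and LRT p < α.  Candidates
passing the two HR criteria but not the LRT are recorded as near-misses in
the decision trace.  No multiplicity correction is applied across the
candidates: the sweep is a model-selection device, not simultaneous
inference, and the report states this.  The optimum is the qualifying
candidate with the largest LRT statistic; exact ties break to the smaller g
(the wider gray zone, i.e. the larger safety margin for patients who might
still benefit from temozolomide).  An empty candidate category yields an
inestimable row with `qualifies = false` — never a silent drop.

## Survival engine

Self-contained; external survival packages appear only as cross-check
oracles in the tests.

* **Kaplan–Meier** — product-limit estimator with Greenwood variance and
  95% bands on the log(−log) scale: S^(exp(±z·se)), z = 1.959964.  The
  median is the smallest event time with Ŝ ≤ 0.5 (+∞ if never reached); its
  confidence bounds are the first event times at which the lower / upper
  band drops to ≤ 0.5, serialized as −inf / +inf when a band never crosses
  (typical for very small categories).
* **Cox regression** — Newton–Raphson on the log partial likelihood with the
  Efron correction for tied event times (Breslow available; the two agree
  when no ties exist).  Risk-set moments are suffix sums over the
  time-sorted data; untied event times are handled fully vectorized and only
  tied groups use an explicit loop.  Convergence requires a relative
  log-likelihood change below 1e-10 *and* a gradient max-norm below 1e-9
  within 50 iterations; each step is halved at most 10 times until the
  likelihood does not decrease, with the acceptance tolerance scaled by
  |log-likelihood| to respect float rounding on large cohorts.  Standard
  errors come from the inverse observed information; Wald CIs and two-sided
  z-tests per coefficient; the global score test at β = 0 is also reported
  (for a category-only model it is the log-rank test).  A monotone likelihood
  (perfectly separating covariate) is detected post hoc — coefficient beyond
  ±20 or SE above 1e3 — and reported with `converged = false`, a warning and
  an unbounded Wald interval, not an exception: tiny gray zones can produce
  it and must stay visible in the candidate table.
* **Nested LRT** — 2·(ℓ_full − ℓ_reduced) clipped at 0, df = coefficient
  difference, upper χ² tail.  Model pairs must carry the identical subject
  set (enforced through a signature of the sorted time/event data).  The
  difference of the two models' score statistics is reported alongside as a
  secondary diagnostic; it is *not* the LRT and is never used for selection.

## Synthetic cohorts

`grayzone.simulate` generates cohorts with the structure the method assumes;
its defaults encode the development-cohort regime, and a validation preset
encodes a small, short-follow-up cohort with a sparse intermediate band.

* **Latent average methylation** — two-component truncated-normal mixture on
  [0, 100]: low mode N(3, 3²), high mode N(38, 18²), high-mode weight 0.53.
  This reproduces a cohort mean ≈ 21%, SD ≈ 21%, ~49% of samples at or above
  12%, and ~14–16% of samples in the [5, 12) band.
* **Per-site profiles** — the latent mean is the single shared factor;
  per-site residuals are *proportional* to it, site = m·(1 + c·ε), with the
  slope c solved so the inter-site Pearson correlation of the emitted
  profiles hits the target (default 0.90):
  corr = V_m / (V_m + c²·E[m²]).  Proportional residuals keep unmethylated
  samples pinned near 0% (as real assays do) and avoid the truncation bias
  that additive homoscedastic noise suffers at the 0% floor.  The sample's
  *true* average methylation, and hence its true category under
  (true_g = 5, true_M = 12), is the mean of this pre-replicate-noise
  profile.
* **Replicate runs** — each run adds a shared per-run offset with SD
  0.89 + 0.04·m (replicate scatter grows with methylation level).  For two
  runs the expected sample SD of run means is then ≈ 1.38% overall and
  ≈ 0.81% below the threshold (E[SD of 2 draws] = σ·√(2/π)).  Values are
  clipped to [0, 100] and the clip fraction is reported (≈ 1–2% under
  defaults).
* **Survival** — proportional hazards on the true category and age group:
  Weibull baseline (shape 1 = exponential, the default) with baseline
  (gray-zone, under-65) median 12.5 months; HR(methylated:gray) = 0.53,
  HR(unmethylated:gray) = 1.8, HR(age ≥ 65) = 2.5.  The baseline median is
  set above the cohort target because the category and age hazards shift the
  mixture: the realized cohort Kaplan–Meier median is ≈ 10.5 months.
  Censoring is administrative over a uniform accrual window (default 38
  months → ~62% deaths; validation preset 13 months → ~39%).  Ages are
  N(57.5, 12²) clipped to [18, 90] (~27% over 65); sex is 64% male and
  carries **no** survival effect, so sex-adjustment sensitivity tests have a
  known null.
* All randomness flows through one `numpy.random.Generator` seeded from a
  single integer; no global state.

What the generator does *not* emulate: assay chemistry, bisulfite-conversion
efficiency, FFPE artefacts, tumor-purity dilution, per-site systematic
offsets, non-proportional hazards, and informative censoring.  Passing tests
on these cohorts therefore demonstrate that the pipeline recovers a
category-structured proportional-hazards signal under realistic marginal
distributions and replicate noise — not that any particular clinical cohort
will yield a gray zone.

## Statistical power of the sweep

The conjunctive qualification rule needs both gray-zone contrasts
significant.  With the development-regime occupancy (~14% of samples in the
gray band) and ~60% deaths, a cohort of 300 carries only ≈ 25–30 gray-zone
events, so SE(log HR unmethylated:gray) ≈ 0.25 against an effect of
log 1.8 ≈ 0.59 — roughly 65% power for that single contrast, and less
jointly.  Even an oracle handed the true categories qualifies in only about
60–65% of such cohorts; correspondingly, across simulated cohorts of n = 300
the sweep returns a boundary near the true g in roughly two-thirds of runs
and "none" in roughly one-fifth (the acceptance suite measures this
recovery curve).  At n ≈ 115 with ~40% events and a sparse intermediate
band, "none" is the typical outcome — the same power failure a small
validation cohort exhibits.  Practical advice follows: check the number of
*events* in the prospective gray band, not just the cohort size, before
applying the method.

## Degenerate inputs and determinism

Empty categories, constant covariates and singular information matrices are
reported per-candidate rather than aborting the sweep; cohorts with no
events, no complete runs or fewer samples than sites fail fast with typed
errors (the CLI maps input errors to exit 2 and configuration errors to
exit 3; a "no gray zone" decision exits 0).  Reports contain no timestamps
and are written with sorted keys, so identical inputs and configuration
produce byte-identical output; NaN and ±∞ serialize as `null` / `"inf"` /
`"-inf"` tokens.
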
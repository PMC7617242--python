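# Methods

## Scope and model

`cotrial` analyzes coclinical trials in patient-derived tumor xenografts
(PDTX): cohorts of mice carrying a patient's tumor are treated in parallel
with the patient, and the in vivo drug response is compared with the
patient's clinical outcome (pathologic complete response, pCR, vs
non-pCR).  The analysis layer covers five stages — in vivo growth
modeling, drug-response metrics and concordance, ex vivo dose–response
screens, mutation dynamics, and metacell phenotype scores — each fed
either by measured data in plain-text formats or by the package's own
synthetic-data generators.

### Tumor growth model

Tumor volume is computed from calipers as TV = W²·H/2 (mm³).  Growth is
assumed exponential, so log volume is linear in time.  For one PDTX model
with arms g (reference: untreated) the mixed model is

    log TV_it = β₀ + β_g + (β₁ + δ_g)·t + u0_i + u1_i·t + ε_it

with per-mouse random intercepts and slopes (u0, u1) ~ N(0, G), G an
unstructured 2×2 covariance, and iid residuals ε ~ N(0, σ²).  Estimation
is REML (ML optional) via statsmodels `MixedLM`.  Key conventions:

- natural logs throughout; "log-daily growth rate" is in 1/day;
- time origin t = 0 at enrollment/treatment start, days as integers;
- volumes below 1 mm³ (regressed/unmeasurable tumors) are floored at
  1 mm³ before the log transform and counted on the fit object; strictly
  negative volumes are rejected;
- a perfect-fit (zero-residual) dataset short-circuits to the OLS solution
  with zero variance components and `singular=True`; a fitted variance
  component pinned at numerical zero likewise sets the `singular` flag
  rather than failing silently.

Inference on fixed-effect contrasts c'β uses t statistics with
Satterthwaite degrees of freedom, computed in-package: df =
2·(c'Vc)² / Var(c'Vc), where the variance of the contrast variance comes
from the delta method with a numerically differentiated REML Hessian over
(G₀₀, G₀₁, G₁₁, σ²).  When the fit sits on the boundary or the Hessian is
not usable, the residual df (n_obs − n_fixed) is the fallback.  On
simulated two-arm trials with 5 mice/arm this yields df ≈ 8 for the
slope-interaction contrast, matching lme4/lmerTest (cross-checked in the
test suite via Rscript); calibration simulations show 95% CI coverage
≈ 95–97% and type-I error ≈ 3–5% at α = 0.05.

### Response metrics

From one fit, per treated arm:

1. `delta_growth_rate` — δ_g, change in log-growth rate vs untreated;
2. `delta_auc` — difference in area under the marginal log-volume curve
   over [0, T].  Because the marginal curves are linear in t this equals
   β_g·T + δ_g·T²/2 exactly, a linear contrast of the fixed effects, so SE,
   CI and p come from the same t machinery.  The AUC lives on the modeled
   (log) scale; a raw-scale variant (trapezoid of the exponentiated
   curves, point estimate only) is available via `scale="raw"`;
3. `growth_rate_on_treatment` — β₁ + δ_g with SE from the full contrast
   variance including the covariance term;
4. `end_volume` — exp of the conditional (BLUP) prediction at T per
   mouse, one value per mouse.

T defaults to 77 days (11 weeks).  The printed dosing cycle structure
(4 × 21-day cycles) is kept intact for schedules even though the analysis
window is 77 days; the two constants disagree by one week in the source
regimen and the package treats the window as the analysis constant and
the cycle structure as the dosing truth.

Concordance with pCR labels: two-sided Wilcoxon rank-sum per metric
(exact distribution when both groups ≤ 12 and untied, otherwise normal
approximation with continuity correction and midranks), Benjamini–Hochberg
correction across the family of per-metric tests.  For the per-mouse end
volumes both analysis modes are possible; the default pipeline pools
mouse-level values within the pCR groups.

The 3×3 sequential-treatment (factorial) analysis fits one mixed model
per second-line treatment with the first-line treatment as the grouping
covariate (reference: first-line untreated) and reports all four metrics
per (first-line, second-line) cell.

### Trial design utilities

Fixed human doses convert to mouse doses by relative body mass
(60 kg : 20 g = 3000:1); per-weight doses are mg/kg × mass.  Spiral
stratified randomization ranks enrollment volumes low→high and assigns
cohorts boustrophedon (1..k, k..1, ...), ties broken by (volume, mouse id)
stable sort; when k does not divide n the last sweep truncates, so cohort
sizes differ by at most one.  The carboplatin design-1 dose (0.16 mg,
from a human AUC5 dose) is stored as a constant because the
pharmacokinetic inputs behind it are not available; paclitaxel design 1
uses the tolerability-adjusted 0.07 mg.

### Ex vivo screens

Observed response (%) = 100 − 100·(I − neg)/(pos − neg).  With this
formula the response is 100 at the negative-control intensity and 0 at
the positive-control intensity, i.e. it behaves as a percent-effect
scale; accordingly the synthetic generator treats the negative control as
background and the positive control as full (untreated) viability, and a
direction flag exists because control identities vary between assay
setups.  Isotonic regression (scikit-learn, pool-adjacent-violators)
fits the replicate responses monotonically over dose — non-decreasing
with concentration by default.  The AUC is the trapezoid integral of the
fitted curve over log10 concentration, normalized by 100 × the log10 dose
range so it lies in [0, 1] for responses in [0, 100] and is comparable
across drugs and dose grids (per-drug grids, e.g. a 10-fold lower grid
for poorly soluble compounds, are supported).  Sensitization by a prior
in vivo treatment is the AUC shift post-treated minus untreated.

### Mutation dynamics

Presence = VAF ≥ threshold (default 0.05, a typical exome detectability
level; configurable).  Emergent: present in zero untreated samples and
≥ 1 treated/post-treated sample.  Depleted: present in ≥ 2 distinct
untreated *mice* (multi-region samples of one mouse count once) and zero
exposed samples.  These classes are mutually exclusive at any threshold,
and raising the threshold can only retire a call to "none", never flip it
(property-tested).  When an `effect` annotation is present the universe
is restricted to nonsynonymous SNVs, frameshift indels and stop-gains.
Cross-sample concordance is Spearman correlation over variants present in
either sample (absent = VAF 0).

### Metacell phenotype scores

Cell QC keeps cells with ≥ 750 non-mitochondrial UMIs and a
mitochondrial fraction strictly below 0.40.  Per-metacell enrichment is
e_{g,m} = log2((f_{g,m} + ε)/(f_{g,pool} + ε)) with ε = 1e−5 on the
fraction scale.  Epithelial / mesenchymal / IER scores average enrichment
over the 50 genes whose enrichment profiles correlate best (Pearson,
across metacells) with the anchors KRT81, VIM and JUNB respectively.  The
EMT continuum (epithelial, EM-hybrid, EM-hybrid-IER and mesenchymal
metacells) is stratified into 5 groups by mesenchymal-minus-epithelial
score; the IER axis (EM-hybrid and EM-hybrid-IER metacells) into 4 groups
by IER score.  Binning is equal-width over the observed score range
(quantile binning behind a flag) — the choice is open in the source
analysis, and equal-width keeps gaps between well-separated clusters as
stratum boundaries.  TF trajectories are mean enrichments per stratum;
state composition is the percentage of each condition's cells per state.
State labels and metacell partitions are consumed as input; deriving them
is out of scope.

## Synthetic data: what it emulates and what it does not

The growth generator runs the mixed model forward (defaults: β₀ =
log 100 — enrollment at ~100 mm³ as in the fixed-volume trial design,
β₁ = 0.05/day ≈ 2-week doubling, sd_u0 = 0.2, sd_u1 = 0.005/day, zero
intercept–slope correlation, σ = 0.2, weekly measurements over 77 days,
5 mice/arm).  The random-effect and residual magnitudes are calibration
choices — the source analysis does not report them — picked to produce
visible mouse-to-mouse growth heterogeneity (slope scatter about one
sixth of a strong treatment effect) and ~20% multiplicative measurement
noise, typical of caliper data.  The generator does not model engraftment
failure, immune compartments, time-varying effects or measurement
dropout, so passing tests demonstrate estimator correctness under the
modeled assumptions, not robustness to their violation.

The screen generator uses a decreasing Hill viability curve (EC50 0.3
µmol/L, slope 1, 5% viability floor, 5% CV multiplicative noise, 3
technical replicates on the standard 7-dose grid, 16 + 16 control
wells).  The variant generator plants a clonal backbone (per-variant base
VAF shared across samples) plus emergent / depleted / private variants
obeying the classification rules; private variants are placed in an
untreated sample because a variant private to an exposed sample is
emergent by definition.  The metacell generator mixes epithelial /
mesenchymal / IER / mitochondrial gene programs per metacell
(multinomial UMIs, default epithelial→mesenchymal gradient with IER
bumps on hybrid metacells) so the score and stratification machinery has
recoverable planted structure.

## Numerical choices

- Satterthwaite df: central finite differences, relative steps 1e−5
  (gradient) and 1e−4 (Hessian); df clipped to [1, residual df];
  fallbacks as above.
- Isotonic ties: replicate wells at one dose share the pooled block value.
- Wilcoxon: exact only when both groups ≤ 12 and untied.
- Degenerate stratification (all scores equal) yields a single stratum
  with a warning rather than an error.
- Seeds: every generator takes an explicit seed; the pipeline derives
  per-stage child seeds below 2³¹ from the run seed, so reruns are
  byte-identical.

## Problem sizes in the shipped checks

The calibration suites use 500 trials (effect recovery and CI coverage at
δ = −0.03, n = 5/arm) and 1000 trials (type-I error under the null); the
end-to-end concordance check uses 20 seeded runs of the eight-model demo
panel.  These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands while keeping a full run in the minutes range.

## Known limitations

- Satterthwaite df is approximate near variance boundaries; singular fits
  fall back to residual df, which is anti-conservative when random-slope
  variance is truly present but estimated at zero.
- The AUC metric inherits the log scale of the model; raw-volume AUC is
  exposed only as a point estimate.
- Automatic cell-state calling from markers is deliberately not provided;
  states are metadata.
- The spiral randomizer balances ranks, not volumes; with heavy-tailed
  volume distributions cohort volume means can still differ.
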
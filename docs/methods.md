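# Methods

## Model

The analysis targets mediation in a four-wave panel: does a psychosocial
work characteristic X (demands or social support) influence later
depressive symptoms Y partly by changing an unhealthy behavior M?  All
three constructs are measured repeatedly (biennial waves), and the model
is a lag-1 autoregressive cross-lagged system: each construct at wave t+1
is regressed on every construct at wave t.  Autoregressive paths absorb
rank-order stability; cross-lagged paths carry the hypothesized (and the
reverse-direction) effects; paths are freed per transition because
equality-over-time constraints are rejected on data with time-varying
dynamics (the nested chi-square difference test is part of the toolkit).
Within-wave disturbance covariances and — in latent routes — cross-wave
covariances between the errors of the same item account for contemporaneous
association and item-specific stable variance.

Demands (4 items), support (5 items) and depressive symptoms (6 items) are
latent variables with the first loading fixed to 1; behaviors are binary
single indicators.  Ordinal and binary observations follow the
latent-response (probit) formulation: an item with K categories is a
thresholded standard-normal response, so a binary behavior is
indicator(M* > τ) with prevalence 1 − Φ(τ).

## Effect decomposition

After fitting, the structural solution is a DAG over (construct, wave)
nodes whose edges carry standardized coefficients.  The overall effect of
X@wave1 on Y@wave4 decomposes over forward paths:

* indirect = Σ over paths visiting at least one M node of the product of
  edge coefficients;
* direct = the same sum over paths avoiding M;
* total = direct + indirect (an identity of the calculus, tested to
  1e-12 against an independent matrix-product oracle: total is the (Y, X)
  entry of the ordered product of per-transition coefficient matrices, and
  the direct part repeats the product with all edges into M removed).

Standardization multiplies each raw coefficient by sd(source)/sd(target)
under the model-implied latent covariance — recommended practice when
mediators are binary, since raw probit-scale coefficients are not
comparable across models.

Uncertainty is propagated by Monte Carlo simulation: 20,000 coefficient
vectors are drawn from a multivariate normal centered at the estimates
with the fitted covariance (structural coefficients only; loadings,
thresholds and the standardization ratios are held at their point
estimates), the decomposition is recomputed per draw, and percentile
intervals are reported.  Intervals are plain percentile (not
bias-corrected), matching the standard form of the Monte Carlo CI method.
The proportion mediated indirect/total is flagged "not interpretable"
unless |total| is materially nonzero and its CI excludes zero.

## Screening and gating

Mediation models are fitted only for behaviors that pass a two-leg screen:
bivariate cross-lagged models (exposure–behavior and behavior–outcome,
both directions freed per transition) must each show at least one
significant forward path at two-sided α = 0.05.  No multiplicity
correction is applied — this is deliberately liberal screening, erring
toward fitting a mediation model.  Reverse-direction paths are always
estimated and reported but never enter the gate.

## Estimation routes

The instruments are ordinal and the behaviors binary, which strains
normal-theory SEM; conversely, categorical estimators complicate missing
data handling.  The package therefore exposes both routes explicitly:

* **wls (categorical-faithful).**  Step 1: item thresholds from univariate
  margins (normal quantiles of cumulative proportions) and pairwise ML
  polychoric/tetrachoric correlations with thresholds fixed (Olsson
  two-step); polyserial for continuous×ordinal pairs and Pearson for
  continuous×continuous (baseline covariates).  The bivariate normal CDF
  is a vectorized 20-point Gauss–Legendre scheme with the high-correlation
  tail expansion, accurate to ~1e-10.  Step 2: diagonally weighted least
  squares on the off-diagonal correlations, weights = inverse asymptotic
  variances.  The asymptotic covariance Γ of the correlation vector is
  assembled from per-observation influence functions (pair score over unit
  expected information, thresholds treated as fixed); Γ feeds sandwich
  standard errors and the mean-scaled test statistic T·df/tr(UΓ).
  Including threshold-estimation uncertainty in Γ (the full weight matrix)
  is a known refinement not implemented here; with the moderate thresholds
  of these instruments its effect on the correlations' variances is small.
  Binary/ordinal variables use the delta parameterization: latent-response
  variances are fixed at 1, so item residual variances — and the
  disturbance variance of a single-indicator construct — are derived
  quantities, not free parameters.
* **ml (missingness-faithful).**  Items treated as continuous under a
  normal-theory likelihood; with `missing_policy="fiml"` the casewise
  likelihood is evaluated per missingness pattern and the saturated
  loglikelihood for the chi-square comes from an EM estimate of the
  unrestricted mean/covariance.  The independence baseline has a closed
  form.

A recursive path model in which every construct is observed (single
indicator, no constraints) has closed-form ML: per-equation OLS, extended
with cross-equation coefficient covariances when equations share a
regressor set (the seemingly-unrelated-regressions equivalence).  The
engine detects this case and uses it; the general optimizer is verified
against it in the tests.  This observed-variable route powers the
replicated simulation studies, where fitting thousands of measurement
models would be waste.

Numerical choices: L-BFGS-B with up to three seeded jittered restarts and
a high-precision (3-point gradient) polish pass; convergence at gradient
norm < 1e-6; covariance matrices via eigenvalue-clipped pseudo-inverses;
non-positive-definite Monte Carlo vcov repaired to the nearest PSD matrix
(logged); polychoric estimates at the boundary clipped to ±0.999 with a
warning.  Fit indices use the standard definitions
CFI = 1 − max(χ²_m−df_m, 0)/max(χ²_m−df_m, χ²_0−df_0, 0) and
RMSEA = sqrt(max(χ²_m−df_m, 0)/(df_m(n−1))).

## Scoring rules

Demand/support composites are means of the 1–4 items (missing if more than
half the items are missing — the instruments' sources are silent on this,
so the fraction is configurable).  The six depressive items (0–4) are
summed to 0–24, missing if any item is missing by default.  Excessive
drinking is consumption-based in the first two analysis waves (men ≥ 21
units/week, women ≥ 14, or ≥ 6 units per occasion at least weekly) and
CAGE-based (≥ 2 of 4 items) thereafter, reflecting the instrument change
between those waves; which instrument the final wave used is not
documented, so the per-wave assignment is configurable.  Smoking is daily
vs. other (sensitivity: any smoking), diet unhealthy vs. other categories,
inactivity never/very little vs. active (sensitivity: adding "now and
then" to the inactive side).  The behavior count sums the four indicators.

## Synthetic cohort generator

The generator emulates the study conditions: N = 3,706 subjects over four
waves; latent demands, support, four behavior propensities and depressive
symptoms evolving by the lag-1 system; ordinal items via loadings and
thresholds; binary behaviors as deterministic thresholdings of their
propensities.  Innovation variances are solved so that every construct has
unit variance at every wave — hence the generating coefficients are
standardized coefficients, and `true_effects` returns the exact
total/direct/indirect effects as matrix-product path sums, giving every
downstream stage an analytic ground truth.  Wave-1 latents are drawn from
the fixed point of the covariance recursion (the stationary start).

Default calibration targets the published baseline marginals: thresholds
chosen so demand/support composites average ≈ 2.6 / 3.1, behavior
prevalences ≈ 8.3% (smoking), 5.2% (alcohol), 6.8% (diet), 16.1%
(inactivity), and a right-skewed depressive score (observed mean ≈ 4.8
against the reported 5.4; exact matching of the skewed composite is not
attempted).  Cross-lagged defaults concentrate small negative
support→behavior and positive behavior→depression effects with a direct
support→depression path, and give demands no behavior paths — the regime
the screening stage should rediscover.  Baseline covariates (age, sex,
civil status, education with realistic marginals) shift wave-1 latent
means only.  Missingness is cell-level MCAR or MAR (masking probability
increasing in the observed wave-1 driver score); whole-subject informative
dropout is out of scope.

What the generator does not emulate: non-normal latent innovations,
time-varying covariates, measurement non-invariance, instrument changes
mid-panel (behaviors are generated as indicators directly), and real-world
item wording effects.  Passing tests therefore demonstrate correctness of
the machinery under the model's own assumptions, not robustness to their
violation.

## Simulation studies and problem sizes

The replicated studies use the observed-variable X/M/Y variant (AR 0.5,
X→M 0.2, M→Y 0.2, X→Y 0.15; null variant X→M 0, M→Y 0.3): 500
replications at n = 500 for interval coverage and null calibration, 50
replications at n = 2000 for observed-route recovery, and 10 replications
for the latent DWLS route (bivariate 5-item support construct with a
binary behavior), each replication a full measurement-model fit.  Observed
coverage of the 95% interval pools to ≈ 95% across seeds; the null
false-positive rate sits near the nominal 5% — with three mediating paths
each containing exactly one zero coefficient times nonzero factors, the
indirect estimator is approximately linear at this null rather than the
doubly-degenerate single-product case, so near-nominal (not conservative)
calibration is expected.

## Design notes and limitations

* The source analysis reports both a categorical robust-WLS estimator and
  full-information ML; these are not jointly implementable as printed, so
  they are exposed as the two routes above — wls as the reference
  categorical analysis, ml/fiml as the missingness-faithful sensitivity.
* Baseline covariates enter as exogenous predictors of the wave-1
  constructs only.  A consequence worth knowing: in the recursive
  observed-score route the lag-1 coefficients condition on the previous
  wave and are exactly invariant to this form of adjustment.
* Wave bookkeeping: effects run from X at analysis-wave 1 to Y at
  analysis-wave 4 (the four analysis waves map to 2008–2014).
* Whether within-wave residual construct correlations should be freed at
  every wave was an open choice; they are freed at all waves by default.
* Monte Carlo draws cover structural coefficients only; drawing
  measurement parameters as well would widen intervals slightly.
* The latent DWLS route's sandwich omits threshold uncertainty (above);
  single-indicator binary mediators are modeled on the latent-response
  scale, so their "measurement error" is not separable.
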
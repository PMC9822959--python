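# Methods

This note documents the statistical machinery in `stockshift`, the choices
made where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## Data model

A stock is an aligned annual triplet (SSB in tonnes, recruitment in
thousands at a stated age, fishing mortality per year) on a gap-free
calendar-year axis; missing values are explicit (NaN) and excluded pairwise
per analysis, never imputed. Recruitment reported at age *a* in assessment
year *y* is attributed to spawn year *y − a*, so a stock–recruitment pair
(S<sub>t</sub>, R<sub>t</sub>) relates parent biomass to the offspring it
produced. Units are taken as labelled in the input files; no conversion is
attempted.

## Flag 1 — abrupt changes in SSB

**Binary segmentation.** Greedy recursive search for changes in mean. The
split is chosen to maximize the within-segment SSE reduction; it is accepted
only if the Gaussian log-likelihood gain with segment-wise re-estimated
variance exceeds an MBIC-style penalty (default `3 log n`) and both children
have ≥ `min_segment` observations. Choosing splits by SSE keeps the search
equal to the brute-force minimum-SSE segmentation on well-separated steps,
while the segment-wise-variance gate makes the accept/reject decision
invariant to affine transformations of the data. `min_segment` defaults to
5 years — the same quasi-stability floor the consensus rule uses — and
`max_changes` to 5. Degenerate (zero within-segment variance) costs are
floored at 10⁻¹² of the overall variance, which preserves scale invariance.

**Bayesian product-partition sampler.** The change-in-mean partition model
with block means shrunk toward a common level (prior variance inversely
proportional to block size), U(0, p₀) prior on the change probability and
U(0, w₀) on the signal-to-noise ratio w = σ²/(σ²+σ₀²); integrating means,
level and variance analytically leaves, for a partition with k blocks,
a marginal ∝ ∫p^(k−1)(1−p)^(n−k)dp · ∫w^((k−1)/2)(W+Bw)^(−(n−1)/2)dw with
W/B the within/between block sums of squares. Each interior boundary
indicator is Gibbs-resampled from its full conditional; the two
one-dimensional integrals are evaluated by 24-node Gauss–Legendre quadrature
in log space, and block sums come from prefix sums so one update is O(block
length). Defaults: p₀ = w₀ = 0.2, 5000 sweeps, 500 burn-in, declaration
threshold 0.5 on the posterior change probability; runs are deterministic
given the seed. A zero-variance series returns an all-zero posterior with a
warning. Within a run of consecutive above-threshold positions only the
local posterior maximum is declared, since posterior mass for one change
often smears over two adjacent boundaries.

**Consensus.** A change is declared where the two detectors agree within
±1 year (each candidate matches at most once, greedily in year order); the
binary-segmentation year is reported because that method is deterministic.
Consensus years closer than 5 years are thinned by keeping the higher
posterior. Periods tile the observed range, period k ending the year before
change k+1.

## Flag 2 — hysteresis in the lagged F → SSB relationship

The lag n in F<sub>t−n</sub> → SSB<sub>t</sub> is the maximizer of the
absolute cross-correlation over lags 0–10 (ties to the smaller lag). The
lagged pairs, in temporal order, enter an exact dynamic-programming
multiple-break regression (minimum total per-segment OLS RSS for each break
count m; m selected by BIC with 2(m+1)+m parameters; segments at least
max(3, ⌈0.15·n⌉) observations). RSS alone cannot select m — it is monotone
in m — hence the information criterion. Segments with no predictor variance
fall back to intercept-only fits and are flagged.

The loop classifier splits the trajectory at the year of maximum smoothed F
(5-year moving average) into an ascending-pressure and a descending-pressure
branch and compares branch SSB over the shared F range in 5 equal-width F
bins (all bins must be populated by both branches, otherwise
*indeterminate*). A loop requires both a Welch-test significant branch
difference (α = 0.05) *and* a branch gap of at least 10% of the observed SSB
range; the effect-size gate exists because sampling error alone makes ~5% of
truly reversible trajectories "significant". The *pre-collapse period* is
the ascending branch until SSB first falls below half its running maximum
(the collapse itself happens on the way up once F crosses the fold and must
not contaminate the reference range). A significant loop is *closed* when
the final five years' mean SSB re-enters the pre-collapse range, *open* when
it stays below the pre-collapse minimum although mean final F is at or below
the largest F that sustained that biomass before the collapse.

## Flag 3 — non-stationary stock–recruitment relationships

Candidates: Beverton–Holt `R = αS/(1+βS)` and Ricker `R = S·e^(α−βS)` under
multiplicative lognormal error (the fisheries standard; the Ricker fit is the
exact closed-form OLS of log(R/S) on S, the Beverton–Holt a bounded
trust-region NLS on the log scale started from the 1/R-vs-1/S linearization
with a small restart grid), a linear and a log-log linear model, a
one-breakpoint segmented (G)LM, and the temporal breakpoint regression of
flag 2 applied to (S, R) in spawn-year order. The segmented model uses the
iterative linearization (working covariates U = (S−ψ)₊ and V = −1[S>ψ],
update ψ ← ψ + γ̂/δ̂) started at mean S; when the iteration cycles — which
happens when ψ is weakly identified, e.g. on straight-line data — the
best-RSS ψ of the recent iterates is taken and flagged, so the null case
surfaces as "no supported break" rather than an error. After convergence a
deterministic local grid (width ±8% of the S range at range/1000 resolution)
replaces ψ only when it strictly lowers the RSS: the broken-line RSS is
piecewise smooth with kinks at the data, and the fixpoint can stop one basin
away from the optimum. GLM families for the segmented model are chosen from
the Pearson dispersion φ of a Poisson fit: Poisson for φ ∈ [0.8, 1.2],
quasi-Poisson for moderate over- (or any under-) dispersion, negative
binomial for φ > 5, Gaussian for non-count (rescaled) recruitment.

Models compete by leave-one-out cross-validation with all errors on the raw
recruitment scale; the *winner is the model with the lowest training RMSE*
(training fit is the relevant notion when the question is whether the
historical relationship was discontinuous; the test RMSE is reported
alongside as predictive skill). A candidate failing any fold is excluded and
reported. Because training RMSE is monotone in model flexibility, the
pipeline flags non-stationarity only when the discontinuous winner is also
*supported*: the breakpoint regression must have retained ≥ 1 break under
BIC, and the segmented model must have a significant slope difference *and*
beat the linear model on BIC — the Wald test at an estimated breakpoint is
anti-conservative on its own.

## Temperature flag — threshold GAM

Smooths are penalized regression splines: a uniform (unclamped) B-spline
basis of dimension k (cubic for k ≥ 4, else degree k−1) with a
second-difference coefficient penalty. With uniform knots the penalty null
space is exactly the linear functions, so the heavy-smoothing limit is the
least-squares line. λ is selected on a 57-point log grid (10⁻⁶–10⁸) by
GCV = n·RSS/(n − tr S)²; GCV valleys are typically flat near the minimum, so
among grid points within 0.5% of the minimum the smoothest fit is taken
(this also resolves the exact ties that arise when the data lie in the
penalty null space). Reported edf = tr(S) − 1, so edf 1 means a linear fit
(values ≤ 2 weakly, > 2 strongly non-linear); the GCV denominator uses the
full trace. The per-λ profile is computed from one generalized
eigendecomposition per design, so a whole grid costs one k×k eigenproblem.

The threshold GAM fits separate k = 4 smooths of recruitment on SSB for
observations below/above a candidate SST threshold; candidates are 20 evenly
spaced values between the 0.2 and 0.8 SST quantiles, skipping any that
leaves a regime under 5 observations. The two-regime model with a shared
intercept spans exactly the same fit space as two independent per-regime
fits (each uncentered regime basis absorbs a constant), so it is computed
that way, with the joint GCV using edf = tr_below + tr_above − 1 to count
the intercept once. Candidates falling between the same two observed SST
values induce identical partitions, making the GCV profile piecewise
constant; the reported threshold is the central candidate of the minimizing
plateau rather than its edge. Regime "slope" significance is the Wald p of
the OLS linear trend through the regime's smooth predictions at the data
points (a smooth has no single slope; an exactly linear nonzero trend gives
p = 0, an exactly flat one p = 1).

The decision is a conjunction: LOOCV (with the threshold re-selected inside
each fold) must prefer the tGAM over the plain k = 3 GAM, the regime edfs
must differ by ≥ 0.5, at least one regime slope must be significant at 0.05,
and the GCV profile minimum must lie ≥ 5% below the profile median (the
valley-depth default was calibrated on no-effect simulations to keep the
null acceptance rate below one in ten). Because the verdict is a
conjunction, the expensive LOOCV is skipped when the three cheap criteria
already fail; the LOOCV flag is then reported as undetermined. The lag-1
autocorrelation of the tGAM residuals is reported as a diagnostic and never
gates the verdict.

## Synthetic stocks

`simulate_stepped_series` — piecewise-constant mean plus stationary AR(1)
noise, for change-point benchmarks.

`simulate_hysteretic_stock` — discrete-time harvested population
B′ = B + r·B·(B/A − 1)(1 − B/K) + ι − f·B, multiplied by lognormal process
noise and floored at 10⁻⁶K. With A = 0 the growth term is plain logistic and
the equilibrium SSB(F) map is single-valued (reversible). With A > 0 the bare
map makes the collapsed state absorbing even at f = 0 (below A the stock
always declines), so a genuine fold requires the small immigration/refuge
inflow ι, defaulting to 1.2× the maximum low-biomass decline rate — just
enough that the collapsed branch loses stability at a positive F. The fold
levels are never assumed: `equilibrium_continuation` iterates the noise-free
map from the carrying capacity and from the floor over an F grid (step 10⁻³,
recorded in the truth object) and reports the largest F keeping the upper
branch high (collapse_F) and the largest F from which the floor still
recovers (recovery_F). Recruitment is emitted through a Ricker SRR applied
to spawn-year biomass, reported at the recruitment age.

Benchmark scenario defaults (the study conditions used by the tests and the
acceptance script): K = 1000 t, r = 0.5 yr⁻¹, A = 0.2K, 5% lognormal process
noise, F ramped 0 → 1.2·collapse_F over 40 years, back down over 40 years,
then held 40 years at the floor. r = 0.5 keeps the upper basin wide enough
that 5% noise cannot eject the stock over the basin edge above K (the
additive Allee map is violently unstable above ≈1.15K at r = 0.8), and the
40-year hold covers the ≈28-year transit of the Allee valley during recovery
at F = 0.

`simulate_diagnostic_stock` — the canonical end-to-end scenario. The
all-effects variant adds a 20-year unfished spin-up, then the ramp above,
and generates recruitment from an SST-switched SRR under a warming trend
(10 → 17 °C over 140 years, interannual noise 0.15 °C) crossing the 12 °C
threshold around year 50, i.e. while the stock is still on its densely
sampled upper branch: the cold regime is then a strong linear SSB→R
relationship over the pre-collapse biomass cluster and the warm regime a
weak dome over the full collapse-and-recovery range — regimes that differ in
slope, shape (edf) and level. The two regime curves intersect at the biomass
the stock holds when SST crosses the threshold (≈750 t), so the inevitable
boundary-year misassignments carry no information either way. Recruitment
error in this scenario is additive Gaussian (sd 60 t): the temperature flag
runs on GCV-smoothed raw-scale fits, and GCV assumes constant error
variance. The null variant uses reversible dynamics under gently varying F
(AR-correlated around 0.15 yr⁻¹), a single stationary Ricker SRR with 10%
lognormal noise, white 5% observation error on SSB, and SST with no effect.

What the generators do **not** emulate: age structure and assessment-model
smoothing (real ICES series are outputs of statistical catch-at-age models,
with strong serial correlation in their errors), density-dependent growth or
maturation, fishery selectivity changes, and environmental covariates beyond
a single SST series. Passing the benchmarks therefore demonstrates that each
stage recovers the structure it targets under clean, known dynamics — not
that the flags are unconfounded on real assessment output.

## Numerical choices and degenerate inputs

- Change-point and breakpoint positions follow the period-start convention
  (a change at year y means the new period begins in y).
- Binary-segmentation tie-breaks go to the earliest split; GCV ties to the
  smoothest fit; lag-selection ties to the smaller lag.
- The Beverton–Holt β is bounded below by −(1−10⁻⁹)/max(S) so the predicted
  mean stays positive; negative estimates are flagged, not rejected.
- B-spline predictions clamp the predictor to the knot range (constant
  extrapolation at the boundary values).
- Zero-variance inputs raise errors in lag selection and linear fits, fall
  back to intercept-only segments in breakpoint regressions, and return
  all-zero posteriors (with a warning) in the Bayesian sampler.
- All simulation seeds are plain integers below 2³¹; every stochastic
  routine is bit-reproducible given its seed.

## Known limitations

- Plain GCV undersmooths with non-vanishing probability: on a truly linear
  regime of n ≈ 40–60 points the fitted edf exceeds 1.5 in roughly 10–15% of
  replicates, so the "edfs differ" criterion of the temperature flag has an
  irreducible per-dataset failure rate of the same order on regime pairs
  that include a linear limb. The conjunction with the LOOCV gate protects
  the null direction (measured null acceptance ≈ 8–9%), not the power.
- The lowest-training-RMSE winner rule favors flexible models by
  construction; the support gate (BIC + slope-difference significance)
  restores calibration for the pipeline flag but is itself a package
  operationalization.
- The mean-change detectors assume exchangeable within-period noise;
  strongly autocorrelated fluctuations (map eigenvalue ≳ 0.6 in the
  generator, slow assessment-error correlation in real data) produce genuine
  level excursions that both detectors will flag. That is a property of the
  method, not a bug in the implementation.
- The hysteresis classifier's thresholds (10% branch gap, five matched bins,
  half-of-running-max collapse marker) are explicit operationalizations of a
  judgement the underlying approach makes visually; they are calibrated on
  the reversible null (zero false loops in 100 replicates) but are not
  universal constants.
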
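# Methods

This note records the statistical models, the numerical choices behind
them, what the synthetic surveys do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Joint discrete–continuous trip-distance model

**Model.**  For each trip, mode choice over {walk, car, transit} follows a
multinomial logit with linear utilities `V_m = γ_m'z` (reference mode:
car, the most frequent mode; its utility vector is fixed at zero).  Given
the chosen mode *m*, log distance is normal: `ln d = θ_m'z + σ ε_d`.  The
design `z` is `[1, encoded covariates, trend terms]`.  Selectivity is
introduced through Lee's transformation: the selection event for the
chosen mode and the distance error are mapped to standard-normal scores
assumed jointly bivariate normal with correlation ρ.  The per-trip
density is

    f(d, m) = (1/(σ_m d)) φ(u) Φ( (Φ⁻¹(P_m) − ρ_m u) / √(1−ρ_m²) ),
    u = (ln d − θ_m'z)/σ_m ,

whose integral over *d* is exactly `P_m` (so the discrete margin is the
MNL), and which at ρ = 0 factorizes into the product of the MNL
probability and the log-normal density — both facts are asserted by tests.

**Pooling.**  By default one σ and one ρ are shared across modes
(`pooled=True`), matching how a single log-distance scale and a single
discrete–continuous correlation are conventionally reported for this
model; `pooled=False` estimates per-mode values.  The pooled model is
nested in the free one (tested).

**Prediction.**  `predict_distance` returns the log-normal *mean*
`exp(θ'z + σ²/2)` because the downstream expected-distance overlay needs
an expectation; the median `exp(θ'z)` is available via `kind="median"`.

## 2. Trivariate ordered probit for trip frequency

Latent propensities `t*_j = β_j'x + ε_j` per mode with
`ε ~ MVN(0, R)`, R a correlation matrix (probit normalization: unit error
variances, no intercept — the three thresholds per mode absorb location).
Counts are classified as {0, 1, 2, 3+}; the open class pools three or
more trips, which are rare in senior diaries.  A person's likelihood is
the MVN probability of the box formed by the per-mode threshold intervals
shifted by `β_j'x`.

**Exact rectangles.**  `method="exact"` conditions on the dimension that
minimizes the remaining conditional correlation and integrates
`φ(t) × (conditional bivariate rectangle)` with 32 Gauss–Legendre nodes
over the (clipped at ±6.8 SD) conditioning interval; the bivariate CDF is
the sine-transformed correlation integral with 8–32 nodes chosen by |ρ|.
The integrand is entire, so convergence is geometric: observed accuracy
is ~1e-8 absolute against scipy's adaptive QMC integrator (tested).  A
diagonal R short-circuits to the exact product of univariate interval
probabilities, making independence factorize to machine precision.
Accuracy degrades gracefully for |conditional ρ| ≳ 0.97 (a nearly
singular R).  Analytic derivatives use the standard reductions: limit
derivatives are `φ(limit) ×` conditional bivariate rectangles; correlation
derivatives follow Plackett's identity.  A numba-compiled kernel, equal to
the numpy reference path to ≤1e-12 (tested), carries the estimation inner
loop.

**GHK.**  The seeded recursive importance sampler is retained as a
cross-check (tested against `exact` within Monte-Carlo error) and as the
route to more than three modes, where deterministic conditioning
quadrature stops being attractive.

## 3. Trend surface and coordinate scaling

Both models include six location covariates: standardized x, y, their
product and squares, and the straight-line CBD distance in km.
Coordinates are z-scored (mean/population-SD of the estimation sample, or
a caller-supplied scaler) before the polynomial expansion; raw projected
metres squared would spread design columns over ~14 orders of magnitude
and destroy optimizer conditioning.  The fitted scaler is serialized
inside each model's JSON so grid prediction reuses the estimation-sample
scaling.  CBD distance is Euclidean; diary records may carry
survey-supplied (e.g. network) distances, which are used as stored.

## 4. Estimation

Both fits maximize the exact likelihood with analytic gradients
(validated against finite differences in the tests) using dense BFGS on
the **per-observation average** log likelihood, converging at gradient
norm 1e-7 on that scale (≈ 5e-4 on the summed scale at n = 5000; a raw
1e-8 summed-gradient tolerance would be below float resolution at
|LL| ~ 1e4).  L-BFGS-B was tried first and abandoned: its Moré–Thuente
line search stalls on this likelihood, triggering the relative-reduction
stop far from the optimum.

Constraints never bind: σ is optimized as log σ, ρ as arctanh ρ,
thresholds as (first cut, log increments), and R through the
partial-correlation (C-vine) map, which is a bijection onto the positive
definite correlation matrices.

Starting values: independent MNL + per-mode OLS on log distance (ρ = 0)
for the joint model; three univariate ordered probits with R = I for the
trivariate model.

Standard errors invert the observed information, obtained by numerically
differentiating the analytic score at the optimum on the natural
parameter scale.  The `FitResult` also carries a constant-only benchmark
log likelihood and McFadden's adjusted ρ² (`1 − (LL − K)/LL₀`).

**Inference on ρ.**  Without exclusion restrictions the selection
correlation is identified only through functional form, and the Wald t on
ρ̂ is badly calibrated in survey-sized samples: in our simulations its
observed-information standard error understates the sampling spread of ρ̂
and shrinks spuriously when ρ̂ drifts large, so the test over-rejects a
true ρ = 0 several times its nominal size at any n we tried.  The package
therefore provides `rho_zero_lr_test`: the restricted (ρ = 0) MLE is
closed-form because the likelihood factorizes, and the
parameterization-invariant likelihood-ratio statistic is compared to
χ²(1).  The test suite verifies its calibration on 20 simulated surveys
of ~9,300 trips; users testing ρ on their own data should prefer the LR
route for the same reason.

## 5. Compliance map algebra

For a fixed profile (all personal and built-environment covariates held
constant) and each grid-cell centroid: predicted walking distance d̂,
walking-frequency class probabilities, then

    TDWD = d̂ (1·P₁ + 2·P₂ + k_cap·P₃₊),  WWM = TDWD · w / s,
    compliance % = 100 · WWM / guideline minutes.

Choices, all configurable: the open class 3+ is valued at `k_cap = 3`
trips (a conservative lower bound — the class is open above); class 0
contributes nothing; w = 5 days/week; s = 68.4 m/min (a published mean
senior walking speed); guideline 150 min/week; compliance is *not* capped
at 100%.  The grid (default 250 m cells) affects visualization only, not
estimation.  `area_by_compliance` reports area per compliance bin plus
explicit underflow/overflow, so total area is conserved under any bin
edges; an optional mask excludes cells (e.g. water).  Rasters serialize
as ESRI ASCII grids plus a long-format CSV.

## 6. Synthetic surveys

`make_default_config` builds a rectangular 30 × 20 km city with uniform
residences, an off-center CBD, and covariates drawn independently per
person (categorical frequencies; a continuous activity-density index
declining linearly with CBD distance).  Frequency classes are drawn from
the ordered-probit model read generatively; each person's realized total
count (class 3+ realized as exactly three trips) sets their number of
trips; each trip's mode comes from the MNL and its log distance from the
Gaussian copula consistent with Lee's transformation — drawing the
chosen mode's selection score as a truncated normal `e | e ≤ Φ⁻¹(P_m)`
and setting the distance score to `ρe + √(1−ρ²)·z`.  This makes the
simulator's law *exactly* the density the estimator maximizes, which is
the premise of the recovery tests.  All randomness flows from two child
streams spawned from the single config seed (persons vs trips), so output
is reproducible and the two stages are independently re-runnable.

The `"full"` preset emulates the broad composition of a large Canadian
metropolitan seniors' diary: mode shares near 17/61/21% walk/car/transit,
mean walking trip ≈ 0.75 km (overall ≈ 5.4 km), ≈ 2.6 trips per person,
log-distance scale 1.084, selection correlation −0.472 and latent
frequency correlations (−0.474, −0.231, −0.656) — values chosen once to
sit at the published magnitudes for such surveys.  The `"compact"` preset
keeps the identical error structure over two covariates plus the trend
surface, for estimator studies.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: correlated covariates (income, licence and
vehicle ownership are independent here), network rather than straight-line
distances, household clustering and within-person correlation beyond the
shared covariates, zero-trip persons absent from out-of-home diaries
(truncation), reporting/recall error, and real built-environment fields
(the synthetic density is a smooth gradient).  Recovery results certify
the estimators under their own assumptions, not robustness to their
violation.

## 7. Study sizes in the test suite

Recovery studies run on the compact preset: 20 seeds × ~5,200 trips
(joint) and 20 seeds × 5,000 persons (frequency), checking ≥95% of true
parameters inside ±3 estimated SE, pooled.  The ρ = 0 study uses 20 seeds
× ~9,300 trips, where the χ²(1) calibration of the LR test holds (the
statistic's null calibration is visibly conservative-to-nominal there;
at half that size occasional marginal rejections appear).  The R = I
study uses 20 seeds × 5,000 persons and checks all |off-diagonal
R̂| < 0.1.  These sizes keep the complete suite at laptop scale (minutes,
one core) while leaving each check's verdict limited by statistics, not
by optimizer or quadrature error.

## 8. Degenerate inputs and edge behaviour

Zero/negative-distance diary rows are dropped and counted at read time
(they carry no length information and break the log transform).  A mode
absent from the trips, an unobserved frequency class, or a rank-deficient
design raises a named estimation error before optimization.  Probability
clipping floors are 1e-15 (MNL) and 1e-300 (rectangles); standard-normal
bounds are clipped at |8.3| SD (below double resolution of the summed
probabilities).  `mnl_probabilities` subtracts the row maximum before
exponentiation and never returns NaN for finite utilities.  Identical
coordinates (zero variance on an axis) raise a degenerate-scale error
rather than silently producing infinite trend terms.

## 9. Known limitations

* ρ is weakly identified without exclusion restrictions (§4); Wald
  inference on it is unreliable and per-mode ρ even more so.
* The `exact` trivariate method is specific to J = 3 outcomes; beyond
  that, use GHK.
* Compliance rasters hold the profile's built-environment covariates
  constant over space; spatial variation enters only through the trend
  surface.  Feeding spatially varying covariate fields would require
  rasterized covariates, which the data model does not currently carry.
* The frequency model conditions on persons appearing in the diary; if
  the survey records only persons with out-of-home activity, the class-0
  probabilities inherit that truncation.
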
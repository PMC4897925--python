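# Methods

`minetown` implements a three-stage analysis of how residential proximity to
industrial point sources (two open-pit mines near a small town) relates to the
prevalence of two binary respiratory outcomes in children, together with a
synthetic-town generator that makes every stage testable by parameter
recovery.  This note records the models, the defaults and why, the numerical
choices, and what the tests do and do not establish.

## Data model and exposure

The unit of analysis is a child: geocoded residence, two binary outcomes
(asthma, rhinoconjunctivitis), and eleven categorical questionnaire
covariates, any of which may be missing.  Distances from each residence to
each source are great-circle distances (haversine formula, mean Earth radius
6371.0 km); the "average" exposure is the arithmetic mean of the per-source
distances treated as a single source.  For the dichotomized analyses a child
is coded exposed when its distance is at or below the empirical 25th
percentile (type-7 linear-interpolation quantile; ties exposed).  Children
with missing coordinates are excluded; residences farther than mean + 4 sd of
the centroid-distance distribution (configurable) are treated as isolated and
excluded, a stand-in rule for a protocol that reports only exclusion counts.

## Stage 1 — dichotomized logistic regression with multiple imputation

Maximum-likelihood logistic fits (statsmodels IRLS) with Wald 95% intervals.
A covariate is retained as a potential confounder when its crude
single-covariate association with the outcome reaches joint Wald p < 0.05
(threshold configurable; multi-level covariates use a joint chi-square over
their dummy block).  Item nonresponse is handled by multiple imputation under
missingness-at-random: for each of m = 7 imputations the parameters of a
joint multivariate-normal model on a latent numeric scale (binary categories
as 0/1, multi-level categories as dummy blocks) are estimated by EM on a
bootstrap resample, missing cells of the original table are then drawn from
their conditional normal and rounded back to valid categories.  Estimates are
pooled with Rubin's rules, total variance `T = W + (1 + 1/m) B`, with
Barnard–Rubin small-sample degrees of freedom.  Between-imputation variance
numerically indistinguishable from zero is clamped to zero so pooling
identical fits is exact.

## Stage 2 — Bayesian P-spline additive model

The distance effect is modelled as an unknown smooth in a Bernoulli-logit
structured additive model: cubic B-splines on 20 equidistant interior knots
(defaults; configurable) with a second-order random-walk prior on the
coefficients and diffuse Normal(0, 100²) priors on the intercept and
confounder effects.  The smooth is constrained to sum to zero over the
observed distances, which identifies it against the intercept; extracted
curves are therefore centered log-odds-ratio profiles with pointwise
2.5/97.5% posterior bands.

Sampling combines two Metropolis–Hastings kernels built on the iteratively
weighted least squares (IWLS) Gaussian approximation of the full
conditional — a grouped variance/coefficient move and a full-IWLS
coefficient refresh that proposes from the approximate conditional — plus a
conjugate (truncated) inverse-gamma update of the smoothing variance.  The
jump-to-conditional-mode character of the refresh is deliberate: a
gradient-walking kernel (MALA) was tried here and, by drifting gradually
along weakly identified near-separating boundary directions while the
conjugate update raised the variance in response, it escorted the chain
into a large-variance wilderness from which mixing never recovered; the
independence-style proposal cannot drift.  Several pathologies shaped the
numerical design:

* **Grouped variance move.** Alternating coefficient/variance updates can
  lock into a collapsed smoothing variance: with τ² ≈ 0 the IWLS proposal is
  confined to the penalty null space (straight lines) and can never propose
  the curvature that would justify a larger τ².  Each sweep therefore also
  makes a joint Metropolis move proposing τ²′ by a log-scale random walk
  together with coefficients drawn from the IWLS approximation *under* τ²′,
  accepted with the exact joint ratio.
* **Smoothing-variance hyperprior.** The conventional IG(0.001, 0.001)
  hyperprior concentrates enormous mass at zero; for weak binary signals the
  posterior then oversmooths to a line and the credible band undercovers a
  genuinely curved truth badly (observed pointwise truth coverage 0.43 on a
  plateau-decay fixture).  Conversely a heavy right tail admits a
  near-unpenalized overfit region in which IWLS proposals behave like
  mismatched independence proposals and the chain can freeze.  The default is
  the moderately informative IG(2, 0.1) (mode 0.033 — the natural scale for
  log-odds smooths of order-one amplitude) with the support truncated at
  τ² = 5: honest smooths need τ² ≈ 0.005–0.1, and an unbounded upper tail
  is exactly where the runaway described above lives.  Under this default,
  truth coverage on the plateau-decay fixture is complete, flat truths
  remain honestly covered (pointwise null coverage ≈ 0.93, stable when
  chains are lengthened), and no freezing was observed.  A diffuse proper
  ridge (sd 100) on the spline block additionally keeps coefficients
  bounded.

Defaults of 70,000 iterations with 15,000 burn-in and two chains follow
standard practice for these models; thinning 10 bounds memory.  Convergence
is summarised by split potential-scale-reduction (R̂) for the intercept, the
smoothing variance, and the smooth at three reference distances; any R̂ > 1.1
flags the fit.

### Prior calibration for stage 3

The excess odds at the source, α, gets a log-normal prior read off the STAR
band: because the centered smooth is only identified up to a constant, the
source log odds ratio is measured relative to the curve's far-field level
(its mean over the top quartile of the distance range — a single boundary
point of a P-spline is unstable under sparse tail data).  The prior median of
α is exp(source log-OR) − 1 and the upper 97.5% quantile matches the band's
upper limit at the minimum distance, with σ floored at 0.4: the (α, φ, δ)
likelihood is nearly flat, and an over-tight α prior would simply be returned
as the posterior.  φ keeps a weakly informative log-normal with median 1 km
(σ = 0.5); δ is uniform over the observed distance range.

## Stage 3 — parametric distance-odds models

The distance–odds function is a plateau with Gaussian decay,

    f(d) = 1 + α                      for d ≤ δ
    f(d) = 1 + α·exp(−((d − δ)/φ)²)   for d > δ,

with α ≥ 0 the excess odds at the source (odds ratio 1 + α), δ ≥ 0 the
plateau radius (km) and φ > 0 the decay scale (km).  The decay must carry a
negative exponent for the function to describe risk declining with distance;
f enters the logit predictor as **log f**, so that 1 + α is exactly the odds
ratio between a child at the source and a far-field child with identical
covariates.  A literal additive-f predictor is available behind
`f_mode="additive"` for comparison; with the additive form 1 + α becomes an
additive log-odds shift instead of an odds ratio, which contradicts the
parameter's interpretation, so log-f is the default.

Residual spatial variation is a low-rank Gaussian-kernel field: T = 40 knots
by k-means over planar-projected residences, kernel bandwidth the median
inter-knot distance, knot weights constrained to sum to zero (orthonormal
contrast parametrization, so the constraint is exact in every draw) with a
Normal(0, τ²) prior and inverse-gamma τ².  Four nested models are fitted —
Model 0 (confounders only), 1 (+ spatial), 2 (+ log f), 3 (+ both) — and
compared by DIC = D̄ + pD with pD = D̄ − D(posterior means).  For
weakly-identified nonlinear parameters the plug-in deviance can exceed D̄,
giving negative pD; this known pathology is warned about and reported as-is.

Sampling: the intercept, confounder effects and spatial coordinates form a
single joint block (separate updates mix poorly because the intercept and
the field level are strongly correlated a posteriori) updated by
preconditioned MALA with an adapted step; (log α, log φ, δ) move by adaptive
random-walk Metropolis (Robbins–Monro scale plus empirical covariance,
frozen after burn-in) *together with a compensating intercept shift* — a
volume-preserving shear along the β₀ ↔ mean-log-f ridge that otherwise
dominates the autocorrelation; τ² is conjugate inverse-gamma.  The spatial
kernel bandwidth is 1.5× the median nearest-neighbour knot distance — tying
it to the overall knot-cloud extent makes all kernels nearly identical
(design condition numbers ~10⁹) and the weight block unidentifiable.
Stage-3 defaults are 4 chains of 20,000 iterations (5,000 burn-in); tests
use shorter chains scaled to their fixture sizes.

### Threshold distance

The threshold is the largest distance below which the pointwise lower 95%
credible bound of f stays above 1.  Since f > 1 strictly at every finite
distance, the crossing is judged against 1 + tol with tol = 0.05 — an excess
odds of 5% or less is treated as negligible.  The crossing is located by
linear interpolation on an 80-point grid from the source outward; a bound
that never drops to the tolerance yields a threshold censored at the grid
end, and a bound already below it at the source yields none.

## Synthetic-town generator

The generator emulates the study conditions the pipeline was designed for:
275 children (288 enrolled in the exclusion fixture) scattered isotropically
(sd 0.26 km) on a local tangent plane around a town centre, a gold mine
2.1 km away and a copper mine 1.9 km away at bearings 40° apart — close
bearings make the two distances positively correlated, so the average
distance keeps a realistic spread (≈ 0.26 km) instead of collapsing.  A
single isotropic spread cannot reproduce both reported per-mine distance
spreads (0.26 and 0.37 km); the gold-mine geometry is matched.  Covariate
marginals and per-item nonresponse rates default to questionnaire-typical
values (e.g. 46% girls; 61/275 missing for hours-at-home).  Outcomes are
Bernoulli draws from the stage-3 model itself (truth α = 2, φ = 1.1 km,
δ = 0.8 km, mild covariate effects, spatial sd 0.2) with the intercept
calibrated by root-finding so overall prevalences hit 24% and 34%.
Missingness is injected MAR: the gap probability depends only on sex and age
group, with the intercept solved so the marginal rate matches the target.

The spatial truth uses the same low-rank knot construction as the fitting
model (clean self-consistency for recovery tests); a dense Gaussian-process
mode (`spatial_mode="gp"`) exists to probe misspecification.  What the
generator does **not** emulate: street networks and clustered housing,
spatially structured covariates, wind direction or source geometry, and
informative (non-MAR) nonresponse.  Passing recovery tests therefore show
the estimators work when their assumptions hold, not that those assumptions
hold in any real town.

## Test problem sizes

Parameter-recovery and DIC-ordering checks use 20 replicates of n = 2000
children surrounding a single mine (Rayleigh-distributed distances, so the
plateau region is populated) with two chains of 3,000 iterations; the
credible-band calibration check uses 200 flat-truth replicates of n = 250
with single short chains; oracle equivalences use exact small fixtures.
These sizes were chosen so each check has enough Monte-Carlo resolution for
its stated tolerance.

## Known limitations

* (α, φ, δ) are weakly identified when observed distances do not span the
  plateau; posteriors then track the calibrated prior — a documented property
  of this model class, which is why stage 2 exists.
* DIC with plug-in posterior means can yield negative pD for these nonlinear
  terms; comparisons between models whose pD is pathological deserve caution.
* The MVN latent imputation model is approximate for categorical data
  (rounding step); chained-equation alternatives would be a reasonable
  extension.
* One outcome × one exposure mode per fit; multi-disease and multi-source
  joint models are out of scope.
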
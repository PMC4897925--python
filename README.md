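# minetown

Distance–risk modelling of childhood respiratory disease around industrial
point sources.

## The problem

In small communities that grow around open-pit mines, the question "does
living closer to the mine raise a child's risk of asthma or
rhinoconjunctivitis?" usually has to be answered without any emission
measurements: the only exposure information is each child's geocoded
residence and the locations of the sources.  This package implements a
complete three-stage analysis for that setting — cross-sectional data, one
row per child with two binary outcomes and questionnaire covariates, plus a
table of source coordinates — together with a synthetic-town generator so
that every estimator can be validated by parameter recovery.

## The models

**Stage 1 (dichotomized logistic regression).**  Distance to each source
(haversine great-circle, and the average over sources) is dichotomized at its
first quartile; logistic models estimate the closest-quartile odds ratio,
crude and adjusted for covariates that pass a crude-association screen
(Wald p < 0.05).  Item nonresponse is handled by bootstrap-EM multiple
imputation (m = 7) pooled with Rubin's rules.

**Stage 2 (Bayesian P-spline STAR).**  logit π_i = β₀ + f(d_i) + x_iᵀβ with
f a penalized B-spline smooth (RW2 prior, sum-to-zero constraint), fitted by
MCMC.  The centered curve with its 95% credible band shows the shape of the
distance–risk relationship without assuming one, and calibrates the priors
for stage 3.

**Stage 3 (parametric distance-odds models).**  The core estimand is the
plateau/Gaussian-decay distance-odds function

    f(d) = 1 + α                          d ≤ δ
    f(d) = 1 + α·exp(−((d − δ)/φ)²)       d > δ

entering the logit as log f, so 1 + α is the odds ratio at the source, δ the
plateau radius (km) and φ the decay scale (km).  Four nested models —
confounders only, + low-rank spatial field S(s) (40 k-means knots), + log f,
+ both — are fitted by MCMC and compared by DIC, and the threshold distance
(largest distance up to which the lower 95% credible bound of f stays above
1, to a 5% negligibility tolerance) summarises where proximity still carries
risk.

See `docs/methods.md` for assumptions, priors, sampler design and
limitations.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the default
synthetic town (275 children, a gold mine 2.1 km and a copper mine 1.9 km
from the town centre):

```
python analysis/01_simulate_town.py --seed 1 --outdir results
python analysis/02_logistic_mi.py   --seed 1 --outdir results
python analysis/03_star_curve.py    --seed 1 --outdir results
python analysis/04_pointsource_models.py --seed 1 --outdir results
```

Script 01 prints the generated study conditions:

```
wrote 275 children to results/study.csv
  distance to gold    : mean 2.11 km (sd 0.24, range 1.37-2.82), Q1 cut-off 1.96 km
  distance to copper  : mean 1.93 km (sd 0.22, range 1.19-2.74), Q1 cut-off 1.77 km
  distance to average : mean 2.02 km (sd 0.21, range 1.42-2.71), Q1 cut-off 1.88 km
  asthma: prevalence 22.2%
  rhinoconjunctivitis: prevalence 31.3%
```

and script 02 the stage-1 estimates — for each exposure, the odds of disease
for children in the closest distance quartile relative to everyone else,
pooled over seven imputations:

```
asthma: screened confounders -> ['parental_atopy', 'mother_working', 'lives_with_both_parents']
  gold     pooled OR 1.85 (0.93-3.65)
  copper   pooled OR 1.18 (0.58-2.38)
  average  pooled OR 1.60 (0.80-3.17)
```

(The generative truth has an elevated-odds plateau at the mines, so pooled
ORs above 1 with wide intervals at n = 275 are exactly the expected
behaviour.)  Scripts 03–04 then fit the STAR curve, calibrate priors, fit
Models 0–3 and print the DIC table, the posterior (α, φ, δ) and the
threshold distance.  On the same seed the stage-3 run reports Model 3
(distance function + spatial effect) as best by DIC (182.1, against 183.7
for the confounders-only Model 0 — the margins between these models are
small, as expected when the distance signal is modest), posterior means
α̂ = 2.07, φ̂ = 1.07 km, δ̂ = 1.30 km against the generative truth
(α = 2, φ = 1.1, δ = 0.8), an odds ratio at the source of ≈ 3.1, and a
threshold distance of 1.41 km — the largest distance up to which the lower
95% credible bound of f stays above 1.  `analysis/05_report.py` runs all
stages through `minetown.pipeline.run_all` and writes a fully seeded
`report.json` + `report.md`.

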
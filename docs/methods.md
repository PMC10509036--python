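# Methods

## The composite coverage index

The composite coverage index (CCI) summarises reproductive, maternal,
newborn and child health (RMNCH) service coverage as a weighted average of
eight intervention coverage proportions in four equally weighted domains:

    CCI = 1/4 [ DFPSm + (ANC4 + SBA)/2 + (BCG + 2 DPT3 + MSL)/4 + (ORS + CAREP)/2 ]

family planning (DFPSm), maternal and newborn care (ANC4, SBA),
immunisation (BCG, DPT3 double-weighted, MSL) and case management of
childhood illness (ORS, CAREP).  The per-indicator weights are therefore
(1/4, 1/8, 1/8, 1/16, 1/8, 1/16, 1/8, 1/8); they sum to one, the index is
linear and monotone in every indicator, and a constant indicator vector c
maps to CCI = c.  Inputs are validated as proportions in [0, 1]; the 0–100
scale is accepted only behind an explicit `percent` flag, never silently
rescaled.

## Hierarchical trend model

Stratum-level CCI values from national household surveys (DHS/MICS-style
extracts) form a sparse country–year panel.  The observation model works
on the logit scale so that fitted and projected coverage always stays
inside (0, 100)%:

    y_l = logit(CCI_l) = x_l' beta + u_{j(l)} + eps_l,   eps_l ~ N(0, tau^2)

with fixed effects x_l comprising an intercept, calendar year (centred at
2015, scaled per decade, so the year coefficient reads "logits per
decade"), stratum dummies with a declared reference level (national for
the residence variant, Q1 for wealth, no-education for education), and
standardised country-level covariates: SDI (socio-demographic index, unit
interval), GGDPH (government health spending, % of GDP) and log GDP per
capita.  GDPC is logged before standardisation because its raw scale spans
two orders of magnitude across countries.  Country intercepts u_j are
partially pooled within regions:

    u_j ~ N(v_{k(j)}, sigma_c^2),    v_k ~ N(beta_0, sigma_r^2),

so countries with a single survey (a large fraction of real panels) borrow
strength from their region.  Wealth and education variants exclude the
residence terms; residence-by-country interaction dummies are available as
an option with a tighter N(0, 1) shrinkage prior.  Covariate slopes are
global (not country-specific): with many countries contributing one data
point, country-level slopes are not identifiable, and the hierarchy on the
intercepts carries the between-country heterogeneity.

### Priors and sampling

Fixed effects get independent N(0, 10^2) priors on the standardised scale.
Two hyperprior families are implemented for (tau, sigma_c, sigma_r):

* baseline: Gamma(0.01, 0.01) on each precision;
* sensitivity: half-Cauchy(0, 25) on each SD, via the inverse-gamma
  scale-mixture representation (sigma^2 | a ~ InvGamma(1/2, 1/a),
  a ~ InvGamma(1/2, 1/25^2)), which keeps every conditional conjugate.

Inference is a blocked Gibbs sampler written for this model; every full
conditional is closed-form, so each sweep is a Cholesky solve for the
slope block plus vectorised draws for the intercepts and variances.  The
sampler uses the hierarchically *centred* parameterization (the global
intercept is the hypermean of the region effects) — the same joint
posterior as putting the intercept in the design matrix, but it removes
the additive ridge between the intercept and the random-effect means that
otherwise inflates autocorrelation badly (we observed potential scale
reduction factors of ~1.6 on the intercept in the non-centred form versus
~1.03 centred, at identical cost).  Stored draws are converted back to the
deviation convention (u, v relative to beta_0) so prediction is always
`X beta + u`.  Defaults: 4 chains, 5 000 iterations, 2 500 burn-in; an
explicit seed is mandatory and chains are seeded by `SeedSequence.spawn`,
making every fit bit-reproducible.

### Numerical choices

* logit clipping eps = 1e-3 (configurable): boundary CCI values in sparse
  strata stay finite without dropping the observation.
* Design rows are canonicalised (sorted by country, year, stratum level)
  before fitting, so posteriors are exactly invariant to input row order.
* Exact rank deficiency in the design raises immediately with a pointer to
  the VIF screen; near-collinearity is the screen's job, not the sampler's.
* A degenerate hierarchy (single country) automatically reduces to
  ordinary Bayesian linear regression; with a flat prior and known tau the
  posterior matches the GLS closed form, which is tested.
* Convergence is assessed with the classic (non-split) Gelman–Rubin PSRF
  on every scalar parameter, sqrt(((n-1)/n W + B/n)/W); a split-chain
  variant is available.  Fits with any fixed-effect PSRF above 1.1
  (configurable) are flagged `converged=False` with a warning — never
  silently.

## Model checking

* **VIF screen.**  Computed on the candidate covariate columns only (not
  dummies or intercepts): VIF_j = 1/(1 - R^2_j) from the auxiliary
  regression of covariate j on the others plus an intercept.  Iterative
  elimination removes the single worst covariate while any VIF exceeds 5,
  with an alphabetical tie-break; perfect collinearity reports +inf and
  goes first.  Every round is recorded.
* **DIC.**  Spiegelhalter's version: pD = mean deviance minus deviance at
  the posterior mean of the parameters; DIC = mean deviance + pD.
* **Posterior predictive check.**  For each draw, a replicate panel is
  simulated from the fitted model and a discrepancy statistic (default:
  mean of the CCI proportions; SD and quantiles optional) is compared with
  the observed value; p = Pr(T_rep >= T_obs) with ties counted 1/2.
  Values near 0.5 indicate no evidence of misfit.  The observed-vs-
  replicate convention makes the p-value equivariant: swapping roles maps
  p to 1 - p.
* **Prior sensitivity.**  The gamma and half-Cauchy fits are compared by
  the per-parameter absolute difference of posterior medians, reported
  both raw and as a fraction of the posterior SD; any fixed effect moving
  more than half a posterior SD raises a flag.

## Projection and aggregation

Every posterior draw is pushed through the linear predictor for each
requested country × year × stratum cell (covariates must already extend to
the target year) and mapped through the inverse logit, giving a per-draw
CCI grid.  Summaries are the posterior mean and central 95% credible
interval in percent, plus P(CCI >= 80%), the probability of meeting the
universal-coverage target; a country is classed *on track* when that
probability at 2030 is at least 0.70.  The reporting grid defaults to
{2000, 2005, ..., 2030}.

Regional aggregation combines member-country trajectories on the logit
scale (so aggregates stay inside the unit interval) and back-transforms.
The default is DerSimonian–Laird random-effects pooling: per year, each
country's posterior mean and SD on the logit scale define the DL weights
(method-of-moments tau^2 from Cochran's Q); those weights are applied to
every posterior draw and summaries are taken over draws, with the
between-country heterogeneity SD reported.  A per-draw weighted mean with
caller-supplied (e.g. population) weights is the alternative; no
population data are bundled.  Single-country regions pass through
unchanged.

## Inequality

Residence is nominal, so absolute inequality is the signed percentage-
point difference urban minus rural, evaluated per posterior draw.  Wealth
quintiles and education levels are ordinal, so inequality is the slope
index of inequality (SII): weighted least squares of per-level coverage on
ridit scores (midpoints of the cumulative population-share intervals;
equal shares by default — quintiles are fifths by construction, education
shares should be supplied when known).  On the natural scale the SII is
the fitted difference between ridit 1 and ridit 0, directly in percentage
points; a log-scale variant regresses ln(coverage proportion) and
back-transforms the two end-points before differencing.  Natural is the
default because the reported unit is percentage points; the log variant
exists because coverage ratios are sometimes preferred when levels are
small.  Natural-scale SII is linear in the level coverages, so posterior
uncertainty propagates by applying a fixed coefficient vector to every
draw (no delta method).  Year-over-year trends are summarised as start,
end, change, and a narrowing/widening/stable flag on the magnitude, with
reductions of at least 10 points marked separately.

## Synthetic data generator

The generator emulates the structure of stratified RMNCH coverage
extracts, with every default chosen to match the panel the method is
designed for: 9 regions, 70 countries, surveys observed 2000–2020 with
projections to 2030, 20 of 70 countries contributing exactly one survey
and the rest 3–8 (≈290 national data points), residual logit-scale noise
SD 0.25.  Covariate trajectories are smooth and plausible: logistic growth
for SDI (strictly increasing, inside the unit interval), log-linear growth
for GDP per capita, AR(1)-around-trend for GGDPH clipped inside (0, 20)%
of GDP.  Optional columns provide a DAH/HRH pair sharing a latent
aid/health-system factor (a realistic strong-collinearity case for the
VIF screen) and a near-duplicate of GDPC whose faint SDI coupling makes
the duplicate — not the original — the screen's first elimination.

Observations are drawn from exactly the model the package fits: region
and country effects from their normal hierarchy, a latent logit-CCI
surface from the true coefficients, and Normal logit-scale noise at
survey years sampled uniformly without replacement.  The default true
parameters put a typical country near 55–60% national CCI in 2015 with a
wide cross-country spread, so that by 2030 some but not most countries
reach the 80% target — the landscape real LMIC panels show.  Default
wealth (0, 0.25, 0.50, 0.75, 1.05 logits) and education (0, 0.35, 0.80)
offsets are monotone; urban (+0.30) exceeds rural (−0.35).

What the generator does **not** emulate: survey design effects (a single
noise SD stands in for stratum-specific sampling error), household/cluster
microdata, non-linear time trends, spatially correlated shocks, and
informative missingness of survey years (years are missing completely at
random, whereas real survey scheduling may correlate with system
capacity).  Passing recovery and calibration tests therefore shows the
inference machinery is correct and well-calibrated *under the stated
model*, not that the model is adequate for any particular real panel —
that is what the posterior predictive and sensitivity checks are for on
real data.

## Problem sizes used by the test suite and acceptance script

Parameter-recovery and calibration tests use 20 independently seeded
bundles of 9 regions × 36 countries (~190 stratified observations each)
fitted with 4 chains × 2 000 iterations — dimensions chosen so the full
suite runs in well under a minute of sampling while keeping every
inferential property measurable.  The analysis scripts and the acceptance
script run the full 70-country study with 4 chains × 2 500 iterations.

## Known limitations

* Covariate effects that trend with time (SDI especially) are only weakly
  separable from the secular year effect on sparse panels; their
  posteriors are wide and their point estimates noticeably shrunken, which
  is why recovery bias is asserted only for the well-identified effects
  (year, residence offsets).
* DIC is reported because it is the conventional companion of this model
  family; it shares the known weaknesses of pD under strong hierarchy.
* The DL regional weights are derived from posterior summaries, then held
  fixed across draws; fully draw-wise reweighting would couple weights to
  sampling noise in each draw and was deliberately avoided.
* No survey-weighted likelihood; observations enter with equal precision.
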
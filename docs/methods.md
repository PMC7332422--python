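# Methods

`lipidtrends` estimates population mean total, non-HDL and HDL
cholesterol (mmol/l) by country, year, sex and age band from
heterogeneous survey data, and carries the estimates through to
age-standardized trend summaries and attributable-mortality
calculations. This note records the model, the synthetic data that
exercises it, and the numerical and design choices a maintainer would
want to know about.

## The estimation problem

Population surveys measuring blood lipids differ in coverage (national,
subnational, community), setting (rural, urban, mixed), measurement
technology (laboratory vs portable devices with narrow analytical
ranges) and calendar time. The estimand is the general national
population mean for each country-year-sex-age cell, which requires
borrowing strength across years, countries and regions, and adjusting
for systematic differences between study types.

## Record cleaning

Participants are included if aged 18+ and not pregnant. Implausible
values are removed with strict windows: total cholesterol outside
(1.75, 20) mmol/l, HDL outside (0.4, 5) mmol/l, or total below HDL.
Values exactly at a window edge are retained (the windows are written as
strict inequalities). When LDL is present, a record is removed when

    LDL·(1 − e_LDL) + HDL·(1 − e_HDL) > TC·(1 + e_TC)

with allowable-error limits e_TC = 8.9%, e_HDL = 13%, e_LDL = 12%
(CRMLN standards). **The combining rule is a package decision**: the
limits are published but the inequality that combines them is not, so we
adopt the most permissive reading — each component is shifted to its
error-limit extreme in the record's favour before the comparison. A
removed record is attributed to the first rule it violates in a fixed
order (age, pregnancy, total window, HDL window, total<HDL, CRMLN), so
per-rule counts add up exactly to the total removed.

Cleaned records are collapsed into study × sex × age-band stratum
summaries (bands 18-19, 20-29, then 10-year bands to 70-79, and 80+).
The weighted mean uses survey weights; its standard error is the
weighted sample variance with an n/(n−1) correction divided by the Kish
effective sample size (Σw)²/Σw², which reduces to sd/√n under equal
weights. Design effects beyond weights are out of scope. Strata with a
single observation carry no variance information; they get SE = NaN and
are dropped before modelling. Non-HDL is summarized as the weighted mean
of per-person (total − HDL) over persons with both measurements.

## Portable-device adjustment

Portable analyzers cannot report values outside their analytical range;
participants at or beyond a limit are dropped (readings *at* a limit are
indistinguishable from out-of-range codes), which biases the restricted
mean toward the centre. Conversion regressions trained on laboratory
studies map restricted-range stratum means back to full-range means: the
response is the full-data mean, the predictor the mean after mimicking
the truncation, with terms for age (band midpoint, standardized) and
sex always included and pairwise interactions with the restricted mean
toggled by exhaustive BIC search (ties broken toward fewer terms).
Non-HDL conversions additionally carry the stratum mean total and HDL
cholesterol. Strata with fewer than 25 individuals are excluded from
training. One model is fitted per (metric, device-range) pair.

Applying a conversion draws repeatedly from (i) the sampling
distribution of the input mean, (ii) the coefficient sampling
distribution, (iii) the residual distribution, and summarizes the draws
as the adjusted mean and SE. The device ranges shipped with the package
(`pipeline.default_device_specs`) are **illustrative synthetic values**,
not manufacturer specifications; real analyses must supply their own
table.

## Hierarchical trend model

For one metric and sex, a stratum summary y_i with standard error s_i is
modelled as

    y_i = F(c_i, t_i) + A(c_i, a_i) + study terms + ε_i,
    ε_i ~ N(0, s_i² + ν²_type)

with country-year level

    F(c, t) = a₀ + a_sr + a_r + a_c + (b₀ + b_sr + b_r + b_c)·t̃
            + u_w(t) + u_sr(t) + u_r(t) + u_c(t)
            + γ_urb·(urban share − ½) [+ γ_tc·(TC covariate)]

where t̃ is the year centred and scaled to decades, and each u is a
second-order random-walk (RW2) deviation — a smoothness prior penalizing
second differences — at the world, super-region, region and country
level with level-specific smoothness variances. Each RW2 vector is
parameterized as u = Z·w, with Z an orthonormal basis of the subspace
orthogonal to {1, t}: the sum-to-zero and detrending constraints
therefore hold *exactly in every draw* and the linear slopes stay
identified. Estimates for a country-year are informed by its own data
where available and otherwise shrink toward region, super-region and
world signals.

The age curve A is a cubic spline over band midpoints with a global
coefficient vector plus hierarchically shrunk country perturbations. We
use an **unrestricted cubic B-spline basis** (interior knots at 35, 45,
55, 65; boundary at the extreme band midpoints 18.5 and 85; one basis
column dropped and columns centred for identifiability) rather than a
natural spline: natural boundary constraints force linearity beyond the
boundary knots, which would exclude ordinary cubic age patterns —
including the ones the synthetic generator produces — from the model
family and build structural bias into the 18-19 and 80+ bands.

Study-type terms implement the bias and precision differences between
study designs: fixed effects for subnational and community studies; one
random intercept per subnational/community study (variance τ²_type),
which lets national data carry more weight than equally sized
subnational data; extra observation variance ν²_type for the same
types; and fixed effects for rural-only and urban-only studies weighted
by the gap between study-level urbanization (0 or 1) and the country's
urban share in the study year — a rural-only study in a 60%-urban
country enters with weight 0.6. The proportion urban is always a
covariate; the non-HDL and HDL models additionally take the
age-standardized posterior-mean total cholesterol per country-year as a
covariate, computed from the total-cholesterol fit run first (point
covariate; full joint uncertainty propagation between metrics is out of
scope).

**Priors.** The source analyses defer their exact priors to a separate
statistical paper, so all hyperparameters here are package defaults,
declared in `trend_model.PriorSpec`: diffuse N(0, 10²) on fixed effects
and global age coefficients; half-normal on every standard deviation
(scales: 0.5 mmol/l for intercept offsets, 0.2 mmol/l-per-decade for
slopes, 0.03 for RW2 innovations, 0.2 for age perturbations, 0.3 for
study random effects and extra variance). These are weakly informative
relative to observed between-country lipid variation.

**Sampling.** Blocked Gibbs: all location parameters are drawn jointly
from their exact multivariate-normal full conditional (the design is
sparse; the per-iteration cost is one dense Cholesky of the posterior
precision), and every standard deviation is updated by univariate slice
sampling on the log scale. The sampler is correct for any linear-
Gaussian hierarchy of this form; correctness is verified against a
conjugate normal-normal oracle and by coverage experiments rather than
asserted from the algorithm. Default settings retain 5,000 post-burn-in
draws; the tests and acceptance script use smaller worlds and draw
counts (stated inline) chosen so recovery and coverage checks are
decisive at desk scale. A split-chain R-hat above 1.05 flags the run
(without aborting); flagged runs at small draw counts are expected and
the recovery tests are designed to be robust to them.

The estimand excludes the study terms. For comparing *held-out
observations* with estimates, `predictive_observation_draws` adds back
the study-type fixed effects and draws the random-effect, extra-variance
and sampling noise — the correct predictive distribution for an
observed stratum summary.

## Post-processing

Age-standardized means are weighted averages of band-level estimates per
draw, using the WHO world standard population (2000-2025) collapsed onto
the analysis bands: the 18-19 band takes two fifths of the 15-19 weight,
10-year bands sum two 5-year groups, 80+ pools 80-84 and 85+, and the
result is renormalized to sum to one over the adult bands (the standard
is named in the source analyses; the band mapping is our
interpretation). Regional and global aggregates are population-weighted
averages of country estimates at band level, which makes aggregation
exactly associative (world via regions equals world via countries).

Change per decade is (value at the final year − value at the first
year) divided by elapsed decades — 3.8 for 1980-2018. An inclusive
year-count convention (divisor 3.9) is supported via
``decade_divisor``; elapsed time is the default because change-per-time
refers to elapsed time. Posterior probabilities of decline/increase are
the fractions of draws with negative/positive change. Credible
intervals are 2.5-97.5 percentiles throughout. All files are in mmol/l;
1 mmol/l = 38.61 mg/dl for rendering.

## Attributable burden

For each cell, the population attributable fraction compares the mean
relative risk under the observed exposure distribution N(mean, SD) with
a counterfactual at the optimal level:

    PAF = (E_obs[RR(X)] − E_cf[RR(X)]) / E_obs[RR(X)],
    RR(x) = rr^max(0, x − m)

with m the midpoint (2.0) of the optimal band 1.8-2.2 mmol/l and rr the
age-specific relative risk per mmol/l above it. The counterfactual is
normal with the observed SD centred at m (a uniform draw over the band
is available as an option; both are package decisions — the source
analyses do not print the integrand or the counterfactual dispersion).
Expectations use adaptive quadrature; a closed-form path (mixture of a
censored mass and a lognormal-type term) exists for draw-level
propagation and is cross-checked against quadrature in the tests.
Exposure SD is an input (the trend model estimates means, not
dispersions). Age bands older than the RR table inherit its oldest
entry. The RR curves shipped in `burden.illustrative_rr_curves` are
**synthetic illustrative values** for exercising the pipeline.
Attributable deaths are PAF × cause-specific deaths per cell; the
deaths table is an input.

## Hold-out validation

Two external-predictive-validity tests: (1) hold out all data from 10%
of countries with data; (2) hold out 10% of sources — per affected
country either a random half of its sources or all of its 2000-2018
sources, the modes alternating deterministically under the seed so both
appear in every repetition. Held-out units are sampled within
data-availability strata: data rich (≥5 sources, at least one after
2000), data poor (1 source), average (2-4). A country with ≥5 sources
but none after 2000 is classified average (the rich class explicitly
requires a recent source). Each test runs five repetitions; errors are
held-out value minus estimate (over-estimation ⇒ negative error);
overall medians pool the errors rather than averaging stratum medians.
Coverage uses the posterior-predictive distribution for an observed
stratum described above. Leakage is asserted: a held-out unit
contributes zero observations to its repetition's fit.

## The synthetic world

The generator produces the study conditions end to end: a configurable
hierarchy (countries → regions → super-regions) with populations and
rising logistic urbanization curves; true surfaces built from the same
structural family the model fits — hierarchy intercept/slope offsets,
RW2 deviations (doubly-cumulated innovations, centred and detrended so
slopes are identified), cubic-polynomial age curves per sex with small
country-level perturbations, and an urbanization effect; a study
portfolio matching the observed composition of large lipid databases
(36.3% national / 22.2% subnational / 41.5% community, 10% on portable
devices), with zero-mean offsets for national studies and nonzero-mean,
larger-variance offsets for subnational and community ones; and
individual records with survey weights, correlated (total, HDL) values,
optional LDL, pregnancy flags and under-18 records to exercise the
filters.

Choices worth flagging:

- Individual values are drawn from a correlated normal *truncated to the
  plausibility windows and to TC > HDL* (rejection sampling). The clean
  synthetic population therefore contains no genuinely implausible
  values — implausible records are measurement errors, represented
  solely by explicit injection — so filter recall/false-positive tests
  are exact. The truncation displaces stratum means from nominal truth
  by well under 0.01 mmol/l at defaults.
- Injected implausible values are drawn uniformly outside the windows
  ([0.5, 1.74] ∪ [20.01, 30] for total; the analogue for HDL), which
  guarantees the filter hit and gives exact ground truth.
- The individual-level correlation between total and HDL (default 0.2)
  is not pinned down by the source literature and is exposed as
  ``RecordConfig.tc_hdl_corr``.
- Configurations whose variance components would push more than 1% of
  surface cells outside the plausibility windows are rejected.

What the generator does *not* emulate: survey nonresponse, duplicate
sources, complex design effects beyond weights, non-normal individual
distributions, and device biases beyond range truncation. Passing tests
therefore demonstrate correctness of the machinery under the stated
model family, not robustness to real-data pathologies outside it.

## Numerical choices and degenerate inputs

- RW2 terms require at least 5 years; shorter ranges drop them (trend =
  intercept + slope).
- Observation SEs are floored at 1e-3 mmol/l in the model design: a
  numerically zero SE would give one observation unbounded weight and
  break the precision Cholesky.
- The non-HDL conversion's total/HDL predictor means are restricted to
  the companion device ranges in training (and the raw restricted means
  are supplied at application): with full-range predictors the response
  TC − HDL is reproduced exactly and the regression degenerates to a
  deterministic identity with zero residual variance.
- Rank-deficient conversion designs drop aliased columns via pivoted QR
  with a logged warning.
- PAF integrals are checked finite; non-finite values raise.
- A NaN in the sampler state raises with the iteration index.
- Ties in BIC selection go to the model with fewer terms.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical (config, seed) reproduces every
  output bitwise.

## Problem sizes used in the checks

The parameter-recovery and coverage experiments use 30 countries / 3
regions / 10 years with 2,000 retained draws (coverage of true
age-standardized means) and 60 countries / 6 regions / 20 years with 10
sources per country (slope recovery, r ≥ 0.8): slope identification
needs either a long window or dense data, and these sizes make the
check decisive while staying desk-scale. Validation runs at 30
countries over 1995-2009 with five repetitions per test. The
end-to-end drivers use 12 countries over 2000-2014.

## Known limitations

Single-chain sampling with split-half diagnostics (rather than multiple
independent chains); no joint uncertainty propagation from the
total-cholesterol covariate into the fraction models; exposure SD for
the PAF taken as input rather than modelled; the shipped device ranges
and RR curves are synthetic stand-ins; no support for published-report
(tabulated) data, duplicate detection, or survey design effects beyond
weights.
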
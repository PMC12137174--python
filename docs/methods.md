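# Methods

This package re-implements, end to end on synthetic data with known ground
truth, a small-area estimation pipeline for healthy life expectancy (HALE)
by county, race and ethnicity, sex, age group, and year. The pipeline has
six stages: synthetic-data generation, hierarchical prevalence models per
health indicator, cause-group YLD-rate regressions with draw-splitting
uncertainty propagation, raking to state benchmarks, Sullivan's method on
abridged life tables, and draw-based summaries with significance and
masking rules.

## The estimation problem

County-by-race estimates of years lived with disability (YLD, a rate in
[0, 1] expressing proportional health loss per person-year) cannot be
observed directly: burden estimates exist only at state level, and survey
indicators of morbidity arrive at mixed aggregation (some at fine strata,
some pooled over counties or ages). The pipeline therefore (1) models
indicator prevalence at fine strata from mixed-resolution binomial data,
(2) regresses state-level YLD benchmarks on fine-stratum predictors under
an aggregation-consistent likelihood, (3) rescales ("rakes") the resulting
county-race YLD rates so their population-weighted state averages match
the benchmarks exactly, and (4) converts life tables plus YLD rates into
HALE. Uncertainty propagates through every stage as 1000 aligned draws.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed:

* **Geography** — 48 counties on a near-square lattice (4-neighbor
  adjacency, optionally rewired), partitioned into 4 contiguous states.
  The graph is abstract: it reproduces the *structure* of a merged-county
  geography (sparse symmetric adjacency, connected components) without
  real boundaries.
* **Strata** — 2 races (configurable to 5), 2 sexes, abridged ages
  {[0,1), [1,5), 5-year groups to [85,∞)} (19 groups), years 2009–2019.
  An optional education axis is supported for the indicator models only.
* **Populations** — county totals are lognormal (median ≈ 15 000,
  σ = 1.1 on the log scale) with Beta-distributed minority shares, a
  smooth declining age structure, a 51/49 sex split, and +0.5%/year
  growth. The heavy tail guarantees that some county-race populations
  fall below the 1 000-person masking threshold, so the masking path is
  exercised naturally.
* **Random fields** — every surface combines link-scale fixed effects
  with intrinsic Gaussian Markov random fields: ICAR over the county
  graph (precision = graph Laplacian), RW1 over year and age
  (second-difference penalty), and centered exchangeable race (and
  education) deviations. Fields are sampled exactly on the sum-to-zero
  subspace via the eigendecomposition pseudo-inverse of each precision.
* **Links** — logit for prevalence; log for mortality and YLD rates.
* **Mortality** — a fixed baseline log-m\_x schedule calibrated to a
  life expectancy at birth near 80 years, plus small county/race fields
  and a mild upward year trend (+0.02 per decade on the log scale).
* **Indicator prevalence** — three indicators by default, each with an
  intercept, a standardized-age-midpoint slope, and coefficients on two
  county-level sociodemographic covariates (spatially smooth standardized
  ICAR fields), plus the random fields above.
* **YLL and YLD truth** — per-cause YLL rates are proportional to
  mortality with county jitter. Per-cause YLD truth is log-linear in log
  YLL (coefficient 0.8 for the first cause, moderate values for the
  rest), the first indicator's prevalence, and the first covariate, with
  per-age base offsets anchoring the all-cause rate to a realistic
  profile: floor 0.04 rising logistically to ≈ 0.44 in the oldest group
  (midpoint 55 years, scale 20). With the default fields this yields
  roughly 19% of life lived in poor health at the default scale, toward
  the high end of plausible national levels. Because the YLD age profile is anchored by offsets
  rather than by the (much steeper) YLL age gradient, rates stay well
  below 1 and summed state benchmarks remain feasible for raking.
* **Observations** — per indicator, each (race, sex, age, year) cell is
  observed either at county level (one binomial observation per county)
  or, with probability 0.25, only as state aggregates. Successes are
  k ~ Binomial(n, p̄) with p̄ the population-weighted mean prevalence of
  the observation's stratum set and n = 1000 by default; aggregated
  observations therefore match the estimator's likelihood exactly, which
  is deliberate — the target of the test is the stated likelihood, not a
  survey micro-simulation.
* **Benchmarks** — state-level per-cause YLD rates are exact
  population-weighted means of the truth with optional lognormal draw
  noise (σ = 0.02 by default, 1000 draws).
* **Seeds** — one master seed; child streams are spawned in a fixed
  documented order (covariates, mortality, YLL, one per indicator, one
  per cause), so adding a surface never perturbs earlier ones. Identical
  seed and configuration give byte-identical output files.

What the generator does *not* emulate: survey design effects and weights,
questionnaire semantics, misclassification, multirace bridging, real
geography, or interactions among random effects (main effects only — the
interaction structure of the original models is not public). Passing
tests therefore demonstrate correctness of the estimation machinery under
its own assumptions, not robustness to real-data pathologies.

## Indicator models

Hierarchical logit models per indicator: fixed effects (intercept, age
trend, covariates) plus the ICAR/RW1/exchangeable blocks, one precision
parameter per block. An observation's success probability is the
population-weighted average of its member strata's prevalences, so
coarse data contribute without disaggregation assumptions beyond the
weighting.

Inference is Laplace-approximate maximum marginal likelihood, the
strategy of TMB-style mixed models, re-implemented: an inner Newton solve
(analytic gradient and Hessian; Gauss–Newton fallback with damping when
the full curvature is indefinite; backtracking line search so accepted
steps never decrease the joint objective) finds the mode of all effects
given the precisions; the precisions are then optimized by L-BFGS-B on
the Laplace objective (joint density at the mode plus half the
prior-minus-curvature log-determinant difference), with forward
differences (step 0.05) for the outer gradient. Sum-to-zero constraints
are soft: a fixed precision of 1e4 on each block's per-component sum
keeps all precision matrices sparse and full rank. A weak ridge (1e-4) on
the fixed effects guarantees positive-definite curvature; separable data
(all k = 0 or all k = n) trigger a warning and a stronger ridge (1e-2).

Numerical choices: gradient ∞-norm tolerance 1e-6 (the convergence flag
is set honestly from the final gradient); at most 100 inner Newton
iterations with a two-strikes stall guard (two consecutive relative
improvements below 1e-9 end the inner loop); at most 200 outer
iterations; log precisions clipped to [−12, 12]; aggregated probabilities
clamped to [1e-12, 1 − 1e-12].

Posterior prevalence draws sample all effects from the Gaussian
approximation at the mode (curvature as precision, via Cholesky) and map
through the design and inverse logit; 1000 draws per indicator by
default. Conditioning on the estimated precisions slightly understates
hyperparameter uncertainty; the observed 95%-interval coverage of true
stratum prevalence on the default synthetic run is ≈ 92%, inside the
[88%, 99%] band the tests require. The education axis, when present, is
marginalized out of the draws with population weights before they feed
the YLD stage.

## YLD models and draw splitting

Per cause, the log state benchmark is modeled as Gaussian around the log
of the population-weighted average of exp(linear predictor) over the
state's county-race strata. The predictor contains an intercept, log YLL,
age-group main effects (YLD age profiles are far shallower than YLL
profiles, so the regression needs its own age level), indicator
prevalences, and covariates. The outcome is modeled on the log scale
because rates are positive and multiplicative. Fitting is nonlinear least
squares with an analytic Jacobian, warm-started from a linearized
regression; coefficient covariance is the Gauss–Newton estimate scaled by
the residual variance.

Uncertainty propagation splits draws: 50 models per cause, model m
consuming input draw m of every stochastic input (indicator draw m,
benchmark draw m×20); each model contributes 20 prediction draws
(coefficient sampling plus stratum-level residual noise — without the
residual term the 20 within-model draws would be nearly degenerate),
concatenated in (model, draw) order into 1000 draws. Draw lineage
(model-of-draw) is carried as metadata and asserted when cubes are
combined, so draw d of the all-cause sum is built only from
draw-d-lineage inputs and cross-quantity correlation survives. Summing
the 16 cause cubes is element-wise by draw; values above 1 (full-time
disability per person-year) are clipped with the count logged.

## Raking

For every (state, sex, age, year, draw) cell, county-race all-cause YLD
rates are multiplied by benchmark / weighted-mean — multiplicative
because rates are positive and the adjustment is a rescaling. Values
pushed above 1 are clipped and the remaining strata re-raked (at most 50
passes) so the constraint still holds exactly; the post-condition
|weighted mean − benchmark| ≤ 1e-10 × benchmark is asserted for every
cell before returning, and an infeasible cell (benchmark unreachable even
with all strata at 1) raises an error naming the cell. Raking is applied
to the all-cause sum (the reading most consistent with the source
methodology); a per-cause option exists through the same function.

## Life tables and Sullivan's method

Abridged life tables use the standard recursion q = n·m/(1 + (n−a)·m)
with radix 100 000, terminal q = 1 and terminal person-years l/m.
Defaults: a₀ = 0.2 for [0,1) (infant deaths cluster early), a = n/2
elsewhere. Sullivan's method discounts person-years by the all-cause YLD
rate: HALE\_x = Σ\_{y≥x} nL\_y (1 − d\_y) / l\_x, computed per draw —
never on draw means — with plain within-group weighting (no sub-group
interpolation). Years in poor health are e\_x − HALE\_x and the
proportion is their ratio. HALE "at birth" is HALE\_0; all ages are
computed and summarized.

## Summaries, significance, masking

Point estimates are draw means; 95% uncertainty intervals are the
2.5th/97.5th empirical percentiles with linear interpolation between
order statistics (pinned for reproducibility). Sexes are combined and
counties aggregated nationally by population-weighted per-draw means;
summaries are always taken after aggregation. A difference is
statistically significant when the fraction of aligned difference draws
above zero is < 2.5% or > 97.5%; ties count as not-greater (conservative).
County-race populations with mean annual population below 1 000 are
masked — flagged and excluded from disparity summaries, with unmasked
values never altered. A county-level *total population* series is the
population-weighted aggregate over races and is masked only when every
race series in that county is masked. Reported percentages are count
ratios rounded half-up to one decimal. HALE is aggregated directly with
population weights rather than recomputed from pooled life tables (the
stated procedure); the pooled alternative can be built from the same
primitives.

## Pipeline and problem sizes

Stages communicate through delimited-text files plus binary draw-cube
directories (deterministic `.npy` payloads), each stage writing a JSON
manifest of configuration hash, seed, input hashes, and output hashes and
row counts; a stage refuses to run on inputs whose hashes do not match
what their producer recorded. Per-stage seeds derive from the master seed
and the stage name, so the chain is deterministic end to end and reruns
are byte-identical.

The default problem size — 48 counties, 2 races, 19 ages, 11 years
(≈ 40 000 strata), ≈ 30 000 observations per indicator, 16 causes × 50
models, 1000 draws — was chosen so a complete run finishes in minutes on
a single core while keeping every structural feature of the full-scale
problem (spatial adjacency, mixed aggregation, draw lineage, masking).
The unit-test configurations are smaller still (typically 12 counties, 7
age groups, 4 years) except where a check is explicitly about the default
scale (parameter recovery and coverage, raking exactness).

## Known limitations

* The Laplace approximation conditions posterior draws on the estimated
  precisions; interval coverage is accordingly a few points below
  nominal rather than exact.
* Random effects are additive main effects; no space×time or age×time
  interactions.
* The YLD regressions share one covariate set across causes (configurable
  per cause); the original cause-specific covariate selections are not
  public.
* Aggregated synthetic observations follow the estimator's
  weighted-average likelihood exactly; real pooled survey counts are sums
  of heterogeneous binomials, a mild misspecification this artifact does
  not probe.
* The clip-and-rerake bound interacts with raking only when benchmarks
  approach 1; the generator's realistic YLD profile keeps this path rare
  outside targeted tests.
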
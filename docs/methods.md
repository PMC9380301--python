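# Methods

## Problem setting

A deeply phenotyped cohort observes `n` participants on `p` typed variables
(continuous, ordinal, nominal), but by design not every variable on every
participant: instruments are administered per diagnosis group and enrolment
schedule, so the matrix decomposes into overlapping participant × variable
subsets, each with its own item non-response on top. Cells a participant's
group was never meant to provide are *structurally absent* — a distinct,
type-level state that must never be imputed (e.g. an autism diagnostic
interview in a typically developing control). Within each subset, item
non-response is treated as MCAR; across the pooled matrix the block design
makes missingness MAR at worst (driven by observed variables such as age),
and MNAR mechanisms are out of scope.

## Round-Robin imputation engine

`RoundRobinImputer` implements fully conditional specification:

1. order variables by ascending missing count (`m_j`; stable ties by column
   position; a descending rule is available),
2. initialize all missing cells at column means,
3. per round, for each variable in order, fit the configured regressor of
   that variable on all other (currently completed) columns using the rows
   where the target is *originally observed*, and replace the target's
   originally missing cells with predictions,
4. stop when the largest absolute change of any imputed cell between
   consecutive rounds, standardized by the column's observed sd, drops
   below `tol` (default 1e-3), or after `max_rounds` (default 100),
5. round ordinal cells to the nearest admissible level, clipping values
   beyond the extremes.

Rounding happens once after convergence, not inside rounds: the fixed-point
iteration stays continuous, avoiding oscillation between adjacent levels.
The convergence metric and tolerance are this package's choices (no
standard exists); the default tolerance matches the scale of seed-to-seed
estimator variability observed in multiple imputation.

Strategies: `mean` and `median` (univariate baselines), `bayesian_ridge`,
`decision_tree` (unbounded depth), `extra_trees` (default 10 trees — the
configuration found best in the motivating evaluation), and
`nearest_neighbours` (k = 5, Euclidean distance on standardized predictors;
k is a documented tunable). Regressors come from scikit-learn; the engine,
schedule, convergence rule and rounding are this package's.

Each stochastic regressor's seed is drawn once per target variable and held
fixed across rounds. With fresh per-round seeds, tree predictions jitter at
the ensemble-variance scale and the iteration cannot converge under any
useful tolerance; with per-variable seeds the round map is deterministic
and a fixed point is reachable. Seed-to-seed variability is still fully
exposed through `multiple_imputation`, which re-runs the whole procedure
under derived master seeds and reports per-cell means and sds.

Nominal binary variables (sex, diagnosis) enter regressions as 0/1 codes;
they are fully observed and never imputed.

## Subset cascade

`execute_cascade` imputes the design's subsets in an optimised order. A
previously imputed subset is an *admissible* conditioner for a target only
if its participant set contains the target's — otherwise predictors would
have to be fabricated for participants outside the conditioner's coverage.
The diagnosis label is excluded from every predictor set (default
`exclusions=("diagnosis",)`) so the completed data do not leak the
case/control label into downstream analyses; sex is retained.

The ordering objective is the number of conditioning variables available to
each target, weighted by the target's block size n × p — a deterministic
proxy for "imputation power". The objective decomposes over ordered pairs
of subsets, so exhaustive search over orderings reduces to exact dynamic
programming on the 2^S lattice of imputed-subset sets (32,768 states at
S = 15, versus 15! ≈ 1.3 × 10^12 permutations). Many orders can tie at the
optimum; the tie-break prefers, at each step and among score-optimal
continuations, the target with the largest immediate gain, then the
smallest subset id — yielding the core all-participant block first and the
largest compatible block conditioned on it second. A cross-validated
objective (`cv_error`, scoring each complete order by executed-cascade
leave-one-out error) is available for small designs; it is exact but
exponential in S and is not the default.

## Evaluation

**Leave-one-observation-out MRE.** Every originally observed cell `(i, j)`
of an imputable variable is masked in turn, the full imputation re-run, and
`E(i,j) = |D_ij − D*_ij|`, `RE(i,j) = E(i,j)/|μ_j|` recorded, with `μ_j`
the mean over the variable's *original* observed set (so RE is comparable
across held-out cells and scale-invariant). `MRE(j)` is the mean of RE over
the variable's evaluated cells. Variables with `|μ_j|` below a floor
(default 1e-8) are flagged undefined and excluded rather than reported with
a meaningless ratio. Besides the exact mode (one full re-imputation per
cell, as the definition requires), a documented fast mode re-fits only the
target variable's regression on the completed matrix without the held-out
row; and the evaluated cells can be subsampled per variable (seeded) to
bound cost on larger cohorts. Exact mode is used wherever the cohort is
small enough.

**Observed-vs-imputed KL.** Per variable with at least one missing cell,
`KL(p_j ‖ q_j) = Σ p log(p/q)` in nats, where `p_j` is estimated from the
observed values and `q_j` from the imputed values at the originally missing
cells. Discrete variables use probability masses over their level sets;
continuous variables use equal-width histograms over the shared range of
observed and imputed values (default 10 bins). Both estimates receive
additive smoothing ε (default 1e-6) and renormalisation — necessary because
a point-mass imputer (the mean model) would otherwise have infinite
divergence, yet it serves as the finite reference point. Variables with no
missing cells are reported not-applicable, never zero by fiat.

**Relative plane and model comparison.** Each model's per-variable
(MRE, KL) is divided by the mean-imputation model's values; the reference
sits at (1, 1) and a model's overall error at a variable is the Euclidean
norm of its relative 2-vector. Variables where the reference is zero or
undefined on either axis are excluded and reported. Pooled model means
weight variables equally. The two best models by pooled mean norm are
compared by a paired t-test over per-variable norms (a single pre-specified
comparison); an all-pairs mode applies Holm correction.

## Synthetic cohort generator

The generator emulates the motivating study's structure: 764 participants
(453 cases, 311 controls) across diagnosis × schedule groups (child,
adolescent, adult, younger/older intellectual-disability schedules), 160
variables (2 fully observed nominals, 42 continuous, 116 ordinal) over 15
subsets whose printed sizes (e.g. subset 1: 28 variables × all
participants; subset 2: 8 × 453 cases; subset 6: 32 × 478) are reproduced
exactly. Group counts not printed in the source material were solved once
for consistency with every printed subset size. Per-subset missingness
rates are placeholders in the 5–30% range (the study's own per-subset
percentages are not machine-readable) and are not calibrated.

Values follow a latent-factor model: participant `z ~ N(0, I_K)` (default
K = 4), variable loadings `w_j ~ N(0, 1)`, per-group mean shifts, and
Gaussian noise (default sd 0.5). Cases receive a per-variable loading
perturbation (`diagnosis_loading_sd`, default 1.0), so variable–variable
relationships differ between diagnostic groups — the clinical-heterogeneity
feature that motivates non-linear imputation models. Two further realism
features shape the marginals the way clinical instruments do: continuous
variables pass the standardized latent index through a monotone
exponential transform (`continuous_skew`, default 0.7; right-skewed,
floor/ceiling-shaped scores), and ordinal level frequencies decay
geometrically (`ordinal_floor_ratio`, default 0.6; floor effects, most
participants at the lowest levels). Ordinal discretisation uses empirical
quantiles at the target level masses, keeping the discrete distributions
non-degenerate for the KL criterion. An age variable is schedule-linked
(uniform within each schedule's age band), fully observed, and available as
the MAR driver.

Missingness injection is MCAR (independent Bernoulli per eligible cell at
the subset's rate) or MAR (cell probability `expit(a + slope · age_std)`
with the intercept calibrated by root-finding so the realized rate matches
the target). Non-imputable variables, the age variable and the MAR driver
are never masked; structurally absent cells are never generated in the
first place. All randomness derives from one master seed through named
substreams (loadings, latents, noise, demographics, mask), so a
(config, seed) pair is bit-reproducible.

What the generator does **not** emulate: the actual instruments' score
distributions and ranges, longitudinal waves, site effects, and MNAR
mechanisms. Passing benchmarks on these cohorts shows the pipeline behaves
as derived under a controlled factor-mixture world; it does not certify
imputation quality on any particular real dataset.

## Numerical and design choices

- KL uses the natural logarithm; values are nats.
- Continuous KL histograms share bin edges between observed and imputed
  samples; a degenerate (zero-width) range collapses to a single bin and
  KL 0.
- The "fast" leave-one-out mode approximates the exact definition; on
  linear cohorts the two modes' per-variable MREs correlate > 0.9 (tested),
  and exact mode is used for the noiseless-limit checks.
- Benchmark-scale runs cap rounds (`max_rounds=4`) and evaluated cells
  (2 per variable) and use a ~0.26-scaled cohort (n ≈ 200); these problem
  sizes keep a full six-model comparison at a few tens of seconds per
  cohort while leaving the qualitative comparisons stable across seeds.
- In the independence limit (zero loadings) the expected relative MRE is 1
  for an unbiased smooth regressor but √(1 + 1/B) for a B-tree ensemble of
  fully grown trees (the prediction averages ~B independent draws); tests
  assert each model against its own derived limit.
- Multiple-imputation stability is summarised per variable by the mean of
  per-cell sds relative to the variable's observed sd; the per-cell maximum
  is also reported but dominated by boundary cells whose ensemble variance
  is irreducible at B = 10.

## Known limitations

- The cascade ordering objective is a proxy; orders beyond the first steps
  depend on it and may differ from orders chosen under other criteria.
- Exact leave-one-out evaluation is O(observed cells) full imputations and
  is only practical on small cohorts; fast mode and cell subsampling are
  the intended path at scale.
- Tree strategies generally reach the round cap rather than the strict
  tolerance; the cap (not the tolerance) is then the effective stopping
  rule, as in the motivating evaluation.
- KL for continuous variables depends on the binning and smoothing choices;
  only relative (model vs reference) comparisons are meaningful.
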
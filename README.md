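# blockimpute

Round-Robin multivariate imputation and benchmarking for block-structured
clinical cohorts.

Deeply phenotyped clinical studies rarely observe every measure on every
participant. Beyond ordinary item non-response, accelerated longitudinal
designs *plan* their missingness: instruments are administered only to the
diagnosis group and enrolment schedule they were designed for, so the data
matrix decomposes into overlapping participant × variable blocks ("subsets"),
each with its own missingness rate — and some cells are *structurally absent*
(never intended to be acquired) rather than missing. Imputing such a matrix
well, and knowing how well, is the problem this package addresses. It is
aimed at biostatisticians and cohort-data managers who must deliver a single
defensible completed dataset to many downstream analysts.

## The method

Let `D` be the n × p data matrix with `m` missing values (`m_j` per
variable, observed index set `O_j`). Missing values are imputed by **fully
conditional specification** with a Round-Robin schedule: variables are
visited in ascending order of `m_j`; missing cells start at their column
means; each round re-fits a regressor of the current variable on all other
(currently completed) variables using rows where the target is observed, and
replaces the target's missing cells with predictions; rounds repeat until
the largest standardized change of any imputed cell falls below a tolerance
(default 1e-3), capped at 100 rounds. Ordinal predictions are rounded to
their nearest admissible level after convergence. Six strategies plug in:
mean, median, Bayesian ridge (BR), decision tree (DT), extra trees (ET,
default 10 trees) and k-nearest neighbours (NN).

Blocks are imputed as a **cascade**: a previously imputed subset may serve
as a predictor for a target subset only if its participants contain the
target's (so no value is ever fabricated for a group it was not intended
for), and the order of subsets is optimised exactly by dynamic programming
over the 2^S lattice of imputed-subset sets. The diagnosis label is excluded
from all predictor sets to avoid biasing downstream case–control analyses.

Quality is measured per variable by two criteria, each normalised by the
mean-imputation model:

* **MRE** (leave-one-observation-out): each observed cell `(i, j)` is masked
  in turn, the imputation re-run, and
  `RE(i,j) = |D_ij − D*_ij| / |μ_j|` averaged over the variable's cells,
  where `μ_j` is the observed-column mean;
* **KL divergence** (nats) between the distribution of observed values and
  the distribution of values imputed at the missing cells, penalising
  imputers that collapse the value spread.

Dividing both by the mean-imputation values places that baseline at (1, 1)
in the relative plane; a model's overall error at a variable is the
Euclidean norm of its relative 2-vector, and models are compared by paired
t-tests over per-variable norms.

A latent-factor synthetic cohort generator reproduces the block structure of
a large autism cohort (764 participants, 453 cases / 311 controls, 160
variables over 15 subsets) with correlated continuous and ordinal variables,
diagnosis-dependent factor loadings, MCAR or MAR missingness, and exact
ground truth for oracle evaluation.

## Worked example

```python
import blockimpute as bi
from blockimpute.evaluation import EvalConfig

matrix, design, truth = bi.generate_cohort(
    bi.leap_like_config(participant_scale=0.26), seed=11)
plan = bi.search_cascade_plan(design)
print([ (s.target, s.conditioners) for s in plan.steps[:2] ])

models = {name: bi.ImputerConfig(strategy=name, max_rounds=4, seed=0)
          for name in ("mean", "median", "bayesian_ridge", "extra_trees")}
result = bi.run_benchmark(matrix, design, models, plan=plan,
                          config=EvalConfig(loo_mode="fast",
                                            max_cells_per_variable=2, seed=11))
print(result.pooled.round(3))
```

prints

```
[(1, ()), (3, (1,))]
                rel_mre  rel_kl   norm
model
bayesian_ridge    0.519   0.132  0.584
extra_trees       0.620   0.138  0.675
mean              1.000   1.000  1.414
median            1.232   0.944  1.649
```

The cascade starts with the all-participant core block and conditions the
next block on it. In the relative plane the univariate baselines sit at a
norm of √2 ≈ 1.41 or worse, the multivariate models far below it: on this
synthetic cohort Bayesian ridge cuts the leave-one-out relative error
roughly in half and both multivariate models cut the observed-vs-imputed
divergence by ~87% — the pattern the benchmark is designed to expose and
quantify.

A `blockimpute` command-line tool wraps the same pipeline
(`blockimpute generate | plan | impute | benchmark --config run.yaml`),
writing result tables and a reproducibility manifest.

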
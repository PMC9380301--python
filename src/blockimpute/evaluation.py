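"""Two-criterion evaluation of imputation quality.

Accuracy — leave-one-observation-out cross-validation: every originally
observed cell ``(i, j)`` is masked in turn (so the problem has ``m + 1``
missing values), the full imputation is re-run, and the error is

    E(i, j)  = |D_ij - D*_ij|
    RE(i, j) = E(i, j) / |mu_j|,   mu_j = mean of the observed column j
    MRE(j)   = mean of RE(., j) over the evaluated cells of variable j.

Dividing by the observed-column mean makes errors comparable across
variables on different scales: RE = 1 means the error is as large as the
variable's typical value.

Distributional fidelity — per variable, the Kullback-Leibler divergence
(natural log) between the distribution of observed values ``p_j`` and the
distribution of values imputed at the originally missing cells ``q_j``.
This penalises imputers that collapse the value distribution (a regressor
that always predicts the conditional mean can score well on MRE while
shrinking the spread). Discrete variables use probability masses over their
level sets; continuous variables use shared equal-width histogram bins over
the union of observed and imputed ranges. Both distributions receive a
small additive smoothing so the divergence stays finite even for a
point-mass imputer such as the mean.

The two criteria live on different scales, so each model's per-variable
(MRE, KL) is divided by the mean-imputation model's values: mean imputation
sits at (1, 1) in this relative plane, and a model's overall quality at a
variable is the Euclidean norm of its relative 2-vector. Models are
compared by a paired t-test over per-variable norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import DEFAULT_EXCLUSIONS, CascadePlan, execute_cascade
from .cohort import ClinicalMatrix, SubsetDesign
from .exceptions import ConfigError, DegenerateTestError
from .imputer import (
    UNIVARIATE,
    ImputedMatrix,
    ImputerConfig,
    impute,
    round_and_clip,
)


@dataclass
class EvalConfig:
    """Evaluation settings: histogram bins and smoothing for the KL
    criterion, leave-one-out mode and cell budget, and the seed."""

    bins: int = 10
    epsilon: float = 1e-6
    loo_mode: str = "exact"
    max_cells_per_variable: int | None = None
    seed: int = 0
    mu_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.bins < 1:
            raise ConfigError("bins must be >= 1")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.loo_mode not in ("exact", "fast"):
            raise ConfigError(f"unknown loo mode {self.loo_mode!r}")


def _column_means(matrix: ClinicalMatrix) -> pd.Series:
    """mu_j over the original observed set O_j, per variable."""
    return matrix.values.mean(axis=0, skipna=True)


def _evaluable_cells(matrix: ClinicalMatrix, rng, max_cells_per_variable):
    """(participant, variable) pairs to hold out: observed cells of
    imputable variables, optionally subsampled per variable."""
    cells = []
    for name in matrix.variable_names:
        if not matrix.spec(name).imputable:
            continue
        obs = list(matrix.observed_index(name))
        if max_cells_per_variable is not None and len(obs) > max_cells_per_variable:
            pick = rng.choice(len(obs), size=max_cells_per_variable, replace=False)
            obs = [obs[k] for k in sorted(pick)]
        cells.extend((pid, name) for pid in obs)
    return cells


def loo_cv_errors(
    matrix: ClinicalMatrix,
    imputer_config: ImputerConfig,
    design: SubsetDesign | None = None,
    plan: CascadePlan | None = None,
    mode: str = "exact",
    max_cells_per_variable: int | None = None,
    seed: int | None = 0,
    mu_floor: float = 1e-8,
    exclusions=DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """Leave-one-observation-out errors for every evaluated cell.

    ``exact`` mode re-runs the complete imputation (cascade if a design and
    plan are given) once per held-out cell, exactly as the evaluation is
    defined. ``fast`` mode runs the base imputation once and, per held-out
    cell, re-fits only the target variable's regression on the completed
    matrix without that row — a documented approximation that scales to
    larger cohorts.

    Returns a frame with columns participant, variable, true, imputed, e,
    re, undefined. ``undefined`` flags variables whose |mu_j| is below
    ``mu_floor`` (their RE is not interpretable and is excluded from MRE).
    """
    if mode not in ("exact", "fast"):
        raise ConfigError(f"unknown loo mode {mode!r}")
    if plan is not None and design is None:
        raise ConfigError("a plan requires its design")
    rng = np.random.default_rng(seed)
    mu = _column_means(matrix)
    cells = _evaluable_cells(matrix, rng, max_cells_per_variable)
    if not cells:
        raise ConfigError("no observed cells to evaluate")

    records = []
    if mode == "exact":
        for pid, name in cells:
            perturbed = matrix.copy()
            perturbed.values.loc[pid, name] = np.nan
            cfg = imputer_config
            if imputer_config.seed is not None:
                cfg = imputer_config.with_seed(int(rng.integers(0, 2**31 - 1)))
            if plan is not None:
                result = execute_cascade(
                    perturbed, design, plan, cfg, exclusions=exclusions
                )
            else:
                result = impute(perturbed, cfg)
            records.append((pid, name, result.values.loc[pid, name]))
    else:
        records = _loo_fast(
            matrix, imputer_config, design, plan, cells, rng, exclusions
        )

    rows = []
    for pid, name, imputed in records:
        true = matrix.values.loc[pid, name]
        e = abs(true - imputed)
        undefined = abs(mu[name]) < mu_floor
        re = np.nan if undefined else e / abs(mu[name])
        rows.append(
            {
                "participant": pid,
                "variable": name,
                "true": true,
                "imputed": imputed,
                "e": e,
                "re": re,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def _loo_fast(matrix, imputer_config, design, plan, cells, rng, exclusions):
    """Fast leave-one-out: impute once, then per held-out cell re-fit only
    the target variable's final regression on the completed matrix."""
    if plan is not None:
        base = execute_cascade(matrix, design, plan, imputer_config, exclusions)
    else:
        base = impute(matrix, imputer_config)
    completed = base.values
    excl = set(exclusions) if plan is not None else set()

    predictors_of = {}
    for name in {c[1] for c in cells}:
        if design is not None and plan is not None:
            owner = design.subset_of_variable(name)
            step = next(s for s in plan.steps if s.target == owner.subset_id)
            cols = [v for v in owner.variables if v != name and v not in excl]
            for c in step.conditioners:
                cols.extend(
                    v for v in design.subset(c).variables if v not in excl
                )
            row_pool = [
                p for p in matrix.participant_ids if p in owner.participants
            ]
        else:
            cols = [v for v in matrix.variable_names if v != name]
            row_pool = matrix.participant_ids
        predictors_of[name] = (cols, row_pool)

    est_factory = imputer_config.make_estimator()
    records = []
    for pid, name in cells:
        obs = [p for p in matrix.observed_index(name) if p != pid]
        if imputer_config.strategy in UNIVARIATE:
            col = matrix.values.loc[obs, name]
            value = col.mean() if imputer_config.strategy == "mean" else col.median()
        else:
            cols, row_pool = predictors_of[name]
            train = [p for p in obs if p in set(row_pool)]
            reg = est_factory._fresh_regressor(rng)
            reg.fit(
                completed.loc[train, cols].to_numpy(),
                matrix.values.loc[train, name].to_numpy(),
            )
            value = float(
                reg.predict(completed.loc[[pid], cols].to_numpy())[0]
            )
        value = float(round_and_clip([value], matrix.spec(name))[0])
        records.append((pid, name, value))
    return records


def mre_per_variable(errors: pd.DataFrame) -> pd.Series:
    """MRE(j): mean relative error over each variable's evaluated cells;
    variables flagged undefined are dropped."""
    ok = errors[~errors["undefined"]]
    return ok.groupby("variable")["re"].mean()


def _histogram(values, spec, edges, bins):
    values = np.asarray(values, dtype=float)
    if spec.is_discrete:
        levels = np.asarray(spec.levels)
        counts = np.array([(values == lv).sum() for lv in levels], dtype=float)
    else:
        counts, _ = np.histogram(values, bins=edges)
        counts = counts.astype(float)
    return counts


def kl_per_variable(
    matrix: ClinicalMatrix,
    imputed,
    bins: int = 10,
    epsilon: float = 1e-6,
) -> pd.Series:
    """KL(p_j || q_j) per variable, in nats.

    ``p_j`` is estimated from the originally observed values, ``q_j`` from
    the imputed values at the originally missing cells. Variables with no
    missing cells get NaN (not applicable — never zero by fiat). Both
    histograms receive additive smoothing ``epsilon`` and are renormalized,
    keeping the divergence finite for degenerate (point-mass) imputers.
    """
    values = imputed.values if isinstance(imputed, ImputedMatrix) else imputed
    mask = matrix.missing_mask
    out = {}
    for name in matrix.variable_names:
        spec = matrix.spec(name)
        if not spec.imputable:
            continue
        miss_rows = mask.index[mask[name]]
        if len(miss_rows) == 0:
            out[name] = np.nan
            continue
        obs = matrix.values.loc[matrix.observed_index(name), name].to_numpy()
        imp = values.loc[miss_rows, name].to_numpy(dtype=float)
        if spec.is_discrete:
            edges = None
        else:
            lo = min(obs.min(), imp.min())
            hi = max(obs.max(), imp.max())
            if hi <= lo:
                hi = lo + 1e-12
            edges = np.linspace(lo, hi, bins + 1)
        p = _histogram(obs, spec, edges, bins) + epsilon
        q = _histogram(imp, spec, edges, bins) + epsilon
        out[name] = float(stats.entropy(p / p.sum(), q / q.sum()))
    return pd.Series(out, name="kl")


def error_norm(rel_mre, rel_kl) -> float:
    """Euclidean norm of the relative 2-vector (mean imputation -> sqrt 2)."""
    return float(np.hypot(rel_mre, rel_kl))


@dataclass
class RelativePoints:
    """Per-variable relative-plane coordinates for each model, plus the
    variables excluded because the reference value was zero or undefined."""

    points: pd.DataFrame  # model, variable, mre, kl, rel_mre, rel_kl, norm
    excluded: list = field(default_factory=list)


def relative_to_reference(
    profiles: dict, reference: str = "mean"
) -> RelativePoints:
    """Divide each model's per-variable MRE and KL by the reference model's
    (mean imputation by default); the reference maps to (1, 1).

    ``profiles`` maps model name -> DataFrame indexed by variable with
    columns ``mre`` and ``kl``. Variables where the reference is 0 or NaN
    on either criterion are excluded and reported.
    """
    if reference not in profiles:
        raise ConfigError(f"reference model {reference!r} has no profile")
    ref = profiles[reference]
    usable = ref.index[
        (ref["mre"] > 0)
        & (ref["kl"] > 0)
        & ref["mre"].notna()
        & ref["kl"].notna()
    ]
    excluded = sorted(set(ref.index) - set(usable))
    rows = []
    for model, prof in profiles.items():
        prof = prof.loc[[v for v in usable if v in prof.index]]
        rel_mre = prof["mre"] / ref.loc[prof.index, "mre"]
        rel_kl = prof["kl"] / ref.loc[prof.index, "kl"]
        for v in prof.index:
            rows.append(
                {
                    "model": model,
                    "variable": v,
                    "mre": prof.loc[v, "mre"],
                    "kl": prof.loc[v, "kl"],
                    "rel_mre": rel_mre[v],
                    "rel_kl": rel_kl[v],
                    "norm": error_norm(rel_mre[v], rel_kl[v]),
                }
            )
    return RelativePoints(points=pd.DataFrame(rows), excluded=excluded)


@dataclass
class PairedTest:
    t: float
    p: float
    mean_diff: float  # mean(a - b); negative favours a
    n: int


def paired_model_test(norms_a, norms_b) -> PairedTest:
    """Paired t-test on per-variable error norms of two models (same
    variables, same order)."""
    a = np.asarray(norms_a, dtype=float)
    b = np.asarray(norms_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired test needs two equal-length vectors")
    if a.size < 2:
        raise ConfigError("paired test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateTestError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return PairedTest(t=float(t), p=float(p), mean_diff=float(d.mean()), n=a.size)


@dataclass
class BenchmarkResult:
    """A full model-comparison run: per-variable relative points, per-subset
    and pooled model means, the ranking by mean norm, and the paired test
    between the two best models."""

    points: pd.DataFrame
    subset_means: pd.DataFrame
    pooled: pd.DataFrame
    ranking: list
    top_pair_test: PairedTest | None
    pairwise_tests: pd.DataFrame | None
    excluded_variables: list


def run_benchmark(
    matrix: ClinicalMatrix,
    design: SubsetDesign | None,
    models: dict,
    plan: CascadePlan | None = None,
    config: EvalConfig | None = None,
    reference: str = "mean",
    all_pairs: bool = False,
) -> BenchmarkResult:
    """Evaluate every model on the two criteria and place them on the
    relative plane.

    ``models`` maps model name -> :class:`ImputerConfig`; the reference
    (mean imputation) is added if absent. Per model, the leave-one-out MRE
    and the observed-vs-imputed KL are computed per variable, divided by the
    reference's values, pooled (equal variable weights) and ranked by mean
    2-D norm; the two best models are compared by a paired t-test. With
    ``all_pairs`` every model pair is tested with Holm correction.
    """
    config = config or EvalConfig()
    models = dict(models)
    if reference not in models:
        models[reference] = ImputerConfig(strategy="mean")
    if len(models) < 2:
        raise ConfigError("benchmark needs at least 2 models")
    rng = np.random.default_rng(config.seed)

    profiles = {}
    for name, icfg in models.items():
        model_seed = int(rng.integers(0, 2**31 - 1))
        errors = loo_cv_errors(
            matrix,
            icfg,
            design=design,
            plan=plan,
            mode=config.loo_mode,
            max_cells_per_variable=config.max_cells_per_variable,
            seed=model_seed,
            mu_floor=config.mu_floor,
        )
        mre = mre_per_variable(errors)
        if plan is not None:
            imputed = execute_cascade(
                matrix, design, plan, icfg.with_seed(model_seed)
            )
        else:
            imputed = impute(matrix, icfg.with_seed(model_seed))
        kl = kl_per_variable(
            matrix, imputed, bins=config.bins, epsilon=config.epsilon
        )
        profiles[name] = pd.DataFrame({"mre": mre, "kl": kl}).dropna()

    rel = relative_to_reference(profiles, reference=reference)
    points = rel.points

    if design is not None:
        subset_of = {
            v: s.subset_id for s in design.subsets for v in s.variables
        }
        points = points.assign(
            subset_id=points["variable"].map(subset_of)
        )
        subset_means = (
            points.groupby(["subset_id", "model"])[["rel_mre", "rel_kl", "norm"]]
            .mean()
            .reset_index()
        )
    else:
        subset_means = pd.DataFrame()

    pooled = (
        points.groupby("model")[["rel_mre", "rel_kl", "norm"]].mean().sort_values("norm")
    )
    ranking = list(pooled.index)

    wide = points.pivot(index="variable", columns="model", values="norm").dropna()
    top_pair_test = None
    if len(ranking) >= 2 and len(wide) >= 2:
        a, b = ranking[0], ranking[1]
        try:
            top_pair_test = paired_model_test(wide[a], wide[b])
        except DegenerateTestError:
            top_pair_test = None

    pairwise = None
    if all_pairs:
        from itertools import combinations

        from statsmodels.stats.multitest import multipletests

        rows = []
        for a, b in combinations(ranking, 2):
            try:
                res = paired_model_test(wide[a], wide[b])
                rows.append({"model_a": a, "model_b": b, "t": res.t, "p": res.p})
            except DegenerateTestError:
                rows.append({"model_a": a, "model_b": b, "t": np.nan, "p": np.nan})
        pairwise = pd.DataFrame(rows)
        ok = pairwise["p"].notna()
        adj = np.full(len(pairwise), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                pairwise.loc[ok, "p"], method="holm"
            )[1]
        pairwise["p_holm"] = adj

    return BenchmarkResult(
        points=points,
        subset_means=subset_means,
        pooled=pooled,
        ranking=ranking,
        top_pair_test=top_pair_test,
        pairwise_tests=pairwise,
        excluded_variables=rel.excluded,
    )
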
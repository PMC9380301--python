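"""Round-Robin (fully conditional specification) imputation.

Every variable with missing values is treated as a regression target in
turn: missing cells start at their column means, then each round re-fits
the configured regressor of the target on all other (currently completed)
columns using rows where the target was originally observed, and replaces
the target's missing cells by the predictions. Rounds repeat until the
largest standardized change of any imputed cell drops below the tolerance,
or a hard round cap is reached. Ordinal predictions are rounded to their
nearest admissible level (and clipped to the extremes) once after
convergence, so the fixed-point iteration itself stays continuous.

Six strategies are supported: the univariate mean / median baselines and
four multivariate regressors — Bayesian ridge, decision tree, extra trees
(default 10 trees) and k-nearest neighbours on standardized predictors.

:class:`RoundRobinImputer` is a scikit-learn estimator (``fit`` /
``transform`` / ``fit_transform``, ``get_params``); :func:`impute` wraps it
for :class:`~blockimpute.cohort.ClinicalMatrix` inputs, handling ordinal
rounding and structural absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import BayesianRidge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import ClinicalMatrix, VariableSpec
from .exceptions import ConfigError, UnimputableError

STRATEGIES = (
    "mean",
    "median",
    "bayesian_ridge",
    "decision_tree",
    "extra_trees",
    "nearest_neighbours",
)

UNIVARIATE = ("mean", "median")
STOCHASTIC = ("decision_tree", "extra_trees")


@dataclass(frozen=True)
class ImputerConfig:
    """Declarative imputer settings; maps 1:1 onto RoundRobinImputer params."""

    strategy: str = "extra_trees"
    max_rounds: int = 100
    tol: float = 1e-3
    order: str = "ascending_missing"
    n_estimators: int = 10
    n_neighbors: int = 5
    max_depth: int | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if not self.tol > 0:
            raise ConfigError("tol must be > 0")
        if self.order not in ("ascending_missing", "descending_missing"):
            raise ConfigError(f"unknown order rule {self.order!r}")

    def make_estimator(self) -> "RoundRobinImputer":
        return RoundRobinImputer(
            strategy=self.strategy,
            max_rounds=self.max_rounds,
            tol=self.tol,
            order=self.order,
            n_estimators=self.n_estimators,
            n_neighbors=self.n_neighbors,
            max_depth=self.max_depth,
            random_state=self.seed,
        )

    def with_seed(self, seed) -> "ImputerConfig":
        return replace(self, seed=None if seed is None else int(seed))


@dataclass
class ImputedMatrix:
    """A completed matrix D* with provenance of the imputation run."""

    values: pd.DataFrame
    mask: pd.DataFrame  # True at originally missing (now filled) cells
    rounds: int
    converged: bool
    trace: list = field(default_factory=list)  # per-round max std. change

    @property
    def matrix(self) -> pd.DataFrame:
        return self.values


def variable_order(matrix, rule: str = "ascending_missing"):
    """Order variable names by missing count under ``rule``; stable, so ties
    keep the original column order."""
    if rule not in ("ascending_missing", "descending_missing"):
        raise ConfigError(f"unknown order rule {rule!r}")
    m_j = matrix.m_j if isinstance(matrix, ClinicalMatrix) else matrix.isna().sum()
    names = list(m_j.index)
    reverse = rule == "descending_missing"
    key = (-m_j).to_numpy() if reverse else m_j.to_numpy()
    order = np.argsort(key, kind="stable")
    return [names[i] for i in order]


def round_and_clip(predictions, spec: VariableSpec):
    """Map regression predictions onto an ordinal variable's level set:
    nearest level, with out-of-range values clipped to the extreme levels.
    Continuous specs pass through unchanged."""
    predictions = np.asarray(predictions, dtype=float)
    if not spec.is_discrete:
        return predictions
    levels = np.asarray(spec.levels, dtype=float)
    idx = np.abs(predictions[:, None] - levels[None, :]).argmin(axis=1)
    return levels[idx]


class RoundRobinImputer(BaseEstimator, TransformerMixin):
    """Chained-equations imputer with a pluggable per-variable regressor.

    Parameters
    ----------
    strategy : str
        One of ``mean``, ``median``, ``bayesian_ridge``, ``decision_tree``,
        ``extra_trees``, ``nearest_neighbours``.
    max_rounds : int
        Hard cap on Round-Robin rounds (multivariate strategies).
    tol : float
        Convergence tolerance on the maximum absolute change of any imputed
        cell between consecutive rounds, on a per-column standardized scale.
    order : str
        ``ascending_missing`` (default) or ``descending_missing``.
    n_estimators, n_neighbors, max_depth :
        Hyperparameters forwarded to the underlying regressor.
    random_state : int or None
        Seeds the stochastic regressors (trees).

    Attributes
    ----------
    statistics_ : ndarray
        Column means (or medians for the median strategy) used for
        initialization / univariate filling.
    regressors_ : list of list
        Per executed round, the fitted regressor for each targeted column
        (multivariate strategies), replayed by :meth:`transform`.
    feature_order_ : ndarray
        Column indices in imputation order.
    n_rounds_ : int
    converged_ : bool
    trace_ : list of float
        Per-round maximum standardized absolute change.
    """

    def __init__(
        self,
        strategy: str = "extra_trees",
        max_rounds: int = 100,
        tol: float = 1e-3,
        order: str = "ascending_missing",
        n_estimators: int = 10,
        n_neighbors: int = 5,
        max_depth=None,
        random_state=None,
    ):
        self.strategy = strategy
        self.max_rounds = max_rounds
        self.tol = tol
        self.order = order
        self.n_estimators = n_estimators
        self.n_neighbors = n_neighbors
        self.max_depth = max_depth
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _validate(self, X):
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if not self.tol > 0:
            raise ConfigError("tol must be > 0")
        X = check_array(
            X, dtype=float, ensure_all_finite="allow-nan", ensure_min_features=1
        )
        miss = np.isnan(X)
        if miss.all(axis=0).any():
            raise UnimputableError("a column has no observed values")
        if self.strategy not in UNIVARIATE and X.shape[1] < 2:
            raise ConfigError(
                "multivariate strategies need at least 2 variables"
            )
        return X, miss

    def _fresh_regressor(self, rng, seed=None):
        """Build the configured regressor; a fixed ``seed`` (used per target
        variable) keeps the Round-Robin map deterministic across rounds so
        tree strategies can reach a fixed point instead of jittering."""
        if seed is None:
            seed = int(rng.integers(0, 2**31 - 1))
        if self.strategy == "bayesian_ridge":
            return BayesianRidge()
        if self.strategy == "decision_tree":
            return DecisionTreeRegressor(
                max_depth=self.max_depth, random_state=seed
            )
        if self.strategy == "extra_trees":
            return ExtraTreesRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=seed,
            )
        if self.strategy == "nearest_neighbours":
            return make_pipeline(
                StandardScaler(),
                KNeighborsRegressor(n_neighbors=self.n_neighbors),
            )
        raise ConfigError(f"{self.strategy!r} has no regressor")  # pragma: no cover

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        """Run the Round-Robin procedure on ``X``, storing the fitted
        per-round regressors so :meth:`transform` can replay them."""
        X, miss = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        means = np.nanmean(X, axis=0)
        if self.strategy == "median":
            self.statistics_ = np.nanmedian(X, axis=0)
        else:
            self.statistics_ = means
        self.n_features_in_ = X.shape[1]
        self.regressors_ = []
        self.trace_ = []

        if self.strategy in UNIVARIATE:
            self.feature_order_ = np.arange(X.shape[1])
            self.n_rounds_ = 1
            self.converged_ = True
            self._fitted_X = self._fill_univariate(X, miss)
            return self

        # scale for the convergence criterion: observed per-column std
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scale = np.nanstd(X, axis=0)
        scale[~np.isfinite(scale) | (scale == 0)] = 1.0

        m_j = miss.sum(axis=0)
        key = -m_j if self.order == "descending_missing" else m_j
        if self.order not in ("ascending_missing", "descending_missing"):
            raise ConfigError(f"unknown order rule {self.order!r}")
        self.feature_order_ = np.argsort(key, kind="stable")

        work = X.copy()
        work[miss] = np.take(means, np.nonzero(miss)[1])
        targets = [j for j in self.feature_order_ if m_j[j] > 0]
        self._fit_targets_ = targets
        other = {j: np.delete(np.arange(X.shape[1]), j) for j in targets}
        col_seed = {j: int(rng.integers(0, 2**31 - 1)) for j in targets}

        self.converged_ = False
        self.n_rounds_ = 0
        for _ in range(self.max_rounds):
            round_regs = []
            max_change = 0.0
            for j in targets:
                obs = ~miss[:, j]
                reg = self._fresh_regressor(rng, seed=col_seed[j])
                reg.fit(work[np.ix_(obs, other[j])], X[obs, j])
                pred = reg.predict(work[np.ix_(miss[:, j], other[j])])
                change = np.abs(pred - work[miss[:, j], j]) / scale[j]
                if change.size:
                    max_change = max(max_change, float(change.max()))
                work[miss[:, j], j] = pred
                round_regs.append(reg)
            self.regressors_.append(round_regs)
            self.trace_.append(max_change)
            self.n_rounds_ += 1
            if max_change < self.tol:
                self.converged_ = True
                break
        self._fitted_X = work
        return self

    def _fill_univariate(self, X, miss):
        out = X.copy()
        out[miss] = np.take(self.statistics_, np.nonzero(miss)[1])
        return out

    def transform(self, X):
        """Complete ``X`` by replaying the fitted imputation sequence."""
        check_is_fitted(self, "statistics_")
        X, miss = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ConfigError("transform with a different number of columns")
        if self.strategy in UNIVARIATE:
            return self._fill_univariate(X, miss)
        work = X.copy()
        means = np.nanmean(X, axis=0)
        work[miss] = np.take(means, np.nonzero(miss)[1])
        for round_regs in self.regressors_:
            for j, reg in zip(self._fit_targets_, round_regs):
                if not miss[:, j].any():
                    continue
                other = np.delete(np.arange(X.shape[1]), j)
                work[miss[:, j], j] = reg.predict(work[np.ix_(miss[:, j], other)])
        return work

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self._fitted_X.copy()


# ---------------------------------------------------------------------------
# ClinicalMatrix front end
# ---------------------------------------------------------------------------


def impute(matrix: ClinicalMatrix, config: ImputerConfig) -> ImputedMatrix:
    """Impute every missing cell of ``matrix`` with the configured strategy.

    Structurally absent cells are filled internally so they can serve as
    predictors, but are restored to absent in the output and excluded from
    the convergence trace's notion of "imputed cells" only insofar as they
    are never reported; ordinal and nominal imputed cells are rounded to
    their level sets after convergence. Observed cells are returned
    untouched, bit for bit.
    """
    est = config.make_estimator()
    X = matrix.values.to_numpy(dtype=float)
    completed = est.fit_transform(X)
    mask = matrix.missing_mask
    out = matrix.values.copy()
    miss_np = mask.to_numpy()
    for k, name in enumerate(matrix.variable_names):
        rows = miss_np[:, k]
        if not rows.any():
            continue
        out.iloc[rows, k] = round_and_clip(completed[rows, k], matrix.spec(name))
    return ImputedMatrix(
        values=out,
        mask=mask,
        rounds=est.n_rounds_,
        converged=est.converged_,
        trace=list(est.trace_),
    )


def multiple_imputation(matrix: ClinicalMatrix, config: ImputerConfig, n_seeds: int):
    """Repeat stochastic imputation under ``n_seeds`` derived seeds and
    summarise per-cell variability.

    Returns a dict with ``cell_mean`` / ``cell_sd`` (DataFrames defined at
    originally missing cells, NaN elsewhere) and ``per_variable_max_sd``.
    Deterministic strategies trigger a warning: their sd is identically 0.
    """
    if n_seeds < 1:
        raise ConfigError("n_seeds must be >= 1")
    if config.strategy not in STOCHASTIC:
        warnings.warn(
            f"strategy {config.strategy!r} is deterministic; "
            "multiple imputation sd will be 0",
            stacklevel=2,
        )
    base = 0 if config.seed is None else int(config.seed)
    child_seeds = np.random.SeedSequence(base).generate_state(n_seeds) % (2**31 - 1)
    stack = []
    for s in child_seeds:
        result = impute(matrix, config.with_seed(int(s)))
        stack.append(result.values.to_numpy(dtype=float))
    cube = np.stack(stack)  # (n_seeds, n, p)
    mask = matrix.missing_mask
    mean = pd.DataFrame(
        cube.mean(axis=0), index=matrix.values.index, columns=matrix.values.columns
    ).where(mask)
    sd = pd.DataFrame(
        cube.std(axis=0, ddof=0),
        index=matrix.values.index,
        columns=matrix.values.columns,
    ).where(mask)
    per_var = sd.max(axis=0).fillna(0.0)
    return {"cell_mean": mean, "cell_sd": sd, "per_variable_max_sd": per_var}
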
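import numpy as np
import pandas as pd
import pytest

from blockimpute import ClinicalMatrix, Subset, SubsetDesign, VariableSpec
from blockimpute.synthetic import CohortConfig, SubsetLayout, generate_cohort

TWO_GROUPS = (("case", "adult"), ("control", "adult"))


def two_group_cohort(
    n_per_group=100,
    p_continuous=10,
    p_ordinal=0,
    rate=0.2,
    n_factors=1,
    loading_scale=1.0,
    noise_sd=0.0,
    diagnosis_loading_sd=0.0,
    seed=42,
    **kw,
):
    """One-subset cohort of two equally sized groups; the workhorse for
    imputer and evaluation tests. Skew and floor effects are off so the
    linear-Gaussian limits (rank-1 / noiseless / independence) are exact."""
    kw.setdefault("continuous_skew", 0.0)
    kw.setdefault("ordinal_floor_ratio", 1.0)
    config = CohortConfig(
        group_counts={g: n_per_group for g in TWO_GROUPS},
        subsets=[SubsetLayout(1, TWO_GROUPS, 0, p_continuous, p_ordinal, rate)],
        n_factors=n_factors,
        loading_scale=loading_scale,
        noise_sd=noise_sd,
        diagnosis_loading_sd=diagnosis_loading_sd,
        group_shift_sd=0.0,
        age_variable=False,
        **kw,
    )
    return generate_cohort(config, seed)


@pytest.fixture
def rank1_cohort():
    """Noiseless rank-1 cohort: every variable is an exact affine function
    of one latent factor, so a multivariate imputer can recover missing
    values exactly."""
    return two_group_cohort(seed=42)


@pytest.fixture
def small_matrix():
    """A 4x3 hand-built matrix: one continuous, one ordinal, one fully
    observed continuous column; two missing cells."""
    values = pd.DataFrame(
        {
            "x": [2.0, 4.0, np.nan, 6.0],
            "score": [0.0, np.nan, 3.0, 1.0],
            "z": [1.0, 2.0, 3.0, 4.0],
        },
        index=["a", "b", "c", "d"],
    )
    specs = [
        VariableSpec("x", "continuous"),
        VariableSpec("score", "ordinal", levels=(0, 1, 2, 3)),
        VariableSpec("z", "continuous"),
    ]
    return ClinicalMatrix(values, specs)


def random_matrix(rng, n=50, p=10, rate=0.2, prefix="v"):
    """Random continuous matrix with MCAR holes (no structural absences)."""
    values = rng.normal(5.0, 2.0, size=(n, p))
    holes = rng.random((n, p)) < rate
    # keep at least one observed value per column
    holes[0, :] = False
    values = np.where(holes, np.nan, values)
    frame = pd.DataFrame(
        values,
        index=[f"r{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(p)],
    )
    specs = [VariableSpec(c, "continuous") for c in frame.columns]
    return ClinicalMatrix(frame, specs)


def random_design(rng, n_subsets, pool_size=12):
    """Random nested-ish subset design over a shared participant pool, for
    exercising the plan search. Variables are abstract names."""
    pool = [f"p{i}" for i in range(pool_size)]
    subsets = []
    for sid in range(1, n_subsets + 1):
        size = int(rng.integers(2, pool_size + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False))
        n_vars = int(rng.integers(1, 6))
        variables = tuple(f"s{sid}_v{k}" for k in range(n_vars))
        subsets.append(Subset(sid, members, variables))
    return SubsetDesign(subsets=subsets)
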
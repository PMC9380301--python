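import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blockimpute import (
    ClinicalMatrix,
    ConfigError,
    DegenerateTestError,
    ImputerConfig,
    VariableSpec,
    error_norm,
    kl_per_variable,
    loo_cv_errors,
    mre_per_variable,
    paired_model_test,
    relative_to_reference,
    run_benchmark,
)
from blockimpute.imputer import ImputedMatrix

from conftest import random_matrix, two_group_cohort


def loo_mean_oracle(matrix):
    """Closed form for the mean strategy: the imputed value at a held-out
    observed cell (i, j) is the mean of O_j without i."""
    mu = matrix.values.mean()
    rows = []
    for v in matrix.variable_names:
        col = matrix.values[v].dropna()
        for pid, true in col.items():
            imputed = col.drop(index=pid).mean()
            rows.append((pid, v, abs(true - imputed) / abs(mu[v])))
    return pd.DataFrame(rows, columns=["participant", "variable", "re"])


class TestLooErrors:
    def test_mean_strategy_matches_closed_form_oracle(self):
        rng = np.random.default_rng(21)
        mat = random_matrix(rng, n=50, p=10)
        errors = loo_cv_errors(mat, ImputerConfig(strategy="mean"), mode="exact")
        oracle = loo_mean_oracle(mat)
        merged = errors.merge(oracle, on=["participant", "variable"], suffixes=("", "_o"))
        assert len(merged) == len(errors) == (mat.n * mat.p - mat.m)
        assert np.allclose(merged["re"], merged["re_o"])

    def test_hand_example_single_column(self):
        # observed {2, 4, 6}: masking the 6 imputes mean(2, 4) = 3,
        # E = 3 and RE = 3/4 since mu = 4 over the original observed set
        frame = pd.DataFrame(
            {"a": [2.0, 4.0, 6.0, np.nan], "b": [1.0, 1.0, 1.0, 1.0]},
            index=list("wxyz"),
        )
        mat = ClinicalMatrix(frame, [VariableSpec(c, "continuous") for c in "ab"])
        errors = loo_cv_errors(mat, ImputerConfig(strategy="mean"), mode="exact")
        row = errors.set_index(["participant", "variable"]).loc[("y", "a")]
        assert row["e"] == pytest.approx(3.0)
        assert row["re"] == pytest.approx(0.75)

    def test_perfect_imputer_on_noiseless_cohort_has_zero_error(self, rank1_cohort):
        mat, _, _ = rank1_cohort
        errors = loo_cv_errors(
            mat,
            ImputerConfig(strategy="bayesian_ridge", max_rounds=10),
            mode="exact",
            max_cells_per_variable=3,
            seed=0,
        )
        assert errors["e"].max() < 1e-3

    def test_near_zero_column_mean_flags_undefined(self):
        frame = pd.DataFrame(
            {"a": [-1.0, 1.0, np.nan, 0.0], "b": [5.0, 6.0, 7.0, 8.0]},
            index=list("wxyz"),
        )
        mat = ClinicalMatrix(frame, [VariableSpec(c, "continuous") for c in "ab"])
        errors = loo_cv_errors(mat, ImputerConfig(strategy="mean"), mode="exact")
        assert errors.loc[errors.variable == "a", "undefined"].all()
        assert not errors.loc[errors.variable == "b", "undefined"].any()
        # undefined variables drop out of the MRE summary
        assert list(mre_per_variable(errors).index) == ["b"]

    def test_re_is_scale_invariant(self):
        rng = np.random.default_rng(22)
        mat = random_matrix(rng, n=20, p=3)
        base = loo_cv_errors(mat, ImputerConfig(strategy="mean"), mode="exact")
        for c in (0.01, -3.0, 1000.0):
            scaled = ClinicalMatrix(mat.values * c, mat.specs)
            res = loo_cv_errors(scaled, ImputerConfig(strategy="mean"), mode="exact")
            assert np.allclose(res["re"], base["re"])

    def test_fast_mode_approximates_exact_for_linear_model(self):
        mat, *_ = two_group_cohort(
            n_per_group=40, p_continuous=5, rate=0.2, noise_sd=0.2, seed=23
        )
        cfg = ImputerConfig(strategy="bayesian_ridge", max_rounds=10)
        exact = loo_cv_errors(mat, cfg, mode="exact", max_cells_per_variable=5, seed=1)
        fast = loo_cv_errors(mat, cfg, mode="fast", max_cells_per_variable=5, seed=1)
        m_ex = mre_per_variable(exact)
        m_fa = mre_per_variable(fast)
        assert np.corrcoef(m_ex, m_fa)[0, 1] > 0.9


class TestMre:
    @pytest.mark.parametrize(
        "res,expected", [([0.5, 1.5], 1.0), ([0.0, 0.0], 0.0), ([0.2, 0.3, 0.7], 0.4)]
    )
    def test_mre_is_arithmetic_mean(self, res, expected):
        errors = pd.DataFrame(
            {"variable": "v", "re": res, "undefined": False}
        )
        assert mre_per_variable(errors)["v"] == pytest.approx(expected)


def single_ordinal_matrix(observed, missing_count, levels=(0, 1)):
    vals = list(observed) + [np.nan] * missing_count
    frame = pd.DataFrame({"s": vals}, index=[f"r{i}" for i in range(len(vals))])
    return ClinicalMatrix(frame, [VariableSpec("s", "ordinal", levels=levels)])


def imputed_with(matrix, fills):
    values = matrix.values.copy()
    holes = values["s"].isna()
    values.loc[holes, "s"] = fills
    return ImputedMatrix(values=values, mask=matrix.missing_mask, rounds=1, converged=True)


class TestKl:
    def test_identical_distributions_give_zero(self):
        mat = single_ordinal_matrix([0, 0, 1, 1], 4)
        imp = imputed_with(mat, [0, 0, 1, 1])
        assert kl_per_variable(mat, imp)["s"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_value(self):
        # p = (1/2, 1/2), q = (1/4, 3/4):
        # KL = 0.5 ln(2) + 0.5 ln(2/3) = 0.14384 nats
        mat = single_ordinal_matrix([0, 1], 4)
        imp = imputed_with(mat, [0, 1, 1, 1])
        kl = kl_per_variable(mat, imp, epsilon=1e-12)["s"]
        assert kl == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3), abs=1e-6)

    def test_point_mass_imputer_strictly_positive(self):
        # mean imputation collapses q to one (smoothed) bin
        rng = np.random.default_rng(30)
        mat = random_matrix(rng, n=40, p=2)
        from blockimpute import impute

        imp = impute(mat, ImputerConfig(strategy="mean"))
        kl = kl_per_variable(mat, imp)
        assert (kl.dropna() > 0).all()

    def test_no_missing_cells_is_not_applicable(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 2.0]}, index=["x", "y"])
        mat = ClinicalMatrix(frame, [VariableSpec(c, "continuous") for c in "ab"])
        imp = ImputedMatrix(
            values=frame.fillna(2.0), mask=mat.missing_mask, rounds=1, converged=True
        )
        kl = kl_per_variable(mat, imp)
        assert np.isnan(kl["a"])
        assert np.isfinite(kl["b"])

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n_obs = int(rng.integers(3, 30))
            n_miss = int(rng.integers(1, 20))
            obs = rng.integers(0, 4, n_obs)
            mat = single_ordinal_matrix(obs, n_miss, levels=(0, 1, 2, 3))
            imp = imputed_with(mat, rng.integers(0, 4, n_miss).astype(float))
            assert kl_per_variable(mat, imp)["s"] >= 0


class TestRelativePlane:
    def make_profiles(self):
        ref = pd.DataFrame(
            {"mre": [1.0, 0.5, 2.0], "kl": [0.4, 0.2, 1.0]},
            index=["v1", "v2", "v3"],
        )
        model = pd.DataFrame(
            {"mre": [0.6, 0.25, 1.0], "kl": [0.32, 0.1, 0.5]},
            index=["v1", "v2", "v3"],
        )
        return {"mean": ref, "other": model}

    def test_reference_maps_to_unit_point(self):
        rel = relative_to_reference(self.make_profiles())
        ref_pts = rel.points[rel.points.model == "mean"]
        assert np.allclose(ref_pts["rel_mre"], 1.0)
        assert np.allclose(ref_pts["rel_kl"], 1.0)
        assert np.allclose(ref_pts["norm"], np.sqrt(2))

    def test_relative_coordinates(self):
        rel = relative_to_reference(self.make_profiles())
        pt = rel.points.query("model == 'other' and variable == 'v1'").iloc[0]
        assert pt["rel_mre"] == pytest.approx(0.6)
        assert pt["rel_kl"] == pytest.approx(0.8)
        assert pt["norm"] == pytest.approx(1.0)  # 3-4-5 triangle

    def test_zero_reference_variable_excluded(self):
        profiles = self.make_profiles()
        profiles["mean"].loc["v2", "mre"] = 0.0
        rel = relative_to_reference(profiles)
        assert rel.excluded == ["v2"]
        assert "v2" not in set(rel.points["variable"])

    def test_missing_reference_is_config_error(self):
        with pytest.raises(ConfigError):
            relative_to_reference({"other": self.make_profiles()["other"]})

    @pytest.mark.parametrize(
        "point,expected", [((0.6, 0.8), 1.0), ((1, 1), np.sqrt(2)), ((0, 0), 0.0)]
    )
    def test_error_norm(self, point, expected):
        assert error_norm(*point) == pytest.approx(expected)


class TestPairedTest:
    def test_identical_norms_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_model_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_model_test([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            res = paired_model_test(a, b)
            d = a - b
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), df=n - 1)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_needs_two_observations(self):
        with pytest.raises(ConfigError):
            paired_model_test([1.0], [2.0])


class TestBenchmark:
    def test_reference_only_rejected(self):
        mat, design, _ = two_group_cohort(n_per_group=20, noise_sd=0.5, seed=40)
        with pytest.raises(ConfigError):
            run_benchmark(mat, design, {"mean": ImputerConfig(strategy="mean")})

    def test_multivariate_beats_reference_on_correlated_cohort(self):
        mat, design, _ = two_group_cohort(
            n_per_group=60, p_continuous=6, p_ordinal=2, rate=0.2,
            noise_sd=0.3, seed=41,
        )
        from blockimpute.evaluation import EvalConfig

        res = run_benchmark(
            mat,
            design,
            {
                "mean": ImputerConfig(strategy="mean"),
                "bayesian_ridge": ImputerConfig(strategy="bayesian_ridge", max_rounds=5),
            },
            config=EvalConfig(loo_mode="fast", max_cells_per_variable=6, seed=2),
        )
        pooled = res.pooled
        assert pooled.loc["bayesian_ridge", "rel_mre"] < 1
        assert pooled.loc["bayesian_ridge", "rel_kl"] < 1
        assert pooled.loc["mean", "norm"] == pytest.approx(np.sqrt(2))
        assert res.ranking[0] == "bayesian_ridge"
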
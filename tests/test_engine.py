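"""Correlation screening, enumeration, robust IRLS, and bootstrap averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aqproxy as aq
from aqproxy.core import ConfigError
from aqproxy.engine import bisquare_weight, correlation_table


class TestPearson:
    def test_perfect_correlation(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0] * 10)
        assert aq.pearson_r(x, x, min_overlap=2) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = pd.Series(np.linspace(0, 1, 30))
        y = -2 * x + 3
        assert aq.pearson_r(x, y, min_overlap=2) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # direct evaluation of the product-moment formula on 4 points
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        y = pd.Series([1.0, 2.0, 2.0, 4.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert aq.pearson_r(x, y, min_overlap=2) == pytest.approx(float(expected))
        assert expected == pytest.approx(0.9233805168766388)

    def test_undefined_cases(self):
        x = pd.Series([1.0, 2.0, 3.0])
        assert np.isnan(aq.pearson_r(x, x, min_overlap=10))  # overlap too small
        assert np.isnan(aq.pearson_r(x, pd.Series([5.0, 5.0, 5.0]), min_overlap=2))

    def test_pairwise_complete(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        y = pd.Series([2.0, 4.0, 6.0, np.nan, 10.0])
        # only rows 0, 1, 4 are complete; exact linearity there
        assert aq.pearson_r(x, y, min_overlap=2) == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 9999),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.normal(size=50))
        y = pd.Series(rng.normal(size=50))
        r = aq.pearson_r(x, y, min_overlap=2)
        assert aq.pearson_r(y, x, min_overlap=2) == pytest.approx(r, abs=1e-12)
        assert aq.pearson_r(a * x + b, y, min_overlap=2) == pytest.approx(r, rel=1e-9)


class TestSelectFeatures:
    def make_table(self, rhos, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        idx = pd.date_range("2017-01-01", periods=n, freq="1h")
        cols = {"y": z}
        for i, rho in enumerate(rhos):
            cols[f"x{i}"] = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
        return aq.TimeTable(pd.DataFrame(cols, index=idx))

    def test_planted_correlations(self):
        t = self.make_table([0.9, 0.5, 0.02])
        feats = aq.select_features(t, "y", ["x0", "x1", "x2"], r_min=0.1)
        assert feats == ["x0", "x1"]

    def test_output_copy_ranks_first(self):
        t = self.make_table([0.5])
        t.frame["twin"] = t.frame["y"]
        feats = aq.select_features(t, "y", ["x0", "twin"], r_min=0.1)
        assert feats[0] == "twin"
        tab = correlation_table(t, "y", ["twin"])
        assert tab["twin"] == pytest.approx(1.0)

    def test_zero_survivors_fatal(self):
        t = self.make_table([0.01, 0.02])
        with pytest.raises(ConfigError, match="no candidate"):
            aq.select_features(t, "y", ["x0", "x1"], r_min=0.5)


class TestEnumerate:
    @pytest.mark.parametrize(
        "n_features,max_inputs,expected",
        [(3, 3, 7), (19, 3, 1159), (1, 3, 1), (5, 2, 15)],
    )
    def test_subset_counts(self, n_features, max_inputs, expected):
        feats = [f"v{i:02d}" for i in range(n_features)]
        models = aq.enumerate_models(feats, max_inputs)
        assert len(models) == expected
        # deterministic order: size then lexicographic, no duplicates
        assert len({m.inputs for m in models}) == expected
        sizes = [m.p for m in models]
        assert sizes == sorted(sizes)


class TestBisquare:
    def test_closed_form(self):
        c = 4.685
        assert bisquare_weight(np.array([0.0]), c)[0] == 1.0
        assert bisquare_weight(np.array([c]), c)[0] == 0.0
        assert bisquare_weight(np.array([c / 2]), c)[0] == pytest.approx(0.5625)
        assert bisquare_weight(np.array([c + 1]), c)[0] == 0.0


class TestRobustFit:
    def test_noise_free_recovery(self, linear_data):
        X, y = linear_data
        fit = aq.fit_robust_ols(X, y)
        assert fit.intercept == pytest.approx(1.5, abs=1e-8)
        assert fit.coefficients["a"] == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["b"] == pytest.approx(-0.7, abs=1e-8)
        assert np.all(fit.final_weights == 1.0)
        assert fit.converged

    def test_equals_ols_on_zero_residual_data(self, linear_data):
        X, y = linear_data
        D = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta_ols, *_ = np.linalg.lstsq(D, y.to_numpy(), rcond=None)
        fit = aq.fit_robust_ols(X, y)
        assert np.max(np.abs(fit.beta - beta_ols)) <= 1e-6

    def test_outlier_resistance_vs_ols(self):
        """Slope recovered within +-0.05 under 10% gross offsets; OLS misses by more."""
        rng = np.random.default_rng(7)
        n = 500
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(scale=0.1, size=n)
        out_idx = rng.choice(n, size=n // 10, replace=False)
        y[out_idx] += 10.0
        X = pd.DataFrame({"x": x})
        fit = aq.fit_robust_ols(X, pd.Series(y))
        D = np.column_stack([np.ones(n), x])
        beta_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert abs(fit.coefficients["x"] - 2.0) <= 0.05
        assert abs(beta_ols[1] - 2.0) > abs(fit.coefficients["x"] - 2.0)
        # outliers get exactly zero weight beyond the tuning constant
        assert (fit.final_weights[out_idx] == 0.0).all()

    def test_cross_check_against_statsmodels_rlm(self):
        """Independent robust-fitting route agrees on contaminated data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        y = -0.5 + 1.5 * x + rng.normal(scale=0.2, size=n)
        y[rng.choice(n, size=40, replace=False)] -= 8.0
        fit = aq.fit_robust_ols(pd.DataFrame({"x": x}), pd.Series(y))
        rlm = sm.RLM(
            y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(c=4.685)
        ).fit()
        assert fit.coefficients["x"] == pytest.approx(rlm.params[1], abs=0.02)
        assert fit.intercept == pytest.approx(rlm.params[0], abs=0.02)

    def test_singular_design_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError):
            aq.fit_robust_ols(X, pd.Series(x))

    def test_insufficient_rows_fatal(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ConfigError, match="insufficient"):
            aq.fit_robust_ols(X, pd.Series(np.arange(10.0)), min_n=30)

    def test_weight_support_matches_cutoff(self):
        """Weights are zero exactly where |standardized residual| > c."""
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.5, size=n)
        y[:5] += 25.0
        fit = aq.fit_robust_ols(pd.DataFrame({"x": x}), pd.Series(y))
        r = fit.residuals / (fit.scale * np.sqrt(1 - fit.leverages))
        assert np.array_equal(fit.final_weights == 0.0, np.abs(r) > 4.685)
        assert fit.final_weights.min() >= 0 and fit.final_weights.max() <= 1


class TestBootstrap:
    def make_data(self, n=400, seed=5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = pd.Series(0.3 + 1.2 * X["a"] - 0.4 * X["b"] + rng.normal(scale=0.3, size=n))
        return X, y

    def test_fraction_one_equals_single_fit(self):
        X, y = self.make_data()
        model = aq.bootstrap_fit(X, y, reps=3, fraction=1.0, seed=9)
        single = aq.fit_robust_ols(X, y)
        assert model.intercept == pytest.approx(single.intercept, abs=1e-12)
        for k in ("a", "b"):
            assert model.coefficients[k] == pytest.approx(single.coefficients[k], abs=1e-12)

    def test_same_seed_bit_identical(self):
        X, y = self.make_data()
        m1 = aq.bootstrap_fit(X, y, reps=5, fraction=0.8, seed=123)
        m2 = aq.bootstrap_fit(X, y, reps=5, fraction=0.8, seed=123)
        assert m1.to_dict() == m2.to_dict()

    def test_different_seed_differs(self):
        X, y = self.make_data()
        m1 = aq.bootstrap_fit(X, y, reps=5, fraction=0.8, seed=1)
        m2 = aq.bootstrap_fit(X, y, reps=5, fraction=0.8, seed=2)
        assert m1.coefficients != m2.coefficients

    def test_average_close_to_full_fit(self):
        """Averaged coefficients within 3 subset-SEs of the full-data fit."""
        X, y = self.make_data(n=600)
        model = aq.bootstrap_fit(X, y, reps=5, fraction=0.8, seed=0)
        full = aq.fit_robust_ols(X, y)
        for k in ("a", "b"):
            ses = [s["std_errors"][k] for s in model.subsets]
            assert abs(model.coefficients[k] - full.coefficients[k]) <= 3 * np.mean(ses)

    def test_subsets_below_min_n_rejected(self):
        X, y = self.make_data(n=30)
        model = aq.bootstrap_fit(X, y, reps=2, fraction=0.5, seed=0, min_n=30)
        assert model.rejected and model.qc.reason == "insufficient data"


class TestParameterRecovery:
    def test_confidence_interval_coverage(self):
        """95% intervals cover the generating coefficients in >=90/100 replicates."""
        from scipy import stats

        true = {"a": 1.2, "b": -0.4, "c": 0.8}
        n = 300
        hits = {k: 0 for k in true}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list(true))
            y = pd.Series(
                0.5 + sum(true[k] * X[k] for k in true) + rng.normal(scale=0.5, size=n)
            )
            fit = aq.fit_robust_ols(X, y)
            tcrit = stats.t.ppf(0.975, df=n - 3 - 1)
            for k in true:
                half = tcrit * fit.std_errors[k]
                if abs(fit.coefficients[k] - true[k]) <= half:
                    hits[k] += 1
        for k, h in hits.items():
            assert h >= 90, f"coefficient {k}: {h}/100 replicates covered"
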
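"""Censored regression (lognormal AFT), model enumeration, AICc, normality."""

import numpy as np
import pandas as pd
import pytest

from edna_biomass import (
    CensoredData,
    aicc_table,
    aicc_value,
    collinear_pairs,
    covariate_transforms,
    enumerate_models,
    fit_censored_lognormal,
    fit_censored_regression,
    model_label,
    shapiro_francia,
    vif,
)


def _censored_dataset(rng, n=80, beta=(0.5, -0.2), sigma=1.2, cens_q=0.2):
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    logc = 6.0 + beta[0] * x1 + beta[1] * x2 + sigma * rng.normal(size=n)
    c = np.exp(logc)
    lod = np.quantile(c, cens_q)
    censored = c < lod
    values = np.where(censored, lod, c)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return CensoredData(values, censored), X


class TestAFTFit:
    def test_null_model_equals_lognormal_fit(self, rng):
        data, _ = _censored_dataset(rng)
        null = fit_censored_regression(data, None)
        ln = fit_censored_lognormal(data)
        assert null.coefficients[0] == pytest.approx(ln.mu, abs=1e-6)
        assert null.scale == pytest.approx(ln.sigma, abs=1e-6)
        assert null.loglik == pytest.approx(ln.loglik, abs=1e-6)
        assert null.n_parameters == 2

    def test_uncensored_equals_least_squares_on_logs(self, rng):
        data, X = _censored_dataset(rng, cens_q=0.0)
        fit = fit_censored_regression(data, X)
        A = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta_ols, *_ = np.linalg.lstsq(A, np.log(data.value), rcond=None)
        np.testing.assert_allclose(fit.coefficients, beta_ols, atol=1e-6)

    def test_matches_lifelines_oracle(self, rng):
        """Independent MLE route: lifelines' lognormal AFT, left censoring."""
        lifelines = pytest.importorskip("lifelines")
        data, X = _censored_dataset(rng)
        fit = fit_censored_regression(data, X)
        df = X.assign(y=data.value, obs=(~data.censored).astype(int))
        aft = lifelines.LogNormalAFTFitter()
        aft.fit_left_censoring(df, "y", event_col="obs")
        params = aft.params_["mu_"]
        assert fit.coef_dict()["intercept"] == pytest.approx(
            params["Intercept"], abs=1e-4
        )
        assert fit.coef_dict()["x1"] == pytest.approx(params["x1"], abs=1e-4)
        assert fit.coef_dict()["x2"] == pytest.approx(params["x2"], abs=1e-4)
        assert fit.loglik == pytest.approx(aft.log_likelihood_, abs=1e-4)

    def test_recovers_known_effects(self):
        """β̂ averaged over replicates sits within 3 MC standard errors."""
        rng = np.random.default_rng(7)
        est = []
        for _ in range(20):
            data, X = _censored_dataset(rng, n=200)
            fit = fit_censored_regression(data, X)
            est.append([fit.coef_dict()["x1"], fit.coef_dict()["x2"]])
        est = np.asarray(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert abs(est[:, 0].mean() - 0.5) < 3 * se[0]
        assert abs(est[:, 1].mean() - (-0.2)) < 3 * se[1]

    def test_rank_deficiency_names_columns(self, rng):
        data, X = _censored_dataset(rng)
        X = X.assign(x3=2.0 * X["x1"])
        with pytest.raises(ValueError, match="collinear"):
            fit_censored_regression(data, X)

    def test_missing_rows_dropped_with_warning(self, rng):
        data, X = _censored_dataset(rng)
        X = X.copy()
        X.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="missing covariates"):
            fit = fit_censored_regression(data, X)
        assert fit.n == data.n - 1

    def test_loglik_never_decreases_with_added_covariate(self, rng):
        data, X = _censored_dataset(rng)
        small = fit_censored_regression(data, X[["x1"]])
        big = fit_censored_regression(data, X)
        assert big.loglik >= small.loglik - 1e-6


class TestTransforms:
    @pytest.mark.parametrize(
        "transform, x, expected",
        [("cube_root", 27.0, 3.0), ("log", np.e, 1.0), ("identity", 5.5, 5.5)],
    )
    def test_values(self, transform, x, expected):
        assert covariate_transforms([x], transform)[0] == pytest.approx(expected)

    def test_log_of_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            covariate_transforms([1.0, 0.0], "log")

    def test_identity_transform_leaves_aicc_unchanged(self, rng):
        data, X = _censored_dataset(rng)
        plain = fit_censored_regression(data, X)
        tagged = fit_censored_regression(
            data, X, transforms={"x1": "identity", "x2": "identity"}
        )
        assert plain.aicc == pytest.approx(tagged.aicc, abs=1e-9)


class TestCollinearity:
    def test_orthogonal_covariates_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1] * 2, "b": [1, 1, -1, -1] * 2})
        v = vif(X)
        assert v["a"] == pytest.approx(1.0, abs=1e-8)
        assert v["b"] == pytest.approx(1.0, abs=1e-8)

    def test_perfect_collinearity_reported_infinite(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="perfectly collinear"):
            v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_correlated_pair_excluded_from_joint_models(self, rng):
        """r = 0.95 → VIF ≈ 10.3 > 5, so the pair is forbidden."""
        n = 10000
        z = rng.normal(size=n)
        tsm = z + rng.normal(scale=np.sqrt(1 / 0.95**2 - 1), size=n)
        X = pd.DataFrame({"tsm": tsm, "chl_a": z, "depth": rng.normal(size=n)})
        v = vif(X)
        assert v["tsm"] > 5 and v["chl_a"] > 5
        pairs = collinear_pairs(X, threshold=5.0)
        assert ("chl_a", "tsm") in [tuple(sorted(p)) for p in pairs]


class TestModelEnumeration:
    def test_two_covariates_give_four_models(self):
        models = enumerate_models(["a", "b"])
        assert sorted(model_label(m) for m in models) == ["a", "a+b", "b", "null"]

    def test_forbidden_pair_pruned(self):
        models = enumerate_models(["a", "b", "c"], forbidden_pairs=[("a", "b")])
        labels = sorted(model_label(m) for m in models)
        assert labels == ["a", "a+c", "b", "b+c", "c", "null"]

    def test_six_covariates_one_forbidden_pair(self):
        covs = ["temp", "secchi", "depth", "tds", "tsm", "chl_a"]
        models = enumerate_models(covs, forbidden_pairs=[("tsm", "chl_a")])
        assert len(models) == 48

    def test_explicit_model_list_mode(self):
        models = enumerate_models(
            ["a", "b", "c"], explicit=[[], ["b"], ["c", "a"]]
        )
        assert [model_label(m) for m in models] == ["null", "b", "a+c"]
        with pytest.raises(ValueError, match="unknown covariates"):
            enumerate_models(["a"], explicit=[["z"]])


class TestAICc:
    def test_hand_computed_value(self):
        assert aicc_value(-100.0, 3, 66) == pytest.approx(206.387, abs=5e-4)

    def test_equal_models_share_weight(self, rng):
        data, X = _censored_dataset(rng)
        fit = fit_censored_regression(data, X[["x1"]])
        table = aicc_table({"m1": fit, "m2": fit})
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])
        np.testing.assert_allclose(table["daicc"], [0.0, 0.0])

    def test_weights_sum_to_one_and_sorted(self, rng):
        data, X = _censored_dataset(rng)
        fits = {
            "null": fit_censored_regression(data, None),
            "x1": fit_censored_regression(data, X[["x1"]]),
            "x1+x2": fit_censored_regression(data, X),
        }
        table = aicc_table(fits)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["aicc"].is_monotonic_increasing

    def test_saturated_model_excluded(self, rng):
        data, X = _censored_dataset(rng, n=4, cens_q=0.0)
        fit = fit_censored_regression(data, X)  # p = 4, n = 4 -> AICc undefined
        with pytest.warns(UserWarning, match="excluded"):
            table = aicc_table({"big": fit, "null": fit_censored_regression(data, None)})
        assert list(table["model"]) == ["null"]


class TestShapiroFrancia:
    def test_blom_quantiles_give_perfect_correlation(self):
        from scipy.stats import norm

        n = 66
        x = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        w, p = shapiro_francia(x)
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_matches_r_nortest_reference(self):
        # frozen oracle values from nortest::sf.test (R 4.3.3)
        x = np.array([
            0.034193, 1.359748, 1.224721, -0.510307, -0.29797, -0.527384,
            0.569726, -0.056064, 0.746886, -1.847325, 1.566549, -0.096432,
            0.680378, -0.136566, -0.379099, 0.46311, 0.824514, -0.20253,
            -0.152786, 0.685699,
        ])
        w, p = shapiro_francia(x)
        assert w == pytest.approx(0.9380304241, abs=1e-9)
        assert p == pytest.approx(0.1907410768, abs=1e-9)
        w2, p2 = shapiro_francia(np.exp(2 * x))
        assert w2 == pytest.approx(0.6517859927, abs=1e-9)
        assert p2 == pytest.approx(3.66220e-05, rel=1e-4)

    def test_rejects_exponential_samples(self, rng):
        rejections = sum(
            shapiro_francia(rng.exponential(size=66))[1] < 0.05 for _ in range(200)
        )
        assert rejections / 200 > 0.9

    @pytest.mark.parametrize("bad", [np.ones(10), np.arange(4)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            shapiro_francia(bad)
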
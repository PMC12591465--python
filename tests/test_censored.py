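"""Censored-lognormal MLE, profile CI, outlier screen, group comparison."""

import numpy as np
import pytest

from edna_biomass import (
    CensoredData,
    compare_groups,
    detect_outliers,
    fit_censored_lognormal,
    mean_confidence_interval,
)


def grid_mle(values, censored, mu_range, sigma_range, step=1e-3):
    """Brute-force (μ, σ) maximiser of the censored-lognormal likelihood.

    Independent of the package's optimiser: evaluates the likelihood on a
    dense grid (coarse pass then refinement at the requested resolution).
    """
    from scipy.stats import norm

    logv = np.log(values)
    cens = np.asarray(censored, bool)

    def loglik(mu, sigma):
        mu = mu[:, None, None]
        sigma = sigma[None, :, None]
        z = (logv[None, None, :] - mu) / sigma
        dens = norm.logpdf(z[..., ~cens]) - np.log(sigma) - logv[~cens]
        cdf = norm.logcdf(z[..., cens])
        return dens.sum(axis=-1) + cdf.sum(axis=-1)

    lo_m, hi_m = mu_range
    lo_s, hi_s = sigma_range
    for res in (step * 20, step):
        mus = np.arange(lo_m, hi_m + res, res)
        sigmas = np.arange(max(lo_s, res), hi_s + res, res)
        ll = loglik(mus, sigmas)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        lo_m, hi_m = mus[i] - 25 * res, mus[i] + 25 * res
        lo_s, hi_s = sigmas[j] - 25 * res, sigmas[j] + 25 * res
    return mus[i], sigmas[j]


class TestLognormalMLE:
    def test_uncensored_reduces_to_closed_form(self, rng):
        x = rng.lognormal(5.0, 1.2, 50)
        fit = fit_censored_lognormal(CensoredData(x, np.zeros(50, bool)))
        mu, sigma = np.mean(np.log(x)), np.std(np.log(x))
        assert fit.mu == pytest.approx(mu, abs=1e-6)
        assert fit.sigma == pytest.approx(sigma, abs=1e-6)
        # natural-scale identities
        assert fit.median == pytest.approx(np.exp(fit.mu), rel=1e-12)
        assert fit.mean == pytest.approx(np.exp(fit.mu + fit.sigma**2 / 2), rel=1e-12)
        assert fit.sd == pytest.approx(
            fit.mean * np.sqrt(np.expm1(fit.sigma**2)), rel=1e-12
        )

    def test_matches_grid_oracle_under_censoring(self, rng):
        x = rng.lognormal(6.0, 1.5, 10)
        censored = x < np.median(x)  # half censored at a common limit
        values = np.where(censored, 220.0, x)
        fit = fit_censored_lognormal(CensoredData(values, censored))
        mu_g, sigma_g = grid_mle(values, censored, (3.0, 9.0), (0.3, 4.0))
        assert fit.mu == pytest.approx(mu_g, abs=1e-2)
        assert fit.sigma == pytest.approx(sigma_g, abs=1e-2)

    def test_scale_equivariance(self, rng):
        """Multiplying all data by e^c shifts μ̂ by c, leaves σ̂ unchanged."""
        x = rng.lognormal(6.0, 1.5, 60)
        censored = x < 300
        values = np.where(censored, 300.0, x)
        base = fit_censored_lognormal(CensoredData(values, censored))
        shifted = fit_censored_lognormal(CensoredData(values * np.e, censored))
        assert shifted.mu == pytest.approx(base.mu + 1.0, abs=1e-5)
        assert shifted.sigma == pytest.approx(base.sigma, abs=1e-5)

    def test_censoring_consistency(self, rng):
        """Uncensoring an observation at its limit changes ℓ finitely."""
        x = rng.lognormal(6.0, 1.5, 40)
        censored = x < 250
        values = np.where(censored, 250.0, x)
        fit_c = fit_censored_lognormal(CensoredData(values, censored))
        censored2 = censored.copy()
        censored2[np.argmax(censored2)] = False
        fit_u = fit_censored_lognormal(CensoredData(values, censored2))
        assert np.isfinite(fit_u.loglik) and np.isfinite(fit_c.loglik)
        assert fit_u.converged and fit_c.converged

    @pytest.mark.parametrize(
        "values, censored, message",
        [
            ([220.0] * 5, [True] * 5, "all observations are censored"),
            ([100.0, 200.0], [False, False], "at least 3"),
            ([100.0, 100.0, 100.0], [False] * 3, "zero variance"),
        ],
    )
    def test_degenerate_inputs_rejected(self, values, censored, message):
        with pytest.raises(ValueError, match=message):
            fit_censored_lognormal(CensoredData(values, censored))

    def test_zero_concentrations_become_censored_at_lod(self):
        data = CensoredData.from_concentrations([0.0, 150.0, 500.0, 0.0], 220.0)
        assert data.n_censored == 2
        np.testing.assert_allclose(data.value, [220.0, 150.0, 500.0, 220.0])
        assert not data.censored[1]  # measured value below LOD stays uncensored


class TestMeanCI:
    def test_interval_contains_the_fitted_mean(self, rng):
        x = rng.lognormal(6.0, 1.0, 80)
        data = CensoredData(x, np.zeros(80, bool))
        fit = fit_censored_lognormal(data)
        ci = mean_confidence_interval(data, level=0.95)
        assert ci.lcl < fit.mean < ci.ucl
        assert ci.method == "profile"

    def test_nested_levels(self, rng):
        x = rng.lognormal(6.0, 1.4, 70)
        censored = x < 220
        data = CensoredData(np.where(censored, 220.0, x), censored)
        narrow = mean_confidence_interval(data, level=0.80)
        wide = mean_confidence_interval(data, level=0.95)
        assert wide.lcl < narrow.lcl < narrow.ucl < wide.ucl

    def test_bootstrap_alternative(self, rng):
        x = rng.lognormal(6.0, 1.0, 50)
        data = CensoredData(x, np.zeros(50, bool))
        ci = mean_confidence_interval(
            data, level=0.9, method="bootstrap", n_boot=200, rng=1
        )
        fit = fit_censored_lognormal(data)
        assert ci.lcl < fit.mean < ci.ucl
        assert ci.method == "bootstrap"


class TestOutlierScreen:
    FIT = None

    def _fit(self):
        # any fit object with the survey's recomputed mean/sd works here
        from edna_biomass import LognormalFit

        return LognormalFit(
            mu=0, sigma=1, mean=2092.4, median=0, sd=8509.4, loglik=0,
            n=70, n_censored=17, converged=True,
        )

    def test_survey_outlier_flagged_with_boundary(self):
        screen = detect_outliers([43433.0, 500.0], ["S1", "S2"], self._fit(), 3.0)
        assert screen["upper"] == pytest.approx(27620.6, abs=0.05)
        assert screen["flagged_site_ids"] == ["S1"]

    def test_value_at_mean_not_flagged(self):
        screen = detect_outliers([2092.4], ["S1"], self._fit(), 3.0)
        assert screen["flagged_site_ids"] == []

    def test_boundary_value_kept_strict_inequality(self):
        fit = self._fit()
        boundary = fit.mean + 3.0 * fit.sd
        screen = detect_outliers([boundary], ["S1"], fit, 3.0)
        assert screen["flagged_site_ids"] == []


class TestGroupComparison:
    def test_identical_groups_give_null_chi2(self, rng):
        x = rng.lognormal(6.0, 1.0, 30)
        data = CensoredData(np.tile(x, 2), np.zeros(60, bool))
        groups = np.repeat(["a", "b"], 30)
        test = compare_groups(data, groups)
        assert test.chi2 == pytest.approx(0.0, abs=1e-5)
        assert test.p == pytest.approx(1.0, abs=1e-4)
        assert test.df == 1

    def test_all_censored_group_warns(self, rng):
        x = rng.lognormal(6.0, 1.0, 20)
        values = np.concatenate([x, [220.0] * 5])
        censored = np.concatenate([np.zeros(20, bool), np.ones(5, bool)])
        groups = np.repeat(["a", "b"], [20, 5])
        with pytest.warns(UserWarning, match="no uncensored"):
            test = compare_groups(CensoredData(values, censored), groups)
        assert 0.0 <= test.p <= 1.0

    def test_detects_a_large_shift(self, rng):
        a = rng.lognormal(5.0, 0.5, 30)
        b = rng.lognormal(8.0, 0.5, 30)
        data = CensoredData(np.concatenate([a, b]), np.zeros(60, bool))
        test = compare_groups(data, np.repeat(["a", "b"], 30))
        assert test.p < 1e-6
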
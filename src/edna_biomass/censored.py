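"""Left-censored lognormal statistics for non-detect-laden concentration data.

Non-detect sites are known only to lie below the limit of detection (LOD), so
ordinary moments are biased; instead the site concentrations are modelled as
lognormal with detects contributing density terms and non-detects contributing
distribution-function terms to the likelihood:

    ℓ(μ, σ) = Σ_detects [log φ((ln x − μ)/σ) − ln(σ x)]
            + Σ_nondetects log Φ((ln L − μ)/σ)

The same likelihood, with μ replaced by a linear predictor x'β, gives the
accelerated-failure-time regression used for the covariate models. Everything
downstream — profile-likelihood confidence limits on the natural-scale mean,
the likelihood-ratio test between groups, AICc model ranking and the
Shapiro–Francia residual normality test — is built on this one log-likelihood.

All likelihood maximisation here is native (BFGS on (β, ln σ) with analytic
gradients); external packages are used only for ordinary linear-algebra
helpers such as the variance inflation factor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr, ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoredData:
    """Concentrations with left-censoring flags.

    ``value`` holds the measured value for detects and the censoring limit
    for non-detects; ``censored`` marks which is which.
    """

    value: np.ndarray
    censored: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))
        if self.value.shape != self.censored.shape:
            raise ValueError("value and censored must have the same shape")
        if np.any(self.value < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.value <= 0) & ~self.censored):
            raise ValueError("uncensored observations must be strictly positive")
        if np.any((self.value <= 0) & self.censored):
            raise ValueError("censoring limits must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.value.size)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @classmethod
    def from_concentrations(cls, concentrations, lod: float) -> "CensoredData":
        """Site concentrations → censored data: zeros become non-detects
        censored at the LOD; positive values below the LOD stay as measured."""
        c = np.asarray(concentrations, dtype=float)
        censored = c <= 0
        return cls(np.where(censored, float(lod), c), censored)


@dataclass(frozen=True)
class LognormalFit:
    """Censored-lognormal MLE with derived natural-scale moments."""

    mu: float
    sigma: float
    mean: float
    median: float
    sd: float
    loglik: float
    n: int
    n_censored: int
    converged: bool


@dataclass(frozen=True)
class MeanCI:
    lcl: float
    ucl: float
    level: float
    method: str


@dataclass(frozen=True)
class GroupTest:
    """Likelihood-ratio test of equal log-means across groups (common σ)."""

    chi2: float
    df: int
    p: float
    group_means_log: dict


@dataclass(frozen=True)
class CensoredRegressionFit:
    """Lognormal AFT fit: ln C = x'β + σ ε with left-censored response."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    scale: float
    loglik: float
    n: int
    n_censored: int
    n_parameters: int
    aicc: float
    residuals: np.ndarray
    converged: bool

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, (float(b) for b in self.coefficients)))


# ---------------------------------------------------------------------------
# core likelihood
# ---------------------------------------------------------------------------

def _nll_grad(params: np.ndarray, X: np.ndarray, logv: np.ndarray, cens: np.ndarray):
    """Negative log-likelihood and gradient in (β, ln σ)."""
    beta, s = params[:-1], params[-1]
    sigma = np.exp(s)
    z = (logv - X @ beta) / sigma
    nll = 0.0
    gbeta = np.zeros(beta.size)
    gs = 0.0
    unc = ~cens
    if unc.any():
        zu = z[unc]
        nll -= np.sum(-0.5 * zu**2 - _LOG_SQRT_2PI - s - logv[unc])
        gbeta -= (X[unc].T @ zu) / sigma
        gs -= np.sum(zu**2 - 1.0)
    if cens.any():
        zc = z[cens]
        lc = log_ndtr(zc)
        nll -= float(np.sum(lc))
        ratio = np.exp(-0.5 * zc**2 - _LOG_SQRT_2PI - lc)  # φ(z)/Φ(z)
        gbeta += (X[cens].T @ ratio) / sigma
        gs += np.sum(ratio * zc)
    return nll, np.append(gbeta, gs)


def _fit_aft_core(X: np.ndarray, logv: np.ndarray, cens: np.ndarray,
                  start: np.ndarray | None = None):
    """Maximise the censored-lognormal likelihood; returns (β, σ, loglik, ok)."""
    n, k = X.shape
    if not (~cens).any():
        raise ValueError("all observations are censored; the likelihood is unbounded")
    if start is None:
        # detected-only moments / least squares give the starting point
        beta0, *_ = np.linalg.lstsq(X[~cens], logv[~cens], rcond=None)
        resid = logv[~cens] - X[~cens] @ beta0
        s0 = np.log(max(np.std(resid), 1e-2))
        start = np.append(beta0, s0)
    res = optimize.minimize(
        _nll_grad, start, args=(X, logv, cens), jac=True, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success:  # one polish with Nelder-Mead from the BFGS point
        res2 = optimize.minimize(
            lambda p: _nll_grad(p, X, logv, cens)[0], res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if res2.fun <= res.fun:
            res = res2
    beta = np.atleast_1d(res.x[:-1])
    sigma = float(np.exp(res.x[-1]))
    return beta, sigma, float(-res.fun), bool(res.success or res.fun < np.inf)


def _loglik_at(mu: float, sigma: float, logv: np.ndarray, cens: np.ndarray) -> float:
    nll, _ = _nll_grad(np.array([mu, np.log(sigma)]),
                       np.ones((logv.size, 1)), logv, cens)
    return -nll


def fit_censored_lognormal(data: CensoredData) -> LognormalFit:
    """MLE of a lognormal distribution under left censoring.

    With no censored observations this reduces to the closed-form lognormal
    MLE (mean and population sd of the logs). Natural-scale summaries follow
    from the fitted (μ, σ): median = e^μ, mean = e^{μ+σ²/2},
    sd = mean·sqrt(e^{σ²} − 1).
    """
    if data.n < 3:
        raise ValueError("need at least 3 observations")
    if data.n_censored == data.n:
        raise ValueError("all observations are censored; cannot fit")
    unc_vals = data.value[~data.censored]
    if np.allclose(unc_vals, unc_vals[0], rtol=0, atol=0):
        raise ValueError(
            "degenerate data: all uncensored values are identical (zero variance)"
        )
    logv = np.log(data.value)
    X = np.ones((data.n, 1))
    beta, sigma, loglik, ok = _fit_aft_core(X, logv, data.censored)
    mu = float(beta[0])
    mean = float(np.exp(mu + sigma**2 / 2.0))
    return LognormalFit(
        mu=mu,
        sigma=sigma,
        mean=mean,
        median=float(np.exp(mu)),
        sd=float(mean * np.sqrt(np.expm1(sigma**2))),
        loglik=loglik,
        n=data.n,
        n_censored=data.n_censored,
        converged=ok,
    )


# ---------------------------------------------------------------------------
# confidence interval on the natural-scale mean
# ---------------------------------------------------------------------------

def _profile_loglik_theta(theta: float, logv, cens, s_hat: float) -> float:
    """Profile log-likelihood over σ at fixed θ = ln(natural-scale mean)."""

    def nll_s(s):
        sig = np.exp(s)
        mu = theta - sig**2 / 2.0
        return _nll_grad(np.array([mu, s]), np.ones((logv.size, 1)), logv, cens)[0]

    res = optimize.minimize_scalar(
        nll_s, bounds=(s_hat - 6.0, s_hat + 4.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return -float(res.fun)


def mean_confidence_interval(
    data: CensoredData,
    level: float = 0.95,
    method: str = "profile",
    n_boot: int = 1000,
    rng=None,
) -> MeanCI:
    """Confidence limits for the natural-scale mean e^{μ+σ²/2}.

    ``method='profile'`` (default) inverts the likelihood-ratio statistic for
    θ = ln(mean) against the χ²₁ quantile; ``method='bootstrap'`` is a
    nonparametric percentile bootstrap of the MLE mean, kept as a
    cross-check for data that stray from lognormality.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    fit = fit_censored_lognormal(data)
    if method == "bootstrap":
        rng = np.random.default_rng(rng)
        idx = np.arange(data.n)
        means = []
        while len(means) < n_boot:
            take = rng.choice(idx, size=data.n, replace=True)
            boot = CensoredData(data.value[take], data.censored[take])
            if boot.n_censored == boot.n:
                continue
            try:
                means.append(fit_censored_lognormal(boot).mean)
            except ValueError:
                continue
        lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
        return MeanCI(float(lo), float(hi), level, "bootstrap")
    if method != "profile":
        raise ValueError(f"unknown CI method '{method}'")

    logv = np.log(data.value)
    cens = data.censored
    s_hat = np.log(fit.sigma)
    theta_hat = np.log(fit.mean)
    ll_hat = fit.loglik
    crit = stats.chi2.ppf(level, df=1)

    def deviance(theta):
        return 2.0 * (ll_hat - _profile_loglik_theta(theta, logv, cens, s_hat)) - crit

    # curvature-scaled first step, then geometric bracket expansion
    step = max(0.25, fit.sigma / np.sqrt(data.n))
    bounds = []
    for direction in (-1.0, +1.0):
        a, fa = theta_hat, deviance(theta_hat)
        b = theta_hat + direction * step
        fb = deviance(b)
        width = step
        while fb < 0.0 and width < 50.0:
            a, fa = b, fb
            width *= 1.8
            b = b + direction * width
            fb = deviance(b)
        if fb < 0.0:
            raise RuntimeError(
                "profile-likelihood bound did not bracket; data may be degenerate"
            )
        lo, hi = (b, a) if direction < 0 else (a, b)
        root = optimize.brentq(deviance, lo, hi, xtol=1e-8)
        bounds.append(float(np.exp(root)))
    lcl, ucl = sorted(bounds)
    return MeanCI(lcl, ucl, level, "profile")


# ---------------------------------------------------------------------------
# outlier screen and group comparison
# ---------------------------------------------------------------------------

def detect_outliers(
    concentrations, site_ids, fit: LognormalFit, multiplier: float = 3.0
) -> dict:
    """Single-pass ±multiplier·sd screen around the fitted natural-scale mean.

    Strict inequalities: a value exactly on a boundary is kept.
    """
    c = np.asarray(concentrations, dtype=float)
    lower = fit.mean - multiplier * fit.sd
    upper = fit.mean + multiplier * fit.sd
    flagged = (c > upper) | (c < lower)
    ids = np.asarray(site_ids)
    return {
        "lower": float(lower),
        "upper": float(upper),
        "flagged_site_ids": [str(s) for s in ids[flagged]],
        "flagged_values": [float(v) for v in c[flagged]],
        "mask": flagged,
    }


def compare_groups(data: CensoredData, groups) -> GroupTest:
    """MLE likelihood-ratio test of equal log-means across groups.

    Null: one common μ and σ; alternative: a separate μ per group with a
    shared σ. χ² = 2(ℓ_full − ℓ_null) on (groups − 1) degrees of freedom.
    """
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    logv = np.log(data.value)
    for lab in labels:
        m = groups == lab
        if not (~data.censored[m]).any():
            warnings.warn(
                f"group '{lab}' has no uncensored observations; its mean is "
                "weakly identified",
                stacklevel=2,
            )
    X_full = np.column_stack([(groups == lab).astype(float) for lab in labels])
    beta, sigma, ll_full, ok_full = _fit_aft_core(X_full, logv, data.censored)
    X_null = np.ones((data.n, 1))
    _, _, ll_null, ok_null = _fit_aft_core(X_null, logv, data.censored)
    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    df = len(labels) - 1
    return GroupTest(
        chi2=float(chi2),
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        group_means_log={str(lab): float(b) for lab, b in zip(labels, beta)},
    )


# ---------------------------------------------------------------------------
# censored regression (lognormal AFT)
# ---------------------------------------------------------------------------

TRANSFORMS = {
    "identity": lambda x: x,
    "log": None,  # handled explicitly to validate positivity
    "cube_root": lambda x: np.cbrt(x),
}


def covariate_transforms(values, transform: str = "identity") -> np.ndarray:
    """Elementwise covariate transform: identity, log, or cube root."""
    x = np.asarray(values, dtype=float)
    if transform == "identity":
        return x
    if transform == "cube_root":
        return np.cbrt(x)
    if transform == "log":
        if np.any(x[np.isfinite(x)] <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(x)
    raise ValueError(f"unknown transform '{transform}'")


def transform_label(name: str, transform: str) -> str:
    if transform == "identity":
        return name
    return f"{transform}({name})"


def _check_rank(X: np.ndarray, terms) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            res = X[:, j] - others @ coef
            denom = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            if denom == 0 or np.sum(res**2) < 1e-10 * max(denom, 1.0):
                bad.append(terms[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_censored_regression(
    data: CensoredData,
    covariates: pd.DataFrame | None = None,
    transforms: dict[str, str] | None = None,
) -> CensoredRegressionFit:
    """Lognormal accelerated-failure-time regression of ln(concentration).

    Rows with any missing covariate are dropped (pass complete rows to keep
    the model set comparable). ``covariates=None`` fits the null
    (intercept-only) model, which coincides with :func:`fit_censored_lognormal`.
    Parameter count for AICc is #coefficients (incl. intercept) + 1 for σ.
    """
    transforms = transforms or {}
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((data.n, 1))
        terms = ("intercept",)
        keep = np.ones(data.n, dtype=bool)
    else:
        cols, names = [], []
        for name in covariates.columns:
            tr = transforms.get(name, "identity")
            cols.append(covariate_transforms(covariates[name].to_numpy(), tr))
            names.append(transform_label(name, tr))
        Xc = np.column_stack(cols)
        keep = np.all(np.isfinite(Xc), axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} row(s) with missing covariates",
                stacklevel=2,
            )
        X = np.column_stack([np.ones(int(keep.sum())), Xc[keep]])
        terms = ("intercept", *names)
    value, cens = data.value[keep], data.censored[keep]
    logv = np.log(value)
    _check_rank(X, terms)
    beta, sigma, loglik, ok = _fit_aft_core(X, logv, cens)
    n = int(keep.sum())
    p = len(terms) + 1  # coefficients + scale
    aicc = aicc_value(loglik, p, n)
    resid = (logv[~cens] - X[~cens] @ beta) / sigma
    return CensoredRegressionFit(
        terms=terms,
        coefficients=beta,
        scale=sigma,
        loglik=loglik,
        n=n,
        n_censored=int(cens.sum()),
        n_parameters=p,
        aicc=aicc,
        residuals=resid,
        converged=ok,
    )


# ---------------------------------------------------------------------------
# collinearity, model enumeration, AICc
# ---------------------------------------------------------------------------

def vif(covariates: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 − R²ⱼ) per covariate.

    Perfectly collinear columns are reported as ``inf`` with a warning.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = covariates.dropna()
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("not enough complete rows for VIF")
    exog = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(X.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v = float(variance_inflation_factor(exog, j + 1))
            if not np.isfinite(v) or v > 1e12:
                warnings.warn(
                    f"covariate '{name}' is perfectly collinear (VIF = inf)",
                    stacklevel=2,
                )
                v = np.inf
            out[name] = v
    return pd.Series(out, name="vif")


def collinear_pairs(
    covariates: pd.DataFrame, threshold: float = 5.0
) -> list[tuple[str, str]]:
    """Covariate pairs whose pairwise VIF 1/(1−r²) exceeds the threshold."""
    pairs = []
    cols = list(covariates.columns)
    for a, b in itertools.combinations(cols, 2):
        sub = covariates[[a, b]].dropna()
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        pair_vif = np.inf if abs(r) >= 1.0 else 1.0 / (1.0 - r**2)
        if pair_vif > threshold:
            pairs.append((a, b))
    return pairs


def enumerate_models(
    covariates: list[str],
    forbidden_pairs: list[tuple[str, str]] | None = None,
    explicit: list[list[str]] | None = None,
) -> list[tuple[str, ...]]:
    """All covariate subsets (plus the null model) avoiding forbidden pairs.

    ``explicit`` bypasses enumeration and validates/labels a stated list of
    models instead (for reproducing a published model table).
    """
    if explicit is not None:
        models = []
        for subset in explicit:
            unknown = set(subset) - set(covariates)
            if unknown:
                raise ValueError(f"unknown covariates in explicit model: {sorted(unknown)}")
            models.append(tuple(sorted(subset)))
        return models
    forbidden = {frozenset(p) for p in (forbidden_pairs or [])}
    models = [()]
    for r in range(1, len(covariates) + 1):
        for subset in itertools.combinations(sorted(covariates), r):
            if any(frozenset(p) <= set(subset) for p in forbidden):
                continue
            models.append(subset)
    return models


def model_label(subset: tuple[str, ...]) -> str:
    return "null" if not subset else "+".join(sorted(subset))


def aicc_value(loglik: float, p: int, n: int) -> float:
    """AICc = −2ℓ + 2p + 2p(p+1)/(n − p − 1)."""
    if n <= p + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


def aicc_table(fits: dict[str, CensoredRegressionFit]) -> pd.DataFrame:
    """Rank fitted models by AICc with Akaike weights.

    All fits must share the same rows (equal n); models with n ≤ p + 1 are
    excluded with a warning. Weights are exp(−ΔAICc/2) normalised to 1.
    """
    ns = {fit.n for fit in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits are not on the same rows; n values {sorted(ns)}")
    rows = []
    for label, fit in fits.items():
        if not np.isfinite(fit.aicc):
            warnings.warn(
                f"model '{label}' excluded: n <= p + 1", stacklevel=2
            )
            continue
        rows.append({"model": label, "loglik": fit.loglik, "df": fit.n_parameters,
                     "aicc": fit.aicc})
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["daicc"] = table["aicc"] - table["aicc"].min()
    rel = np.exp(-table["daicc"] / 2.0)
    table["weight"] = rel / rel.sum()
    return table[["model", "aicc", "daicc", "df", "weight", "loglik"]]


# ---------------------------------------------------------------------------
# Shapiro–Francia normality test
# ---------------------------------------------------------------------------

def shapiro_francia(residuals) -> tuple[float, float]:
    """Shapiro–Francia W′ test of normality with the Royston p-value.

    W′ is the squared correlation between the order statistics and the Blom
    normal scores Φ⁻¹((i − 3/8)/(n + 1/4)); the p-value uses Royston's
    normal approximation for ln(1 − W′), valid for 5 ≤ n ≤ 5000.
    """
    x = np.sort(np.asarray(residuals, dtype=float))
    n = x.size
    if not 5 <= n <= 5000:
        raise ValueError("Shapiro–Francia needs 5 <= n <= 5000")
    if np.allclose(x, x[0], rtol=0, atol=0):
        raise ValueError("residuals are constant; W' undefined")
    m = stats.norm.ppf((np.arange(1, n + 1) - 3.0 / 8.0) / (n + 0.25))
    w = float(np.corrcoef(x, m)[0, 1] ** 2)
    u, v = np.log(n), np.log(np.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sig = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (np.log(max(1.0 - w, 1e-300)) - mu) / sig
    return w, float(stats.norm.sf(z))
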
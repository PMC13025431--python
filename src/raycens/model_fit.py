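"""Model fitting and goodness of fit on real data.

Fits the two-parameter (threshold + scale) and one-parameter Rayleigh models
to complete or censored samples by maximum likelihood and compares them via
log-likelihood, AIC, BIC and the one-sample Kolmogorov-Smirnov statistic.
The two-parameter fit uses the interior profile optimiser, since the
boundary estimate mu-hat = y_(1) forces a zero density at the smallest
observation and is a poor description of real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .model import CensoredSample, RayleighParams, rayleigh2_cdf

__all__ = [
    "FitReport",
    "loglik",
    "aic",
    "bic",
    "ks_statistic",
    "fit_two_parameter",
    "fit_one_parameter",
    "compare_models",
]


@dataclass(frozen=True)
class FitReport:
    model: str  # "two-parameter" | "one-parameter"
    params: RayleighParams
    loglik: float
    k: int
    n: int
    aic: float
    bic: float
    ks_d: float
    ks_pvalue: float

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "mu": self.params.mu,
            "sigma": self.params.sigma,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "AIC": self.aic,
            "BIC": self.bic,
            "KS_D": self.ks_d,
            "KS_pvalue": self.ks_pvalue,
        }


def loglik(y, mu: float, sigma: float, gamma: float | None = None, d=None) -> float:
    """Rayleigh log-likelihood for complete or randomly censored data.

    With censoring indicators d and a censoring scale gamma:
    sum log(y_i - mu) - 2 w1 log sigma - 2 (n - w1) log gamma
    - (beta/2) sum (y_i - mu)^2.  Without them, the complete-data form (all
    units failed, no gamma terms).  Returns -inf when mu >= min(y).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if mu >= y.min():
        return -np.inf
    z = y - mu
    ss = float(np.sum(z**2))
    if d is None:
        return float(np.sum(np.log(z))) - 2.0 * n * np.log(sigma) - ss / (2.0 * sigma**2)
    d = np.asarray(d)
    w1 = int(d.sum())
    if gamma is None:
        raise ValueError("censored log-likelihood needs a censoring scale gamma")
    beta = 1.0 / sigma**2 + 1.0 / gamma**2
    return (
        float(np.sum(np.log(z)))
        - 2.0 * w1 * np.log(sigma)
        - 2.0 * (n - w1) * np.log(gamma)
        - beta / 2.0 * ss
    )


def aic(loglik_value: float, k: int) -> float:
    """Akaike information criterion 2k - 2 logL."""
    return 2.0 * k - 2.0 * loglik_value


def bic(loglik_value: float, k: int, n: int) -> float:
    """Bayesian information criterion k log(n) - 2 logL."""
    return k * np.log(n) - 2.0 * loglik_value


def ks_statistic(data, cdf) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against a fully specified CDF.

    D = max_i max(i/n - F(y_(i)), F(y_(i)) - (i-1)/n); the p-value uses the
    asymptotic Kolmogorov distribution of sqrt(n) D.
    """
    y = np.sort(np.asarray(data, dtype=float))
    n = y.size
    f = np.asarray(cdf(y), dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("CDF produced non-finite values")
    i = np.arange(1, n + 1, dtype=float)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1.0) / n)
    d = max(d_plus, d_minus)
    pvalue = float(special.kolmogorov(np.sqrt(n) * d))
    return float(d), pvalue


def _profile_complete(mu: float, y: np.ndarray) -> float:
    """Complete-data log-likelihood with sigma^2 = sum (y-mu)^2 / (2n) profiled."""
    if mu >= y.min() or mu < 0.0:
        return -np.inf
    n = y.size
    ss = float(np.sum((y - mu) ** 2))
    return float(np.sum(np.log(y - mu))) - n * np.log(ss / (2.0 * n)) - n


def fit_two_parameter(y, grid_size: int = 2048) -> FitReport:
    """Interior ML fit of Rayleigh(mu, sigma) to complete data."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need n >= 3")
    y1 = y.min()
    grid = np.linspace(0.0, y1 * (1.0 - 1e-10), grid_size)
    vals = np.array([_profile_complete(m, y) for m in grid])
    k = int(np.argmax(vals))
    res = optimize.minimize_scalar(
        lambda m: -_profile_complete(m, y),
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, grid_size - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    mu_hat = float(res.x) if -res.fun >= vals[k] else float(grid[k])
    sigma_hat = float(np.sqrt(np.sum((y - mu_hat) ** 2) / (2.0 * y.size)))
    params = RayleighParams(mu_hat, sigma_hat)
    ll = loglik(y, mu_hat, sigma_hat)
    d, p = ks_statistic(y, lambda x: rayleigh2_cdf(x, params))
    return FitReport(
        model="two-parameter",
        params=params,
        loglik=ll,
        k=2,
        n=y.size,
        aic=aic(ll, 2),
        bic=bic(ll, 2, y.size),
        ks_d=d,
        ks_pvalue=p,
    )


def fit_one_parameter(y) -> FitReport:
    """Closed-form ML fit of the scale-only Rayleigh: sigma^2 = sum y^2 / (2n)."""
    y = np.asarray(y, dtype=float)
    sigma_hat = float(np.sqrt(np.sum(y**2) / (2.0 * y.size)))
    params = RayleighParams(0.0, sigma_hat)
    ll = loglik(y, 0.0, sigma_hat)
    d, p = ks_statistic(y, lambda x: rayleigh2_cdf(x, params))
    return FitReport(
        model="one-parameter",
        params=params,
        loglik=ll,
        k=1,
        n=y.size,
        aic=aic(ll, 1),
        bic=bic(ll, 1, y.size),
        ks_d=d,
        ks_pvalue=p,
    )


def compare_models(y) -> dict:
    """Fit both Rayleigh variants and return reports plus ECDF-vs-fitted curves."""
    y = np.sort(np.asarray(y, dtype=float))
    two = fit_two_parameter(y)
    one = fit_one_parameter(y)
    n = y.size
    ecdf = np.arange(1, n + 1, dtype=float) / n
    return {
        "two_parameter": two,
        "one_parameter": one,
        "curves": {
            "y": y,
            "ecdf": ecdf,
            "cdf_two": np.asarray(rayleigh2_cdf(y, two.params)),
            "cdf_one": np.asarray(rayleigh2_cdf(y, one.params)),
        },
    }
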
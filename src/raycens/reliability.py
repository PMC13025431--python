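"""Reliability characteristics: MTSF, hazard, reliability, ETT/OBTT.

For a Rayleigh(mu, sigma) failure law the mean time to system failure is
MTSF = mu + sigma sqrt(pi/2), the hazard is linear, h(s) = (s - mu)/sigma^2,
and the reliability is R(s) = exp(-(s - mu)^2 / (2 sigma^2)).  The expected
time on test for n units under random censoring is the mean of the largest
observed time, ETT = mu + int_0^inf [1 - (1 - e^{-beta t^2/2})^n] dt,
evaluated by adaptive quadrature.  Classical plug-in and GELF Bayesian
estimators of all functionals are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .bayes import GELFSpec, PosteriorDraws, gelf_estimate
from .classical import EstimationResult
from .model import CensoredSample, CensoringModel, RayleighParams

__all__ = [
    "ReliabilitySummary",
    "mtsf",
    "hazard",
    "reliability_fn",
    "ett",
    "ett_complete",
    "default_mission_time",
    "reliability_plugin",
    "reliability_bayes",
]


@dataclass(frozen=True)
class ReliabilitySummary:
    method: str
    s: float
    mtsf: float
    hazard: float
    reliability: float
    p: float
    ett: float
    obtt: float | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "mission_time": self.s,
            "MTSF": self.mtsf,
            "hazard": self.hazard,
            "reliability": self.reliability,
            "p": self.p,
            "ETT": self.ett,
            "OBTT": self.obtt,
        }


def mtsf(params: RayleighParams) -> float:
    """Mean time to system failure, mu + sigma sqrt(pi/2)."""
    return params.mu + params.sigma * np.sqrt(np.pi / 2.0)


def hazard(s: float, params: RayleighParams) -> float:
    """Hazard rate (s - mu)/sigma^2; linear and increasing in s."""
    if s <= params.mu:
        raise ValueError("hazard defined for mission times s > mu")
    return (s - params.mu) / params.sigma**2


def reliability_fn(s: float, params: RayleighParams) -> float:
    """Survival probability exp(-(s - mu)^2 / (2 sigma^2)); 1 at s <= mu."""
    if s <= params.mu:
        return 1.0
    return float(np.exp(-((s - params.mu) ** 2) / (2.0 * params.sigma**2)))


def _ett_integral(beta: float, n: int, upper: float) -> float:
    def integrand(t):
        return -np.expm1(n * np.log(-np.expm1(-beta * t * t / 2.0))) if t > 0 else 1.0

    # the maximum lives on the scale beta^{-1/2} sqrt(2 log n); breakpoints
    # keep the adaptive rule from overlooking that region when upper >> scale
    t_eff = beta**-0.5 * (3.0 + np.sqrt(2.0 * np.log(max(n, 2))))
    points = [p for p in (t_eff / 2.0, t_eff, 2.0 * t_eff) if p < upper]
    val, err = integrate.quad(integrand, 0.0, upper, epsrel=1e-6, limit=1000, points=points or None)
    if not np.isfinite(val):
        raise RuntimeError(f"ETT quadrature failed (value {val}, error {err})")
    return val


def ett(model: CensoringModel, n: int) -> float:
    """Expected time on test E[Y_(n)] for n units under random censoring.

    mu + int_0^U [1 - (1 - e^{-beta t^2/2})^n] dt with the upper limit
    U = mu + 10 max(sigma, gamma), which covers the support of the maximum;
    adaptive quadrature at relative tolerance 1e-6.  Nondecreasing in n and
    equal to the marginal mean for n = 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    upper = model.mu + 10.0 * max(model.sigma, model.gamma)
    return model.mu + _ett_integral(model.beta, n, upper)


def ett_complete(params: RayleighParams, n: int) -> float:
    """Expected time on test without censoring: E[X_(n)] for the failure law."""
    if n < 1:
        raise ValueError("n must be >= 1")
    upper = params.mu + 10.0 * params.sigma
    return params.mu + _ett_integral(1.0 / params.sigma**2, n, upper)


def default_mission_time(params: RayleighParams) -> float:
    """Default mission time s = mu + MTSF/2."""
    return params.mu + mtsf(params) / 2.0


def reliability_plugin(
    result: EstimationResult,
    sample: CensoredSample,
    s: float | None = None,
) -> ReliabilitySummary:
    """Plug the classical estimates into every reliability functional."""
    params = RayleighParams(result.mu, result.sigma)
    if s is None:
        s = default_mission_time(params)
    model = CensoringModel(result.mu, result.sigma, result.gamma)
    return ReliabilitySummary(
        method="plug-in",
        s=s,
        mtsf=mtsf(params),
        hazard=hazard(s, params),
        reliability=reliability_fn(s, params),
        p=model.p,
        ett=ett(model, sample.n),
        obtt=sample.y_max,
    )


def reliability_bayes(
    draws: PosteriorDraws,
    spec: GELFSpec,
    s: float,
    n: int,
    sample: CensoredSample | None = None,
    ett_draw_cap: int = 400,
) -> ReliabilitySummary:
    """GELF Bayes estimates of the reliability functionals.

    Each functional g is evaluated per posterior draw and the GELF transform
    (mean g^{-delta})^{-1/delta} applied.  ETT needs one quadrature per draw,
    so it is evaluated on an evenly thinned subset of at most ``ett_draw_cap``
    draws.
    """
    mu = draws.posterior("mu")
    sig = draws.posterior_scale("sigma")
    gam = draws.posterior_scale("gamma")
    delta = spec.delta

    mtsf_d = mu + sig * np.sqrt(np.pi / 2.0)
    haz_d = (s - mu) / sig**2
    if np.any(haz_d <= 0.0):
        raise ValueError("mission time not above every posterior mu draw")
    rel_d = np.exp(-((s - mu) ** 2) / (2.0 * sig**2))
    p_d = gam**2 / (sig**2 + gam**2)

    step = max(1, mu.size // ett_draw_cap)
    idx = np.arange(0, mu.size, step)
    ett_d = np.array(
        [
            ett(CensoringModel(mu[i], sig[i], gam[i]), n)
            for i in idx
        ]
    )
    return ReliabilitySummary(
        method="bayes-GELF",
        s=s,
        mtsf=gelf_estimate(mtsf_d, delta),
        hazard=gelf_estimate(haz_d, delta),
        reliability=gelf_estimate(rel_d, delta),
        p=gelf_estimate(p_d, delta),
        ett=gelf_estimate(ett_d, delta),
        obtt=sample.y_max if sample is not None else None,
    )
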
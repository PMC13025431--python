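"""Two-parameter Rayleigh distribution and the random-censoring data model.

The lifetime law is Rayleigh(mu, sigma) with density

    f(x | mu, sigma) = ((x - mu) / sigma^2) * exp(-(x - mu)^2 / (2 sigma^2)),
    x >= mu >= 0, sigma > 0,

i.e. a standard Rayleigh shifted by a threshold (minimum-lifetime) parameter
mu.  Under random censoring each unit's failure time X ~ Rayleigh(mu, sigma)
may be pre-empted by an independent censoring time T ~ Rayleigh(mu, gamma)
sharing the same threshold; only Y = min(X, T) and D = 1{X <= T} are observed.
Writing beta = 1/sigma^2 + 1/gamma^2, the observed time Y is again Rayleigh
with location mu and scale beta^{-1/2}, D is Bernoulli(p) with
p = gamma^2 / (sigma^2 + gamma^2), and Y and D are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RayleighParams",
    "CensoringModel",
    "CensoredSample",
    "rayleigh2_pdf",
    "rayleigh2_cdf",
    "rayleigh2_quantile",
    "censoring_prob",
    "joint_density",
    "marginal_y",
    "min_statistic_law",
    "sample_censored",
    "read_censored",
    "write_censored",
]


@dataclass(frozen=True)
class RayleighParams:
    """Location mu >= 0 (time units) and scale sigma > 0 of a shifted Rayleigh."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.mu >= 0.0):
            raise ValueError(f"location mu must be >= 0, got {self.mu}")
        if not (self.sigma > 0.0):
            raise ValueError(f"scale sigma must be > 0, got {self.sigma}")

    def frozen(self):
        """The scipy frozen distribution (loc=mu, scale=sigma)."""
        return stats.rayleigh(loc=self.mu, scale=self.sigma)

    @property
    def mean(self) -> float:
        return self.mu + self.sigma * np.sqrt(np.pi / 2.0)

    @property
    def var(self) -> float:
        return (4.0 - np.pi) / 2.0 * self.sigma**2


@dataclass(frozen=True)
class CensoringModel:
    """Generative law of one randomly censored unit.

    Failure time X ~ Rayleigh(mu, sigma) and censoring time T ~ Rayleigh(mu,
    gamma), independent, sharing the threshold mu.
    """

    mu: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.mu >= 0.0):
            raise ValueError(f"location mu must be >= 0, got {self.mu}")
        if not (self.sigma > 0.0 and self.gamma > 0.0):
            raise ValueError("scales sigma, gamma must be > 0")

    @property
    def beta(self) -> float:
        """Composite precision 1/sigma^2 + 1/gamma^2 of the observed time."""
        return 1.0 / self.sigma**2 + 1.0 / self.gamma**2

    @property
    def p(self) -> float:
        """P(X <= T): probability that a unit fails before being censored."""
        return self.gamma**2 / (self.sigma**2 + self.gamma**2)

    @property
    def failure_law(self) -> RayleighParams:
        return RayleighParams(self.mu, self.sigma)

    @property
    def censoring_law(self) -> RayleighParams:
        return RayleighParams(self.mu, self.gamma)


@dataclass
class CensoredSample:
    """A randomly censored sample: times y_i > 0 and indicators d_i in {0,1}."""

    y: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.d = np.asarray(self.d)
        if self.y.ndim != 1 or self.d.shape != self.y.shape:
            raise ValueError("y and d must be 1-d sequences of equal length")
        if self.y.size < 1:
            raise ValueError("need at least one observation")
        if np.any(self.y <= 0.0):
            raise ValueError("all observed times must be positive")
        if not np.all(np.isin(self.d, (0, 1))):
            raise ValueError("indicators must be 0 (censored) or 1 (failure)")
        self.d = self.d.astype(int)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def y_min(self) -> float:
        """Smallest observation y_(1); the boundary MLE of mu."""
        return float(self.y.min())

    @property
    def y_max(self) -> float:
        """Largest observation y_(n); the observed time on test (OBTT)."""
        return float(self.y.max())

    @property
    def w1(self) -> int:
        """Number of observed failures, sum of d_i."""
        return int(self.d.sum())

    @property
    def y_bar(self) -> float:
        return float(self.y.mean())

    @property
    def d_bar(self) -> float:
        return float(self.d.mean())

    @property
    def s_y2(self) -> float:
        """Sample variance with 1/n normalisation."""
        return float(np.mean((self.y - self.y_bar) ** 2))

    @property
    def w2_star(self) -> float:
        """Sum of squared deviations from the sample minimum."""
        return float(np.sum((self.y - self.y_min) ** 2))

    def w2(self, mu: float) -> float:
        """Sum of squared deviations from a supplied location value."""
        return float(np.sum((self.y - mu) ** 2))


def rayleigh2_pdf(x, params: RayleighParams):
    """Density of Rayleigh(mu, sigma); zero below the threshold."""
    x = np.asarray(x, dtype=float)
    out = params.frozen().pdf(x)
    return out if out.ndim else float(out)


def rayleigh2_cdf(x, params: RayleighParams):
    x = np.asarray(x, dtype=float)
    out = params.frozen().cdf(x)
    return out if out.ndim else float(out)


def rayleigh2_quantile(q, params: RayleighParams):
    """Inverse CDF: mu + sigma * sqrt(-2 log(1 - q)) for q in [0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0.0) or np.any(q >= 1.0):
        raise ValueError("quantile level must lie in [0, 1)")
    out = params.mu + params.sigma * np.sqrt(-2.0 * np.log1p(-q))
    return out if out.ndim else float(out)


def censoring_prob(model: CensoringModel) -> float:
    """P(failure observed before censoring) = gamma^2 / (sigma^2 + gamma^2)."""
    return model.p


def joint_density(y, d, model: CensoringModel):
    """Joint density/mass of (Y, D) at (y, d).

    ((y-mu)/sigma^2)^d ((y-mu)/gamma^2)^(1-d) exp(-beta (y-mu)^2 / 2) for
    y > mu, zero otherwise.
    """
    y = np.asarray(y, dtype=float)
    d_arr = np.asarray(d)
    if not np.all(np.isin(d_arr, (0, 1))):
        raise ValueError("indicator d must be 0 or 1")
    z = y - model.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(
            z > 0.0,
            (z / model.sigma**2) ** d_arr
            * (z / model.gamma**2) ** (1 - d_arr)
            * np.exp(-model.beta * z**2 / 2.0),
            0.0,
        )
    return dens if dens.ndim else float(dens)


def marginal_y(model: CensoringModel) -> RayleighParams:
    """Law of the observed time Y = min(X, T): Rayleigh(mu, beta^{-1/2})."""
    return RayleighParams(model.mu, model.beta ** -0.5)


def min_statistic_law(params: RayleighParams, n: int) -> RayleighParams:
    """Law of the minimum of n iid Rayleigh(mu, sigma) draws.

    The minimum is again Rayleigh with the same threshold and the squared
    scale divided by n, so its mean is mu + sigma * sqrt(pi / (2 n)) and its
    variance (4 - pi) sigma^2 / (2 n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return RayleighParams(params.mu, params.sigma / np.sqrt(n))


def sample_censored(model: CensoringModel, n: int, seed=None) -> CensoredSample:
    """Draw a randomly censored sample of size n.

    Failure and censoring times are generated by inverse transform
    (X = mu + sigma*sqrt(-2 log(1-U))) so that samples produced under two
    models differing only in mu are exact translates of one another when the
    same seed is used.  Ties X = T (measure zero) count as failures.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u1 = rng.random(n)
    u2 = rng.random(n)
    x = model.mu + model.sigma * np.sqrt(-2.0 * np.log1p(-u1))
    t = model.mu + model.gamma * np.sqrt(-2.0 * np.log1p(-u2))
    y = np.minimum(x, t)
    d = (x <= t).astype(int)
    return CensoredSample(y=y, d=d)


def read_censored(path, delimiter=None) -> CensoredSample:
    """Read a two-column (time, status) delimited text file.

    Status must be 0 or 1.  A single header line is skipped if its first
    field is not numeric.  Malformed lines raise with their line number.
    """
    y, d = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(delimiter) if delimiter else line.replace(",", " ").split()
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                yi = float(parts[0])
                di = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if yi <= 0:
                raise ValueError(f"{path}:{lineno}: time must be positive, got {yi}")
            if di not in (0, 1):
                raise ValueError(f"{path}:{lineno}: status must be 0 or 1, got {di}")
            y.append(yi)
            d.append(di)
    return CensoredSample(y=np.array(y), d=np.array(d))


def write_censored(sample: CensoredSample, path) -> None:
    with open(path, "w") as fh:
        fh.write("time,status\n")
        for yi, di in zip(sample.y, sample.d):
            fh.write(f"{yi:.10g},{di}\n")
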
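"""Positive-valued sampling laws used by the synthetic midgut generator.

Clone areas, nuclear cross-section areas and per-fly luciferase activities are
all strictly positive and right-skewed, so every law here is built on the
lognormal.  The generator needs two things that plain ``scipy.stats.lognorm``
does not hand over directly for a doubly-truncated variable: exact analytic
means (used to calibrate expected total clone coverage at the parameter
level) and cheap inverse-CDF sampling under truncation.  Both follow from
standard normal CDFs, so they are implemented here as thin closed-form
wrappers over :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LogNormalLaw",
    "TruncatedLogNormal",
    "CountLaw",
    "PoissonCount",
    "BinomialCount",
    "FixedCount",
]


@dataclass(frozen=True)
class LogNormalLaw:
    """Lognormal parameterised by its median and log-space sigma.

    ``sigma = 0`` degenerates to a point mass at ``median``, which the pooled
    luciferase assay uses as its zero-dispersion sanity case.
    """

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be > 0, got {self.median}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    def mean(self) -> float:
        return float(self.median * np.exp(self.sigma**2 / 2.0))

    def var(self) -> float:
        m = self.mean()
        return float(m * m * (np.exp(self.sigma**2) - 1.0))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full(size, self.median, dtype=float)
        return rng.lognormal(mean=self.mu, sigma=self.sigma, size=size)


@dataclass(frozen=True)
class TruncatedLogNormal:
    """Lognormal restricted to ``(lower, upper]`` with closed-form moments.

    The upper truncation encodes the hard biological maxima the presets are
    built around (e.g. nuclear cross-sections never exceeding 420 um^2 in
    control clones).  Sampling is by inverse-CDF restricted to the truncation
    window, so no rejection loop is needed.
    """

    median: float
    sigma: float
    upper: float
    lower: float = 0.0

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")
        if not (0.0 <= self.lower < self.upper):
            raise ValueError(
                f"need 0 <= lower < upper, got lower={self.lower}, upper={self.upper}"
            )

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    def _z(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return (np.log(x) - self.mu) / self.sigma

    def mean(self) -> float:
        # Partial expectation of a lognormal over (lower, upper]:
        #   E[X | a < X <= b] = exp(mu + s^2/2)
        #       * (Phi(z_b - s) - Phi(z_a - s)) / (Phi(z_b) - Phi(z_a))
        z_lo, z_hi = self._z(self.lower), self._z(self.upper)
        denom = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
        num = stats.norm.cdf(z_hi - self.sigma) - stats.norm.cdf(z_lo - self.sigma)
        return float(np.exp(self.mu + self.sigma**2 / 2.0) * num / denom)

    def second_moment(self) -> float:
        z_lo, z_hi = self._z(self.lower), self._z(self.upper)
        denom = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
        num = stats.norm.cdf(z_hi - 2 * self.sigma) - stats.norm.cdf(z_lo - 2 * self.sigma)
        return float(np.exp(2 * self.mu + 2 * self.sigma**2) * num / denom)

    def var(self) -> float:
        m = self.mean()
        return self.second_moment() - m * m

    def tail_mass_above(self, x: float) -> float:
        """P(X > x) under the truncated law (0 if x >= upper)."""
        if x >= self.upper:
            return 0.0
        z_lo, z_hi = self._z(self.lower), self._z(self.upper)
        denom = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
        return float((stats.norm.cdf(z_hi) - stats.norm.cdf(self._z(x))) / denom)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        z_lo, z_hi = self._z(self.lower), self._z(self.upper)
        p_lo, p_hi = stats.norm.cdf(z_lo), stats.norm.cdf(z_hi)
        u = rng.uniform(p_lo, p_hi, size=size)
        return np.exp(self.mu + self.sigma * stats.norm.ppf(u))


class CountLaw:
    """Integer-count law interface (clones per gut, nuclei per clone)."""

    def mean(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator) -> int:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class PoissonCount(CountLaw):
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    def mean(self) -> float:
        return float(self.rate)

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.poisson(self.rate))


@dataclass(frozen=True)
class BinomialCount(CountLaw):
    n: int
    p: float

    def __post_init__(self) -> None:
        if self.n < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError("need n >= 0 and 0 <= p <= 1")

    def mean(self) -> float:
        return float(self.n * self.p)

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.binomial(self.n, self.p))


@dataclass(frozen=True)
class FixedCount(CountLaw):
    value: int

    def mean(self) -> float:
        return float(self.value)

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.value)
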
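"""Sampling distributions used by the exposure simulation.

Concentrations and body weights are modelled as lognormal; daily water
intake as uniform (triangular available as an alternative shape).  Each
spec is a small frozen dataclass with analytic moments, exact quantiles
and a ``sample`` method driven by a ``numpy.random.Generator``, so the
Monte Carlo engine stays deterministic under a fixed seed.

Two constructors cover the two ways parameters arrive in practice:

* ``lognormal_from_mean_sd`` — moment matching, for contaminants known
  only through a summary table (arithmetic mean and SD);
* ``lognormal_from_median_p95`` — for body weights quoted as a median
  plus a 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .censoring import CensorPolicy, substitute

__all__ = [
    "LognormalSpec",
    "UniformSpec",
    "TriangularSpec",
    "DistributionSpec",
    "lognormal_from_mean_sd",
    "lognormal_from_median_p95",
    "fit_lognormal",
    "quantile",
    "spec_from_dict",
]

#: standard-normal 95th percentile, used to convert a (median, P95) pair
#: into a log-scale sigma
Z_95 = float(stats.norm.ppf(0.95))


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution: ``ln X ~ Normal(mu, sigma)``.

    ``sigma = 0`` is admitted as an explicit point mass at ``exp(mu)``
    (a degenerate spec), which arises for constant inputs such as a
    single-well point-source concentration.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    @property
    def sd(self) -> float:
        return float(self.mean * np.sqrt(np.expm1(self.sigma**2)))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def quantile(self, p: float) -> float:
        _check_prob(p)
        if self.degenerate:
            return self.median
        return float(np.exp(self.mu + stats.norm.ppf(p) * self.sigma))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate:
            return np.full(n, self.median)
        return rng.lognormal(self.mu, self.sigma, size=n)

    def scaled(self, k: float) -> "LognormalSpec":
        """Multiply the variable by ``k > 0`` (e.g. a unit conversion)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return LognormalSpec(self.mu + float(np.log(k)), self.sigma)

    def to_dict(self) -> dict:
        return {"type": "lognormal", "mu": self.mu, "sigma": self.sigma}


@dataclass(frozen=True)
class UniformSpec:
    """Uniform distribution on ``[low, high]`` (e.g. daily intake in L)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("require 0 < low < high")

    @property
    def mean(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def median(self) -> float:
        return self.mean

    @property
    def sd(self) -> float:
        return (self.high - self.low) / np.sqrt(12.0)

    def quantile(self, p: float) -> float:
        _check_prob(p)
        return self.low + p * (self.high - self.low)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)

    def to_dict(self) -> dict:
        return {"type": "uniform", "low": self.low, "high": self.high}


@dataclass(frozen=True)
class TriangularSpec:
    """Triangular distribution on ``[low, high]`` with mode ``mode``.

    Offered as an alternative intake shape when a most-likely
    consumption volume is defensible; the default analysis uses
    ``UniformSpec`` (minimal assumption over a quoted range).
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.mode <= self.high) or self.low == self.high:
            raise ValueError("require 0 < low <= mode <= high with low < high")

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def quantile(self, p: float) -> float:
        _check_prob(p)
        a, c, b = self.low, self.mode, self.high
        fc = (c - a) / (b - a)
        if p < fc:
            return a + np.sqrt(p * (b - a) * (c - a))
        return b - np.sqrt((1 - p) * (b - a) * (b - c))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.triangular(self.low, self.mode, self.high, size=n)

    def to_dict(self) -> dict:
        return {
            "type": "triangular",
            "low": self.low,
            "mode": self.mode,
            "high": self.high,
        }


DistributionSpec = Union[LognormalSpec, UniformSpec, TriangularSpec]


def lognormal_from_mean_sd(mean: float, sd: float) -> LognormalSpec:
    """Lognormal spec whose analytic mean and SD equal the inputs.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.
    ``sd = 0`` yields the degenerate point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        return LognormalSpec(float(np.log(mean)), 0.0)
    sigma2 = float(np.log1p((sd / mean) ** 2))
    mu = float(np.log(mean)) - sigma2 / 2.0
    return LognormalSpec(mu, float(np.sqrt(sigma2)))


def lognormal_from_median_p95(median: float, p95: float) -> LognormalSpec:
    """Lognormal spec with the given median and 95th percentile.

    mu = ln(median), sigma = ln(p95/median) / z_0.95.
    """
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if p95 <= median:
        raise ValueError(
            f"p95 ({p95}) must exceed the median ({median}); "
            "a zero-spread lognormal is not identifiable from these quantiles"
        )
    mu = float(np.log(median))
    sigma = float(np.log(p95 / median)) / Z_95
    return LognormalSpec(mu, sigma)


def fit_lognormal(
    values,
    censored=None,
    censor_policy: CensorPolicy | str = CensorPolicy.HALF_LOD,
) -> LognormalSpec:
    """Fit a lognormal to well-level data by log-space moments.

    Censored entries (carrying the detection limit) are substituted
    according to ``censor_policy`` before log-transforming.  The
    returned spec reproduces the sample log-mean and sample log-SD
    (ddof=1).  Requires at least two detected values; summary-only data
    should use :func:`lognormal_from_mean_sd` instead.
    """
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.zeros(values.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_detected = int((~censored).sum())
    if n_detected < 2:
        raise ValueError(
            "fit_lognormal needs at least 2 detected values; "
            "use lognormal_from_mean_sd / lognormal_from_median_p95 "
            "for summary-level inputs"
        )
    subs = substitute(values, censored, censor_policy)
    if np.any(subs <= 0):
        raise ValueError(
            "non-positive values after censor substitution; "
            "a lognormal cannot be fit (try a different censor policy)"
        )
    logs = np.log(subs)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=1)) if logs.size > 1 else 0.0
    return LognormalSpec(mu, sigma)


def quantile(spec: DistributionSpec, p: float) -> float:
    """Exact analytic quantile of any distribution spec."""
    return spec.quantile(p)


def spec_from_dict(d: dict) -> DistributionSpec:
    """Rebuild a distribution spec from its serialized form."""
    d = dict(d)
    kind = d.pop("type")
    if kind == "lognormal":
        return LognormalSpec(**d)
    if kind == "uniform":
        return UniformSpec(**d)
    if kind == "triangular":
        return TriangularSpec(**d)
    raise ValueError(f"unknown distribution type: {kind!r}")


def _check_prob(p: float) -> None:
    if not 0 < p < 1:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
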
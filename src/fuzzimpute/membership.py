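"""Fuzzy membership functions over a set of neighbor values.

Two membership shapes are supported.  The triangular function is the
piecewise-linear "tent" over (a, b, c) = (min, mean, max) of the neighbor
values:

    mu(x) = 0                 x <= a
            (x - a)/(b - a)   a < x <= b
            (c - x)/(c - b)   b < x < c
            0                 x >= c

so the two extreme neighbor values always receive weight 0 and the mean
receives weight 1.  The Gaussian function is the bell curve

    mu(x) = exp(-(x - mu)^2 / (2 sigma^2))

parameterized by the mean and the *population* standard deviation
(divisor n, not n - 1) of the neighbor values, so every neighbor keeps a
strictly positive weight.

Degenerate spreads (b == a, c == b, sigma == 0) arise when neighbor
values coincide; they are resolved one level up, in the imputer's
fallback chain, rather than by inventing weights here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TriangularParams",
    "GaussianParams",
    "triangular_params",
    "triangular_membership",
    "gaussian_params",
    "gaussian_membership",
    "weighted_average",
    "DegenerateWeightsError",
]


class DegenerateWeightsError(ValueError):
    """Raised when a weight set is degenerate (zero sigma or all-zero weights)."""


@dataclass(frozen=True)
class TriangularParams:
    """Triangle vertices: a = min, b = mean, c = max of the neighbor values."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"require a <= b <= c, got ({self.a}, {self.b}, {self.c})")


@dataclass(frozen=True)
class GaussianParams:
    """Bell-curve center (mu) and width (sigma, population sd >= 0)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def triangular_params(values: Sequence[float]) -> TriangularParams:
    """Fit (min, mean, max) triangle vertices to a non-empty value set."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    return TriangularParams(float(vals.min()), float(vals.mean()), float(vals.max()))


def triangular_membership(x: float, params: TriangularParams) -> float:
    """Piecewise-linear membership of ``x`` in the triangle ``params``.

    Boundary conventions: x <= a and x >= c map to 0; the rising branch is
    closed at b.  A zero-width branch (b == a or c == b) contributes 0.
    """
    a, b, c = params.a, params.b, params.c
    if x <= a or x >= c:
        return 0.0
    if x <= b:
        return (x - a) / (b - a) if b > a else 0.0
    return (c - x) / (c - b) if c > b else 0.0


def gaussian_params(values: Sequence[float]) -> GaussianParams:
    """Mean and population standard deviation of a non-empty value set."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    # ddof=0: population form, the spread of the neighbor set itself.
    return GaussianParams(float(vals.mean()), float(vals.std(ddof=0)))


def gaussian_membership(x: float, params: GaussianParams) -> float:
    """Bell-curve membership of ``x``; equals 1 iff x == mu."""
    if params.sigma == 0:
        raise DegenerateWeightsError("sigma = 0: Gaussian membership undefined")
    z = (x - params.mu) / params.sigma
    return math.exp(-0.5 * z * z)


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    """sum(values * weights) / sum(weights).

    Raises :class:`DegenerateWeightsError` when the weights sum to zero,
    signalling the caller's all-zero-weight fallback (arithmetic mean).
    """
    vals = np.asarray(values, dtype=float)
    wts = np.asarray(weights, dtype=float)
    if vals.size == 0 or vals.shape != wts.shape:
        raise ValueError("values and weights must be non-empty and of equal length")
    if (wts < 0).any():
        raise ValueError("weights must be non-negative")
    total = float(wts.sum())
    if total == 0.0:
        raise DegenerateWeightsError("all weights are zero")
    return float((vals * wts).sum() / total)
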
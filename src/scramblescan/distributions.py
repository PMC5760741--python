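"""Length/count distributions used by the synthetic germline generator.

The source data report only means and medians for the per-category feature
distributions, so the generator uses positive, right-skewed families that can
be pinned to those printed moments:

* counts: shifted geometric (support >= minimum), parameterized by the mean;
* lengths: log-normal, parameterized jointly by mean and median, which fixes
  sigma = sqrt(2 ln(mean/median)) and mu = ln(median);
* pointer lengths: a small empirical integer offset distribution anchored at
  a configurable median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class FixedLength:
    """Degenerate distribution: every draw equals ``value``."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ParameterError("FixedLength.value must be >= 1")

    @property
    def mean(self) -> float:
        return float(self.value)

    @property
    def median(self) -> float:
        return float(self.value)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value, dtype=np.int64)


@dataclass(frozen=True)
class ShiftedGeometricCount:
    """Geometric count shifted to support {minimum, minimum+1, ...}.

    X = minimum - 1 + Geom(p) with p = 1 / (mean - minimum + 1), so the
    distribution mean equals ``mean`` exactly.
    """

    mean: float
    minimum: int = 1

    def __post_init__(self) -> None:
        if self.mean <= self.minimum:
            raise ParameterError(
                "ShiftedGeometricCount.mean must exceed its minimum support"
            )

    @property
    def _p(self) -> float:
        return 1.0 / (self.mean - self.minimum + 1)

    @property
    def median(self) -> float:
        # median of Geom(p) is ceil(-1 / log2(1-p))
        g = math.ceil(math.log(0.5) / math.log(1.0 - self._p))
        return float(self.minimum - 1 + g)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.minimum - 1 + rng.geometric(self._p, size=n)


@dataclass(frozen=True)
class LogNormalLength:
    """Log-normal length pinned to a printed (mean, median) pair.

    mu = ln(median); sigma = sqrt(2 ln(mean/median)). Draws are rounded to
    integers and clamped to [minimum, maximum].
    """

    mean: float
    median: float
    minimum: int = 1
    maximum: int = 10**9

    def __post_init__(self) -> None:
        if self.median <= 0 or self.mean < self.median:
            raise ParameterError(
                "LogNormalLength requires 0 < median <= mean"
            )
        if self.minimum < 1 or self.maximum < self.minimum:
            raise ParameterError("LogNormalLength bounds are inconsistent")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.sqrt(2.0 * math.log(self.mean / self.median))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(self.mu, self.sigma, size=n)
        return np.clip(np.rint(draws).astype(np.int64), self.minimum, self.maximum)


#: offset-from-median probability mass for pointer lengths; keeps the median
#: at the anchor while giving a slight right skew (mean ~ median + 0.49),
#: emulating the reported mean/median gaps (6.55 vs 6; 8.59 vs 8).
_POINTER_OFFSETS = (
    (-2, 0.12),
    (-1, 0.18),
    (0, 0.30),
    (1, 0.16),
    (2, 0.10),
    (3, 0.06),
    (4, 0.04),
    (5, 0.03),
    (6, 0.01),
)


@dataclass(frozen=True)
class PointerLengthDist:
    """Empirical integer pointer-length distribution anchored at a median."""

    median_length: int
    offsets: tuple[tuple[int, float], ...] = field(default=_POINTER_OFFSETS)

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.offsets)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("PointerLengthDist offset weights must sum to 1")
        if self.median_length + min(o for o, _ in self.offsets) < 1:
            raise ParameterError("PointerLengthDist support must stay >= 1 bp")

    @property
    def mean(self) -> float:
        return self.median_length + sum(o * p for o, p in self.offsets)

    @property
    def median(self) -> float:
        return float(self.median_length)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        offs = np.array([o for o, _ in self.offsets])
        probs = np.array([p for _, p in self.offsets])
        draws = self.median_length + rng.choice(offs, size=n, p=probs)
        return np.maximum(draws, 1)


@dataclass(frozen=True)
class PerCategory:
    """A pair of distributions, one per locus category."""

    nonscrambled: object
    scrambled: object

    def for_category(self, scrambled: bool):
        return self.scrambled if scrambled else self.nonscrambled
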
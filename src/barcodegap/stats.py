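"""Identification success rates and Bernoulli (Wald) confidence intervals.

Each query either hits its correct species name or not, so a batch of
identifications is a Bernoulli sample.  The success rate is the exact
rational Number_hit / Number_test (rounding happens only when printing),
and its (1 - alpha) confidence interval is the normal-approximation
(Wald) interval

    p_hat +- z_{1-alpha/2} * sqrt(p_hat (1 - p_hat) / n)

clipped to [0, 1].  The Wald interval is the conventional choice for
reporting barcode identification rates; note its well-known
under-coverage near p -> 1, which the test suite asserts against rather
than hides.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import norm

__all__ = [
    "IdentificationResult",
    "ConfidenceInterval",
    "success_rate",
    "bernoulli_ci",
]


@dataclass(frozen=True)
class IdentificationResult:
    """Exact hit count / total count with percentage formatting helpers."""

    hits: int
    tests: int

    @property
    def rate(self) -> Fraction:
        return Fraction(self.hits, self.tests)

    @property
    def rate_pct(self) -> float:
        """Percentage rounded to 2 decimals (printing is the only rounding)."""
        return round(float(self.rate) * 100.0, 2)

    def __str__(self) -> str:
        return f"{self.hits}/{self.tests} ({self.rate_pct:.2f}%)"


def success_rate(hits: int, tests: int) -> IdentificationResult:
    """Exact identification success rate Number_hit / Number_test."""
    if tests < 1:
        raise ValueError("tests must be >= 1")
    if not 0 <= hits <= tests:
        raise ValueError(f"hits must lie in [0, {tests}], got {hits}")
    return IdentificationResult(hits=hits, tests=tests)


@dataclass(frozen=True)
class ConfidenceInterval:
    p_hat: float
    n: int
    alpha: float
    z: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def bernoulli_ci(p_hat: float, n: int, alpha: float = 0.05) -> ConfidenceInterval:
    """Wald (1 - alpha) confidence interval for a Bernoulli proportion.

    The critical value z is computed from the standard-normal quantile
    function, so any alpha works; bounds are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = float(norm.ppf(1.0 - alpha / 2.0))
    half = z * (p_hat * (1.0 - p_hat) / n) ** 0.5
    return ConfidenceInterval(
        p_hat=p_hat,
        n=n,
        alpha=alpha,
        z=z,
        lower=max(0.0, p_hat - half),
        upper=min(1.0, p_hat + half),
    )
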
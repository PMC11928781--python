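"""Ratio-scale effect estimates and p-value (consonance) functions.

A published ratio-scale estimate — a hazard ratio, risk ratio or odds ratio
with its confidence interval — is modelled as log-normal: the natural log of
the point estimate is treated as a normally distributed estimator whose
standard error is recovered from the width of the reported CI. Everything
else in the package (tests against arbitrary nulls, compatibility curves,
equivalence decisions, observed power) is derived from that one
approximation.

The central object is :class:`RatioEstimate`; the central maps are
:func:`p_value` (candidate null -> two- or one-sided p) and its restatement
as a curve, :func:`consonance_curve`, which records for every candidate
ratio the minimal confidence level at which the interval would exclude it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import (
    AsymmetryWarning,
    InvalidEstimateError,
    InvalidGridError,
    InvalidLevelError,
    InvalidNullError,
)

__all__ = [
    "ALTERNATIVES",
    "RatioEstimate",
    "LogEstimate",
    "HypothesisTestResult",
    "ConsonanceCurve",
    "se_from_ci",
    "p_value",
    "ci_at_level",
    "min_level_to_exclude",
    "consonance_curve",
]

ALTERNATIVES = ("two_sided", "less", "greater")

#: relative log-asymmetry (in units of se) above which a CI is flagged as
#: inconsistent with the log-normal model
_ASYMMETRY_TOL = 0.01


def _check_level(level: float, *, what: str = "level") -> float:
    if not (0.0 < level < 1.0) or not math.isfinite(level):
        raise InvalidLevelError(
            f"{what} must lie strictly inside (0, 1); got {level!r}"
        )
    return float(level)


def _z_quantile(level: float) -> float:
    """Standard normal quantile at (1+level)/2, i.e. the two-sided multiplier."""
    return float(norm.ppf(0.5 * (1.0 + _check_level(level))))


def se_from_ci(ci_lower: float, ci_upper: float, level: float = 0.95) -> float:
    """Recover the log-scale standard error from a reported ratio-scale CI.

    Under the log-normal model the CI at confidence ``level`` is
    ``exp(theta_hat -/+ q * se)`` with ``q`` the standard normal quantile at
    ``(1+level)/2``, so ``se = (ln(ci_upper) - ln(ci_lower)) / (2 q)``.

    Parameters
    ----------
    ci_lower, ci_upper
        Positive interval bounds on the ratio scale, ``ci_lower < ci_upper``.
    level
        Confidence level of the reported interval, strictly in (0, 1).

    Returns
    -------
    float
        Log-scale standard error, strictly positive.
    """
    if not (0.0 < ci_lower < ci_upper) or not (
        math.isfinite(ci_lower) and math.isfinite(ci_upper)
    ):
        raise InvalidEstimateError(
            f"need 0 < ci_lower < ci_upper; got ({ci_lower!r}, {ci_upper!r})"
        )
    q = _z_quantile(level)
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * q)


@dataclass(frozen=True)
class LogEstimate:
    """Log-scale view of a ratio estimate: point ``theta_hat`` and ``se``."""

    theta_hat: float
    se: float
    level_source: float

    def ci(self, level: float | None = None) -> tuple[float, float]:
        """Ratio-scale CI at ``level`` (default: the source level)."""
        q = _z_quantile(self.level_source if level is None else level)
        return (
            math.exp(self.theta_hat - q * self.se),
            math.exp(self.theta_hat + q * self.se),
        )


@dataclass(frozen=True)
class RatioEstimate:
    """A labelled ratio-scale effect estimate with its confidence interval.

    Parameters
    ----------
    label
        Short identifier used in tables and plots.
    point
        Point estimate on the ratio scale (e.g. a hazard ratio); positive.
    ci_lower, ci_upper
        Reported interval bounds, ``0 < ci_lower <= point <= ci_upper``.
    level
        Confidence level of the reported interval (default 0.95).

    Notes
    -----
    The log-scale standard error is derived from the CI width, not from the
    point estimate, so a CI that is not log-symmetric around the point (as
    profile-likelihood intervals or coarsely rounded values can be) makes the
    model only approximate; an :class:`~compatint.errors.AsymmetryWarning` is
    emitted when the log midpoint is more than ``0.01 * se`` away from
    ``ln(point)``.
    """

    label: str
    point: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        se = se_from_ci(self.ci_lower, self.ci_upper, self.level)  # validates
        if not (self.ci_lower <= self.point <= self.ci_upper):
            raise InvalidEstimateError(
                f"{self.label!r}: point {self.point!r} outside CI "
                f"({self.ci_lower!r}, {self.ci_upper!r})"
            )
        mid = 0.5 * (math.log(self.ci_lower) + math.log(self.ci_upper))
        if abs(math.log(self.point) - mid) > _ASYMMETRY_TOL * se:
            warnings.warn(
                f"{self.label!r}: CI is not log-symmetric around the point "
                f"estimate (|ln point - log midpoint| = "
                f"{abs(math.log(self.point) - mid):.2e} > 0.01*se = "
                f"{_ASYMMETRY_TOL * se:.2e}); derived p-values and powers "
                "rest on the log-normal approximation",
                AsymmetryWarning,
                stacklevel=2,
            )

    @property
    def theta_hat(self) -> float:
        """Natural log of the point estimate."""
        return math.log(self.point)

    @property
    def se(self) -> float:
        """Log-scale standard error recovered from the CI."""
        return se_from_ci(self.ci_lower, self.ci_upper, self.level)

    def to_log(self) -> LogEstimate:
        return LogEstimate(self.theta_hat, self.se, self.level)


@dataclass(frozen=True)
class HypothesisTestResult:
    """Wald test of a ratio estimate against a candidate null value."""

    theta0: float
    alternative: str
    z: float
    p: float


@dataclass(frozen=True)
class ConsonanceCurve:
    """Two-sided p-value across a grid of candidate ratio values.

    ``min_excluding_level[i] = 1 - p_values[i]`` is the smallest confidence
    level at which the interval excludes ``thetas[i]``.
    """

    thetas: np.ndarray
    p_values: np.ndarray
    min_excluding_level: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", np.asarray(self.thetas, dtype=float))
        object.__setattr__(self, "p_values", np.asarray(self.p_values, dtype=float))
        object.__setattr__(self, "min_excluding_level", 1.0 - self.p_values)


def p_value(
    estimate: RatioEstimate,
    theta0: float,
    alternative: str = "two_sided",
) -> HypothesisTestResult:
    """Test the estimate against a candidate null value ``theta0``.

    ``z = (ln(point) - ln(theta0)) / se``; the p-value is ``2 (1 - Phi(|z|))``
    for ``two_sided``, ``Phi(z)`` for ``less`` (alternative: true ratio below
    ``theta0``, as in a non-inferiority test against an upper harm margin) and
    ``1 - Phi(z)`` for ``greater``. Full precision is retained; rounding for
    display is the reporting layer's job.
    """
    if not (theta0 > 0.0) or not math.isfinite(theta0):
        raise InvalidNullError(f"null value must be positive; got {theta0!r}")
    if alternative not in ALTERNATIVES:
        raise InvalidNullError(
            f"alternative must be one of {ALTERNATIVES}; got {alternative!r}"
        )
    z = (estimate.theta_hat - math.log(theta0)) / estimate.se
    if alternative == "two_sided":
        p = 2.0 * float(norm.sf(abs(z)))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(norm.sf(z))
    return HypothesisTestResult(theta0=theta0, alternative=alternative, z=z, p=min(p, 1.0))


def ci_at_level(estimate: RatioEstimate, level: float) -> tuple[float, float]:
    """Confidence interval for the estimate at an arbitrary level.

    At ``level == estimate.level`` this reproduces the reported interval (to
    numerical precision); as ``level -> 0`` it shrinks to the point estimate.
    """
    q = _z_quantile(level)
    log = estimate.to_log()
    return (
        math.exp(log.theta_hat - q * log.se),
        math.exp(log.theta_hat + q * log.se),
    )


def min_level_to_exclude(estimate: RatioEstimate, theta: float) -> float:
    """Minimal confidence level at which the CI excludes ``theta``.

    Equals ``1 - p`` with ``p`` the two-sided p-value at ``theta``: any CI at
    a level above this value contains ``theta``, any level below excludes it.
    A value of 0.66 means even a 66% CI is needed to exclude the candidate —
    weak evidence against it; values near 1 mean the data are sharply
    incompatible with it.
    """
    return 1.0 - p_value(estimate, theta, "two_sided").p


def _default_grid(estimate: RatioEstimate, n: int = 400) -> np.ndarray:
    # log-spaced over [point/4, point*4]: covers the visual range of a
    # compatibility graph for any realistically reported ratio
    return np.exp(
        np.linspace(
            math.log(estimate.point / 4.0), math.log(estimate.point * 4.0), n
        )
    )


def consonance_curve(
    estimate: RatioEstimate, grid: np.ndarray | None = None
) -> ConsonanceCurve:
    """Evaluate the two-sided p-value function over a grid of candidates.

    With ``grid=None`` a 400-point logarithmic grid over
    ``[point/4, point*4]`` is used. The curve peaks (p -> 1) at the grid
    point nearest the point estimate and decreases monotonically as the
    candidate moves away on the log scale.
    """
    if grid is None:
        grid = _default_grid(estimate)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidGridError("grid must be non-empty")
    if not np.all(grid > 0.0):
        raise InvalidGridError("grid values must all be positive")
    if grid.size > 1 and not np.all(np.diff(grid) > 0.0):
        raise InvalidGridError("grid must be strictly increasing")
    z = (estimate.theta_hat - np.log(grid)) / estimate.se
    p = 2.0 * norm.sf(np.abs(z))
    return ConsonanceCurve(thetas=grid, p_values=p)
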
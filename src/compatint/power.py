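"""Observed (post-hoc) power and its one-to-one link to the p-value.

Observed power treats the point estimate and its standard error as the true
population values and asks: with what probability would a repeat of the
study reject the null at level alpha? Under the normal model this is

    power = Phi(z_abs - q) + Phi(-z_abs - q),   q = Phi^{-1}(1 - alpha/2),

with ``z_abs = |ln(point) - ln(theta0)| / se``. Since the two-sided p-value
is ``2 (1 - Phi(z_abs))``, observed power is a deterministic, strictly
decreasing function of p at fixed alpha — it carries no information beyond
the p-value itself. The maps in this module make that correspondence
explicit in both directions.

Two landmarks: at p = 1 (estimate exactly at the null) power equals alpha;
at p = alpha power is 0.5 + Phi(-2q), i.e. 50% up to the far-tail term
(about 4e-5 for alpha = 0.05 — "exactly 50%" only if the far tail of the
rejection region is dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import norm

from .errors import InvalidLevelError, InvalidPValueError, OutOfRangeError
from .estimates import RatioEstimate, p_value

__all__ = ["PowerResult", "observed_power", "power_from_p", "p_from_power"]


@dataclass(frozen=True)
class PowerResult:
    """Observed power at significance level ``alpha``.

    ``z_abs`` is the absolute standardised distance between estimate and
    null; ``source`` records whether it came from an estimate or a p-value.
    """

    alpha: float
    z_abs: float
    power: float
    source: str


def _check_alpha(alpha: float) -> float:
    if not (0.0 < alpha < 1.0):
        raise InvalidLevelError(f"alpha must lie in (0, 1); got {alpha!r}")
    return float(alpha)


def _power_from_z(z_abs: float, alpha: float) -> float:
    q = float(norm.ppf(1.0 - alpha / 2.0))
    # both tails of the two-sided rejection region, including the far tail
    return float(norm.cdf(z_abs - q) + norm.cdf(-z_abs - q))


def observed_power(
    estimate: RatioEstimate, theta0: float = 1.0, alpha: float = 0.05
) -> PowerResult:
    """Post-hoc power of the reported estimate against ``theta0``.

    Assumes the observed point estimate and SE are the population truth.
    At ``z_abs = 0`` (point estimate equal to the null) power equals alpha
    exactly; it never falls below alpha.
    """
    _check_alpha(alpha)
    z_abs = abs(estimate.theta_hat - math.log(theta0)) / estimate.se
    return PowerResult(
        alpha=alpha,
        z_abs=z_abs,
        power=_power_from_z(z_abs, alpha),
        source="from_estimate",
    )


def power_from_p(p: float, alpha: float = 0.05) -> PowerResult:
    """Observed power implied by a two-sided p-value at level ``alpha``.

    Inverts the p-value to ``z_abs = Phi^{-1}(1 - p/2)`` and applies the
    power formula; this is the curve relating the two quantities. ``p = 0``
    is rejected (it would require an infinite test statistic).
    """
    _check_alpha(alpha)
    if not (0.0 < p <= 1.0):
        raise InvalidPValueError(
            f"p must lie in (0, 1]; got {p!r}"
            + (" (p = 0 implies an infinite z)" if p == 0 else "")
        )
    z_abs = float(norm.isf(p / 2.0))  # = Phi^{-1}(1 - p/2), stable for tiny p
    return PowerResult(
        alpha=alpha, z_abs=z_abs, power=_power_from_z(z_abs, alpha), source="from_p"
    )


def p_from_power(power: float, alpha: float = 0.05) -> float:
    """Two-sided p-value at which observed power equals ``power``.

    Numerical inverse of :func:`power_from_p` at fixed alpha. The forward
    map's range is [alpha, 1), so ``power`` must lie there; power -> alpha
    gives p -> 1.
    """
    _check_alpha(alpha)
    if not (alpha <= power < 1.0):
        raise OutOfRangeError(
            f"power must lie in [alpha, 1) = [{alpha}, 1); got {power!r}"
        )
    if power == alpha:
        return 1.0
    z_hi = 45.0  # power is indistinguishable from 1 long before this
    z = brentq(lambda t: _power_from_z(t, alpha) - power, 0.0, z_hi, xtol=1e-13)
    return min(2.0 * float(norm.sf(z)), 1.0)
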
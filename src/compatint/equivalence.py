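"""Non-inferiority and equivalence decisions against clinical margins.

A strict null (ratio exactly 1) can be rejected but never supported; to rule
an effect *out* one tests a composite null such as "HR >= 1.25". Two
decision rules are offered:

``ci_rule`` (default)
    Non-inferior when both the point estimate and the relevant CI bound, at
    the estimate's stated level, lie strictly on the acceptable side of the
    margin. This is the rule used with published 95% intervals; with a
    1-alpha CI it is conservative relative to TOST at alpha.

``tost``
    The one-sided p-value against the composite null beyond the margin is
    compared to alpha. Under the log-normal model TOST at alpha agrees
    exactly with the CI rule applied to a 1-2*alpha interval.

Equivalence is the conjunction of the two directional non-inferiority
criteria; whether the interval also excludes a ratio of 1 is a separate
question (an estimate can reject 1 and still be equivalent — a small but
genuine effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import (
    InvalidLevelError,
    InvalidMarginError,
    MissingBoundError,
    NoEvidenceError,
)
from .estimates import RatioEstimate, p_value

__all__ = [
    "EquivalenceBounds",
    "EquivalenceDecision",
    "noninferiority_test",
    "equivalence_test",
    "classify",
    "margin_from_reference",
    "CLASSIFY_LABELS",
]


@dataclass(frozen=True)
class EquivalenceBounds:
    """One- or two-sided clinical margins on the ratio scale.

    At least one bound must be present; with both, ``lower < upper``.
    """

    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise MissingBoundError("at least one margin must be given")
        for name, value in (("lower", self.lower), ("upper", self.upper)):
            if value is not None and not (value > 0.0):
                raise InvalidMarginError(f"{name} margin must be positive; got {value!r}")
        if self.lower is not None and self.upper is not None and not (
            self.lower < self.upper
        ):
            raise InvalidMarginError(
                f"need lower < upper; got ({self.lower!r}, {self.upper!r})"
            )

    @property
    def two_sided(self) -> bool:
        return self.lower is not None and self.upper is not None


@dataclass(frozen=True)
class EquivalenceDecision:
    """Outcome of a non-inferiority or equivalence test.

    ``p_lower`` / ``p_upper`` are the one-sided p-values against the
    composite nulls "ratio <= lower margin" / "ratio >= upper margin";
    whichever direction was not tested is None.
    """

    rule: str
    alpha: float | None
    decision: str
    p_lower: float | None = None
    p_upper: float | None = None


def _check_rule(rule: str, alpha: float | None) -> None:
    if rule not in ("ci_rule", "tost"):
        raise InvalidMarginError(f"rule must be 'ci_rule' or 'tost'; got {rule!r}")
    if rule == "tost" and not (alpha is not None and 0.0 < alpha < 0.5):
        raise InvalidLevelError(f"tost needs 0 < alpha < 0.5; got {alpha!r}")


def noninferiority_test(
    estimate: RatioEstimate,
    margin: float,
    direction: str = "upper",
    rule: str = "ci_rule",
    alpha: float = 0.05,
) -> EquivalenceDecision:
    """Test whether the effect is acceptably small in one direction.

    ``direction="upper"`` tests the composite null "ratio >= margin" (the
    margin caps acceptable harm above 1); non-inferiority requires, under
    the CI rule, both the point estimate and the upper CI bound strictly
    below the margin. ``direction="lower"`` is the mirror image. The
    one-sided p-value against the composite null is always returned.
    Boundary ties (CI bound exactly at the margin) count as not established.
    """
    if not (margin > 0.0) or not math.isfinite(margin):
        raise InvalidMarginError(f"margin must be positive; got {margin!r}")
    if direction not in ("upper", "lower"):
        raise InvalidMarginError(f"direction must be 'upper' or 'lower'; got {direction!r}")
    _check_rule(rule, alpha)

    if direction == "upper":
        p_one = p_value(estimate, margin, "less").p
        ci_ok = estimate.point < margin and estimate.ci_upper < margin
        label = "noninferior_upper"
    else:
        p_one = p_value(estimate, margin, "greater").p
        ci_ok = estimate.point > margin and estimate.ci_lower > margin
        label = "noninferior_lower"

    ok = (p_one < alpha) if rule == "tost" else ci_ok
    kwargs = {"p_upper" if direction == "upper" else "p_lower": p_one}
    return EquivalenceDecision(
        rule=rule,
        alpha=alpha if rule == "tost" else None,
        decision=label if ok else "not_established",
        **kwargs,
    )


def equivalence_test(
    estimate: RatioEstimate,
    bounds: EquivalenceBounds,
    rule: str = "ci_rule",
    alpha: float = 0.05,
) -> EquivalenceDecision:
    """Declare equivalence when both directional criteria hold.

    Requires both margins. The decision ignores whether the interval
    excludes a ratio of 1: equivalence concerns effect magnitude, not the
    strict null.
    """
    if not bounds.two_sided:
        raise MissingBoundError("equivalence testing needs both margins")
    low = noninferiority_test(estimate, bounds.lower, "lower", rule, alpha)
    up = noninferiority_test(estimate, bounds.upper, "upper", rule, alpha)
    both = low.decision != "not_established" and up.decision != "not_established"
    if both:
        decision = "equivalent"
    elif up.decision != "not_established":
        decision = "noninferior_upper"
    elif low.decision != "not_established":
        decision = "noninferior_lower"
    else:
        decision = "not_established"
    return EquivalenceDecision(
        rule=rule,
        alpha=alpha if rule == "tost" else None,
        decision=decision,
        p_lower=low.p_lower,
        p_upper=up.p_upper,
    )


#: exhaustive label set produced by :func:`classify` — the cartesian product
#: of effect direction (CI vs 1) and accuracy (CI vs the margins), with
#: redundant prefixes collapsed.
CLASSIFY_LABELS = (
    "equivalent",
    "beneficial_and_equivalent",
    "harmful_and_equivalent",
    "noninferior_upper_only",
    "noninferior_lower_only",
    "beneficial_and_noninferior",
    "harmful_and_noninferior",
    "beneficial",
    "harmful",
    "inconclusive",
)


def classify(estimate: RatioEstimate, bounds: EquivalenceBounds) -> str:
    """Joint label: does the CI exclude 1, and is the effect acceptably small?

    The two axes are deliberately independent — "beneficial_and_noninferior"
    (rejects 1 downward, rules out harm beyond the upper margin, but its CI
    dips below the lower margin) and "harmful_and_equivalent" (rejects 1
    upward, yet the whole interval sits inside the margins: a real but
    tolerably small risk increase) both occur in practice.
    """
    if not bounds.two_sided:
        raise MissingBoundError("classification needs both margins")
    eq = equivalence_test(estimate, bounds, "ci_rule")
    if estimate.ci_upper < 1.0:
        direction = "beneficial"
    elif estimate.ci_lower > 1.0:
        direction = "harmful"
    else:
        direction = None

    if eq.decision == "equivalent":
        return "equivalent" if direction is None else f"{direction}_and_equivalent"
    if eq.decision in ("noninferior_upper", "noninferior_lower"):
        if direction is None:
            return f"{eq.decision}_only"
        return f"{direction}_and_noninferior"
    return "inconclusive" if direction is None else direction


def margin_from_reference(
    reference_estimates: list[RatioEstimate],
    preserve_fraction: float = 1.0,
    side: str = "upper",
    level: float = 0.95,
    scale: str = "log",
) -> float:
    """Derive a margin from prior evidence by fixed-effect meta-analysis.

    The references are pooled on the log scale with inverse-variance weights
    (``w_i = 1/se_i^2``); the chosen limit of the pooled CI (default 95%)
    is then shrunk by ``preserve_fraction``. With ``scale="log"`` (the
    standard fraction-of-effect-preserved convention) the margin is
    ``limit ** preserve_fraction``; ``scale="ratio"`` instead multiplies the
    limit by the fraction on the ratio scale.
    """
    if not reference_estimates:
        raise NoEvidenceError("need at least one reference estimate")
    if not (0.0 < preserve_fraction <= 1.0):
        raise InvalidMarginError(
            f"preserve_fraction must be in (0, 1]; got {preserve_fraction!r}"
        )
    if side not in ("upper", "lower"):
        raise InvalidMarginError(f"side must be 'upper' or 'lower'; got {side!r}")
    if scale not in ("log", "ratio"):
        raise InvalidMarginError(f"scale must be 'log' or 'ratio'; got {scale!r}")

    weights = [1.0 / est.se**2 for est in reference_estimates]
    total = sum(weights)
    theta = sum(w * est.theta_hat for w, est in zip(weights, reference_estimates)) / total
    se = 1.0 / math.sqrt(total)
    q = float(norm.ppf(0.5 * (1.0 + level)))
    limit = math.exp(theta + q * se) if side == "upper" else math.exp(theta - q * se)
    if scale == "log":
        return math.exp(preserve_fraction * math.log(limit))
    return preserve_fraction * limit
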
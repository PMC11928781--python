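"""Worked example: composite nulls — non-inferiority and equivalence.

A strict null (HR exactly 1) can never be supported; ruling out a
clinically meaningful harm requires a composite null such as "HR >= 1.25".
With margins (0.80, 1.25), an estimate whose whole CI sits inside them is
equivalent even when it rejects HR 1 — a real but tolerably small effect.
"""

import warnings

from compatint import (
    AsymmetryWarning,
    EquivalenceBounds,
    RatioEstimate,
    classify,
    equivalence_test,
    margin_from_reference,
    noninferiority_test,
)

warnings.simplefilter("ignore", AsymmetryWarning)

bounds = EquivalenceBounds(0.80, 1.25)
estimates = [
    RatioEstimate("ischemic events", 0.85, 0.76, 0.96),
    RatioEstimate("bleeding (subgroup)", 0.86, 0.40, 1.87),
    RatioEstimate("hypothetical small harm", 1.15, 1.06, 1.24),
]

for est in estimates:
    ni = noninferiority_test(est, 1.25, "upper")
    eq = equivalence_test(est, bounds)
    print(f"{est.label}: HR {est.point:g} ({est.ci_lower:g}; {est.ci_upper:g})")
    print(f"  non-inferior vs 1.25: {ni.decision} (one-sided p {ni.p_upper:.2f})")
    print(f"  equivalence in (0.80, 1.25): {eq.decision}")
    print(f"  classification: {classify(est, bounds)}")

# margin derivation: pool prior evidence, keep half the effect on the log scale
prior = [
    RatioEstimate("study A", 1.30, 1.05, 1.61),
    RatioEstimate("study B", 1.25, 1.08, 1.45),
]
margin = margin_from_reference(prior, preserve_fraction=0.5, side="upper")
print(f"\nMargin from two pooled reference studies (preserve 1/2): {margin:.3f}")
print("A fraction of 1 would reuse the pooled upper CI limit itself.")
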
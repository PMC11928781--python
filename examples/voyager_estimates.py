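"""Worked example: what a "non-significant" hazard ratio does and does not say.

Two published estimates from a trial of rivaroxaban in peripheral artery
disease: a precise benefit on ischemic events, HR 0.85 (95% CI 0.76-0.96),
and a wide bleeding estimate in a subgroup, HR 0.86 (95% CI 0.40-1.87).
Both point estimates are nearly identical; the information they carry is
not.
"""

import warnings

from compatint import (
    AsymmetryWarning,
    RatioEstimate,
    ci_at_level,
    min_level_to_exclude,
    p_value,
)

# the printed values are rounded, so the CIs are not exactly log-symmetric
warnings.simplefilter("ignore", AsymmetryWarning)

primary = RatioEstimate("ischemic events", 0.85, 0.76, 0.96)
bleeding = RatioEstimate("bleeding (subgroup)", 0.86, 0.40, 1.87)

for est in (primary, bleeding):
    res = p_value(est, 1.0)
    print(f"{est.label}: HR {est.point:g} ({est.ci_lower:g}; {est.ci_upper:g})")
    print(f"  two-sided p vs HR 1:        {res.p:.3f}")
    print(f"  one-sided p vs margin 1.25: {p_value(est, 1.25, 'less').p:.2f}")
    level = min_level_to_exclude(est, 1.25)
    print(f"  1.25 excluded only by CIs up to the {level:.0%} level")
    lo, hi = ci_at_level(est, 0.50)
    print(f"  50% CI: ({lo:.2f}, {hi:.2f})")

print(
    "\nThe bleeding p of 0.70 does not support 'no bleeding risk': even a\n"
    "66% interval still reaches the 1.25 harm margin, while the ischemic\n"
    "estimate excludes HR 1 at the 99.4% level."
)
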
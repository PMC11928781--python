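"""Worked example: post-hoc power adds nothing to the p-value.

Observed power treats the estimate and its SE as the population truth and
asks how often a repeat study would reject the null. At fixed alpha it is a
deterministic, invertible function of the p-value — so quoting both says
the same thing twice.
"""

import warnings

from compatint import (
    AsymmetryWarning,
    RatioEstimate,
    observed_power,
    p_from_power,
    p_value,
    power_from_p,
)

warnings.simplefilter("ignore", AsymmetryWarning)

bleeding = RatioEstimate("bleeding (subgroup)", 0.86, 0.40, 1.87)
p = p_value(bleeding, 1.0).p
power = observed_power(bleeding, 1.0, alpha=0.05).power
print(f"bleeding estimate: p = {p:.2f} -> observed power {power:.0%}")
print(f"power from the p-value alone: {power_from_p(p, 0.05).power:.0%}")
print(f"and back again: p = {p_from_power(power, 0.05):.2f}")

print("\nLandmarks of the p <-> power curve at alpha = 0.05:")
print(f"  p = 1.00 -> power = {power_from_p(1.0, 0.05).power:.2f}  (exactly alpha)")
print(f"  p = 0.05 -> power = {power_from_p(0.05, 0.05).power:.4f}  (~50%)")
print(f"  p = 0.71 -> power = {power_from_p(0.71, 0.05).power:.0%}")
print(
    "\nLow observed power can simply mean the estimate sits near the null —\n"
    "it cannot distinguish 'underpowered' from 'clinically irrelevant'."
)
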
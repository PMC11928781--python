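# compatint

Tools for interpreting "non-significant" results from published ratio-scale
estimates — hazard ratios, risk ratios, odds ratios — without individual
patient data. The unit of input is what a paper prints: a point estimate, a
confidence interval and its level.

Failing to reject the null hypothesis HR = 1 is routinely misread as
evidence that an effect is absent, that a study was underpowered, or that a
multiplicity-corrected result is more trustworthy. `compatint`
operationalises the correct alternatives for clinical epidemiologists,
meta-analysts and methods teachers:

- **Composite-null testing.** Non-inferiority and equivalence decisions
  against clinical margins, by the CI rule (point estimate and CI bound
  strictly inside the margin) or TOST (two one-sided tests), with margin
  derivation from inverse-variance pooled prior evidence.
- **Compatibility (consonance) curves.** For every candidate ratio θ, the
  two-sided p-value and the minimal confidence level `1 − p` at which the
  interval excludes θ — the whole family of CIs at once, not just the 95%
  one.
- **Observed power.** `power = Φ(z − q) + Φ(−z − q)` with
  `z = |ln HR − ln θ₀|/se` and `q = Φ⁻¹(1 − α/2)`; the package exposes the
  exact bijection between p-value and observed power at fixed α, which is
  why post-hoc power adds no information.
- **P-value-set diagnostics.** Proportion significant, empirical false
  discovery rate under Bonferroni correction when ground truth is known,
  and a Kolmogorov–Smirnov test of the set against Uniform(0, 1).

The model throughout is the log-normal approximation: `ln HR` is treated as
normal with standard error `(ln U − ln L)/(2q)` recovered from the reported
interval `(L, U)`.

## Worked example

```python
from compatint import RatioEstimate, p_value, min_level_to_exclude, observed_power

bleeding = RatioEstimate("bleeding", 0.86, 0.40, 1.87)     # HR (95% CI)
print(round(p_value(bleeding, 1.0).p, 2))                  # 0.7
print(round(p_value(bleeding, 1.25, "less").p, 2))         # 0.17
print(round(min_level_to_exclude(bleeding, 1.25), 2))      # 0.66
print(round(observed_power(bleeding, 1.0, 0.05).power, 2)) # 0.07
```

The two-sided p of 0.70 against HR 1 cannot support "no bleeding risk": the
one-sided test against a 1.25 harm margin gives p = 0.17, and only
confidence intervals up to the 66% level exclude 1.25 — the data are
compatible with substantial harm. The observed power of 7% is just the
p-value restated, not evidence of an underpowered design.

The `examples/` directory holds one narrative script per capability
(`voyager_estimates.py`, `equivalence_decisions.py`,
`observed_power_is_the_p_value.py`, `fdr_under_bonferroni.py`,
`pvalue_distributions.py`); each builds a small input, runs the method and
prints what the numbers mean.

## Command line

A thin CLI wraps the library for batch use over delimited tables
(`label,estimate,ci_lower,ci_upper[,level]`):

```sh
compatint test estimates.csv --null 1.0
compatint equiv estimates.csv --lower 0.80 --upper 1.25
compatint power estimates.csv            # or: compatint power --p 0.71
compatint curve estimates.csv --reference 1.25 --plot compat
compatint pset pvals.csv --alpha 0.05 --bonferroni --ks
compatint simulate --n 1000 --mu 2 --seed 42 --out pvals.csv
compatint report estimates.csv --lower 0.80 --upper 1.25 --plot forest.png
```

Full-precision result tables go to stdout or `--out`; rounded human
summaries go to stderr.

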
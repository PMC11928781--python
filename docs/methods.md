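# Methods

## The model: log-normal estimates recovered from printed intervals

Every operation rests on one approximation: for a published ratio-scale
estimate with point `HR` and CI `(L, U)` at level `1 − α`, the log estimate
`θ̂ = ln HR` is treated as normally distributed with standard error

    se = (ln U − ln L) / (2 q),    q = Φ⁻¹((1 + level)/2).

This is the model under which printed HR/CI/p triplets are mutually
consistent, and it lets the package reproduce a paper's p-values from its
intervals alone. Wald tests against any positive null θ₀ use
`z = (θ̂ − ln θ₀)/se`; two-sided p is `2(1 − Φ(|z|))`, which equals twice
the smaller one-sided tail (tested as a property, not assumed).

The approximation fails quietly when the reported interval is not
log-symmetric around the point estimate — profile-likelihood intervals, or
simply aggressive rounding of the printed values. The constructor therefore
warns (`AsymmetryWarning`) when `|ln HR − (ln L + ln U)/2| > 0.01·se`.
Published, rounded inputs routinely trigger this; derived quantities remain
correct to roughly the rounding in the inputs. An extreme case: a printed
pair like HR 1.00 (0.99; 1.01) alongside p = 0.71 is impossible under the
model (a point exactly at the null forces p = 1) and can only reflect
rounding of the point estimate; such inputs are accepted, warned about, and
not treated as exact.

## Compatibility curves

`min_level_to_exclude(θ) = 1 − p_two(θ)`: confidence intervals at levels
below this value exclude θ, levels above include it. The consonance curve
evaluates this over a grid — by default 400 logarithmically spaced points
spanning `[HR/4, HR·4]`, wide enough to cover the informative range for any
realistically reported estimate. The identity
`min_excluding_level = 1 − p` holds exactly by construction; the
complement `min_level + p = 1` is exact up to one ulp (for p < 0.5 the
subtraction `1 − p` rounds).

## Equivalence and non-inferiority

Margins are strictly enforced: a CI bound exactly equal to the margin is
*not* established, because the decision criterion requires the estimate and
bound to be strictly inside. Two rules are offered:

- `ci_rule` (default): point estimate and the relevant bound of the CI *at
  the estimate's stated level* strictly inside the margin. Used with 95%
  intervals this is conservative relative to TOST at α = 0.05.
- `tost`: one-sided p against the composite null beyond the margin,
  compared with α. Under the log-normal model TOST at α coincides exactly
  with the CI rule applied to a `1 − 2α` interval (tested on randomized
  inputs).

The point-estimate check is implied by the CI check for log-symmetric
inputs (the point always lies inside its own interval) but is performed
anyway for robustness to asymmetric, hand-entered values. Equivalence is
the conjunction of the two directional decisions and deliberately ignores
whether the interval excludes 1: magnitude and direction are separate
questions, which is why `classify` reports labels like
`harmful_and_equivalent` (rejects 1 upward, yet the whole interval sits
inside the margins).

Margin derivation pools reference estimates by fixed-effect
inverse-variance weighting on the log scale (`w = 1/se²`), takes the chosen
95% pooled CI limit, and preserves a fraction of it on the log scale
(`margin = limit^f`), the standard fraction-of-effect convention;
ratio-scale multiplication (`f · limit`) is available behind the explicit
`scale="ratio"` option because the convention is not universal.

## Observed power

`power = Φ(z_abs − q) + Φ(−z_abs − q)` keeps the far tail of the two-sided
rejection region. Consequently at `p = α` the power is
`0.5 + Φ(−2q)` — 50.004% at α = 0.05 — rather than exactly 50%; the
familiar "exactly 50%" statement drops the far-tail term, and the two agree
to display rounding (nearest percent) for conventional α. At `p = 1` power
equals α exactly. `power_from_p` computes `z_abs = Φ⁻¹(1 − p/2)` via the
inverse survival function, which is numerically stable for very small p;
`p_from_power` inverts the forward map with Brent's method on
`z ∈ [0, 45]` to an absolute tolerance of 1e-13 in z. Display rounding
(p to two decimals, power to the nearest percent) lives only in the CLI
layer; the library returns full precision.

No prospective power or sample-size planner is included: design-stage power
is a different exercise, and this package concerns interpretation of
completed analyses.

## P-value sets

Significance is strict (`p < threshold`); ties at the threshold are not
significant. Empirical FDR with zero discoveries is reported as undefined
(`None`), never 0 — no discoveries is silence, not perfect error control.
Bonferroni is the only correction used in the decision diagnostics;
Holm and Benjamini–Hochberg are available as clearly labelled extensions
via `adjusted_rejections` (delegating to statsmodels, which uses `p ≤`
conventions — noted in its docstring).

The KS uniformity test is the standard one-sample two-sided test against
Uniform(0, 1), with the exact finite-sample null distribution for n ≤ 100
and the asymptotic Kolmogorov distribution above. The implementation is
cross-checked in the tests against a hand-coded ECDF-supremum oracle
(exact agreement for all n ≤ 20) and against frozen reference p-values
computed independently with R's `ks.test` (agreement to 1e-6 at
n = 5, 10, 50). Dependence between p-values (e.g. composite and component
outcomes tested together) is *not* handled; the test assumes an
independent set, and results on correlated sets are anticonservative.

## Synthetic generators

`simulate_pvalues` draws test statistics `z ~ Normal(μ, σ)` and converts
each to `p = 2(1 − Φ(|z|))` under the **standard normal null reference**,
even when μ ≠ 0 — the null hypothesis stays fixed while the data-generating
truth moves, which is precisely what makes the alternative's p-values pile
up near zero. Defaults follow the canonical demonstration: n = 1000,
σ = 1, μ = 0 (null true) or μ = 2 (null false). Under μ = 2 the expected
fraction with p < 0.05 is `Φ(0.04) + Φ(−3.96) ≈ 0.516`; tests and the
acceptance script treat the realized fraction as stochastic with a
3-binomial-SE band. Only the normal family is implemented; any
location-scale family with a tractable CDF would do, and the generator is
the single place such a hook would go.

The fixed FDR scenarios are constructions (their per-test p-values chosen
to realise the exact transitions 1/3 → 0 and 1/3 → 1 between thresholds
0.05 and 0.005 with 4 true effects and 6 nulls), not measurements of any
dataset. `random_estimate` builds exactly log-symmetric estimates, so
round-trip properties hold to 1e-10 by construction; real printed inputs
are rounded and do not round-trip better than their rounding.

What the generators do **not** emulate: dependence among tests, composite
outcomes, heterogeneous standard errors across a literature, publication
filtering. Passing tests therefore validate the arithmetic and the stated
identities, not robustness to those real-data features.

## Numerical conventions and problem sizes

- Confidence levels and alphas are strict: (0, 1) open; 0 and 1 are
  rejected, never clamped.
- Seeds: a single integer fully determines any simulation;
  property suites use fixed seeds, and the acceptance script derives
  per-scenario child seeds from its `--seed` via `numpy.random.SeedSequence`.
- Suite problem sizes are kept at desk scale as a design choice: 1000-draw
  simulations, 500-seed KS calibration at n = 100, 200–1000-case property
  loops — enough to pin each identity at its stated tolerance.
- Result tables are written with 17 significant digits so CLI output
  parses back bit-for-bit equal to the library's numbers.
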
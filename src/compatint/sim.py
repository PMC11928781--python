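"""Synthetic generators: p-value sets and random ratio estimates.

The p-value generator emulates the classic two-group picture: a test
statistic z drawn from Normal(mu, sd) and converted to a two-sided p-value
under the *standard normal null reference* — the null stays fixed even when
the statistics are generated under an alternative (mu != 0), which is what
makes the alternative's p-value distribution pile up near zero. With the
defaults mu=0 or mu=2, sd=1 and n=1000 this reproduces the canonical
"null is uniform / alternative is left-skewed" histograms; under mu=2 the
expected fraction with p < 0.05 is Phi(0.04) + Phi(-3.96) ≈ 0.516.

The fixed false-discovery scenarios are constructions, not extractions from
any dataset: ten tests (4 true effects, 6 nulls) whose empirical FDR moves
from 1/3 to 0 in scenario A but from 1/3 to 1 in scenario B when the
threshold drops from 0.05 to the Bonferroni-corrected 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import InvalidSpecError
from .estimates import RatioEstimate, _z_quantile
from .pset import NULL, TRUE_EFFECT, PValueSet

__all__ = [
    "SimulationSpec",
    "simulate_pvalues",
    "figure4_fixtures",
    "random_estimate",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Normal test-statistic model: n draws from Normal(mu, sd), seeded."""

    n: int
    mu: float
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise InvalidSpecError(f"n must be a count >= 1; got {self.n!r}")
        if not (self.sd > 0.0):
            raise InvalidSpecError(f"sd must be positive; got {self.sd!r}")


def simulate_pvalues(spec: SimulationSpec) -> PValueSet:
    """Draw z ~ Normal(mu, sd) and return two-sided p-values under the standard normal.

    ``p = Phi(-|z|) + (1 - Phi(|z|)) = 2 (1 - Phi(|z|))`` — both tails beyond
    the sampled statistic, evaluated under the fixed null reference. Truth
    labels are "null" iff mu == 0. Fully reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.normal(spec.mu, spec.sd, spec.n)
    p = 2.0 * norm.sf(np.abs(z))
    truth = np.full(spec.n, NULL if spec.mu == 0.0 else TRUE_EFFECT, dtype=object)
    return PValueSet(p_values=p, truth=truth)


def figure4_fixtures() -> tuple[PValueSet, PValueSet]:
    """Two deterministic 10-test scenarios (4 true effects, 6 nulls).

    Scenario A is the naive expectation: lowering the threshold from 0.05 to
    0.005 drops the empirical FDR from 1/3 to 0. Scenario B has the same
    FDR of 1/3 at 0.05, but at 0.005 the only surviving discovery is a null
    — the correction *raises* the FDR to 1.
    """
    truth = np.array([TRUE_EFFECT] * 4 + [NULL] * 6, dtype=object)
    scenario_a = PValueSet(
        p_values=np.array(
            [0.001, 0.002, 0.003, 0.004, 0.010, 0.030, 0.200, 0.400, 0.600, 0.800]
        ),
        truth=truth.copy(),
    )
    scenario_b = PValueSet(
        p_values=np.array(
            [0.010, 0.020, 0.030, 0.040, 0.004, 0.045, 0.300, 0.500, 0.700, 0.900]
        ),
        truth=truth.copy(),
    )
    return scenario_a, scenario_b


def random_estimate(
    seed: int | np.random.Generator,
    se_range: tuple[float, float] = (0.05, 0.8),
    level: float = 0.95,
) -> RatioEstimate:
    """Random valid ratio estimate for property tests.

    The log point is drawn from Normal(0, 0.5) and the log-scale se
    uniformly from ``se_range``; the CI is built to be exactly log-symmetric
    so every invariant (ordering, round-trip) holds by construction.
    Accepts either an integer seed or an existing Generator.
    """
    lo, hi = se_range
    if not (0.0 < lo < hi):
        raise InvalidSpecError(f"se_range must satisfy 0 < lo < hi; got {se_range!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.normal(0.0, 0.5)
    se = rng.uniform(lo, hi)
    q = _z_quantile(level)
    return RatioEstimate(
        label="random",
        point=float(np.exp(theta)),
        ci_lower=float(np.exp(theta - q * se)),
        ci_upper=float(np.exp(theta + q * se)),
        level=level,
    )
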
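"""Diagnostics for sets of p-values.

A single small p-value cannot tell a true from a false positive, and a
Bonferroni correction can move the empirical false discovery rate in either
direction depending on the (unknown) mix of true effects and nulls. These
diagnostics make that concrete: significance counts at raw and adjusted
thresholds, empirical FDR when ground truth is known (simulations,
constructed scenarios), and a Kolmogorov-Smirnov test of the whole set
against the uniform distribution that all-null p-values would follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InvalidLevelError,
    InvalidPValueError,
    MissingTruthError,
)

__all__ = [
    "TRUE_EFFECT",
    "NULL",
    "PValueSet",
    "FdrDiscoveries",
    "FdrReport",
    "bonferroni_threshold",
    "empirical_fdr",
    "bonferroni_report",
    "proportion_significant",
    "ks_uniformity_test",
    "adjusted_rejections",
]

TRUE_EFFECT = "true_effect"
NULL = "null"


@dataclass(frozen=True)
class PValueSet:
    """P-values with optional ground-truth labels and row labels.

    ``truth`` entries, when present, are ``"true_effect"`` or ``"null"`` and
    must match ``p_values`` in length.
    """

    p_values: np.ndarray
    truth: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise InvalidPValueError("need a one-dimensional, non-empty p-value array")
        if not np.all((p >= 0.0) & (p <= 1.0)):
            raise InvalidPValueError("all p-values must lie in [0, 1]")
        object.__setattr__(self, "p_values", p)
        if self.truth is not None:
            t = np.asarray(self.truth, dtype=object)
            if t.shape != p.shape:
                raise MissingTruthError("truth labels must match p-values in length")
            bad = set(t) - {TRUE_EFFECT, NULL}
            if bad:
                raise MissingTruthError(f"unknown truth labels: {sorted(map(str, bad))}")
            object.__setattr__(self, "truth", t)
        if self.labels is not None and len(self.labels) != p.size:
            raise InvalidPValueError("row labels must match p-values in length")

    @property
    def n(self) -> int:
        return int(self.p_values.size)


@dataclass(frozen=True)
class FdrDiscoveries:
    """Discoveries at one threshold; ``fdr`` is None when nothing is significant."""

    threshold: float
    n_significant: int
    n_false_positive: int
    fdr: float | None


@dataclass(frozen=True)
class FdrReport:
    """Empirical FDR at the raw alpha and at its Bonferroni adjustment."""

    alpha_raw: float
    alpha_adjusted: float
    n_significant_raw: int
    n_significant_adjusted: int
    fdr_raw: float | None
    fdr_adjusted: float | None


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold ``alpha / m`` for ``m`` simultaneous tests."""
    if not (0.0 < alpha < 1.0):
        raise InvalidLevelError(f"alpha must lie in (0, 1); got {alpha!r}")
    if int(m) != m or m < 1:
        raise InvalidLevelError(f"number of tests must be a count >= 1; got {m!r}")
    return alpha / m


def empirical_fdr(pset: PValueSet, threshold: float) -> FdrDiscoveries:
    """Fraction of discoveries at ``threshold`` whose null is actually true.

    Significance is strict (``p < threshold``). With zero discoveries the
    FDR is undefined and reported as None — silence is not evidence of
    perfect error control.
    """
    if pset.truth is None:
        raise MissingTruthError("empirical FDR needs ground-truth labels")
    if not (0.0 < threshold < 1.0):
        raise InvalidLevelError(f"threshold must lie in (0, 1); got {threshold!r}")
    sig = pset.p_values < threshold
    n_sig = int(sig.sum())
    n_false = int((sig & (pset.truth == NULL)).sum())
    return FdrDiscoveries(
        threshold=threshold,
        n_significant=n_sig,
        n_false_positive=n_false,
        fdr=None if n_sig == 0 else n_false / n_sig,
    )


def bonferroni_report(pset: PValueSet, alpha: float = 0.05) -> FdrReport:
    """Empirical FDR before and after Bonferroni correction for all n tests."""
    adj = bonferroni_threshold(alpha, pset.n)
    raw = empirical_fdr(pset, alpha)
    corr = empirical_fdr(pset, adj)
    return FdrReport(
        alpha_raw=alpha,
        alpha_adjusted=adj,
        n_significant_raw=raw.n_significant,
        n_significant_adjusted=corr.n_significant,
        fdr_raw=raw.fdr,
        fdr_adjusted=corr.fdr,
    )


def proportion_significant(pset: PValueSet, alpha: float = 0.05) -> float:
    """Fraction of the set with ``p < alpha`` (strict), as an exact count / n."""
    if not (0.0 < alpha < 1.0):
        raise InvalidLevelError(f"alpha must lie in (0, 1); got {alpha!r}")
    return int((pset.p_values < alpha).sum()) / pset.n


def ks_uniformity_test(pset: PValueSet) -> tuple[float, float]:
    """One-sample two-sided KS test of the p-values against Uniform(0, 1).

    Returns ``(D, p)`` where D is the supremum distance between the
    empirical CDF and the uniform CDF. The exact small-sample null
    distribution is used for n <= 100 and the asymptotic Kolmogorov
    distribution above. A small p flags a set unlikely to consist entirely
    of null results.
    """
    method = "exact" if pset.n <= 100 else "asymp"
    res = stats.ks_1samp(pset.p_values, stats.uniform.cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def adjusted_rejections(
    pset: PValueSet, alpha: float = 0.05, method: str = "bonferroni"
) -> np.ndarray:
    """Rejection flags under a multiplicity correction (extension).

    ``method`` is any :func:`statsmodels.stats.multitest.multipletests`
    method, e.g. ``"bonferroni"``, ``"holm"`` or ``"fdr_bh"``. Note that
    statsmodels rejects at ``p <= threshold`` while the diagnostics above
    use the strict ``p < threshold`` convention, so flags can differ on
    exact ties.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidLevelError(f"alpha must lie in (0, 1); got {alpha!r}")
    reject, _, _, _ = multipletests(pset.p_values, alpha=alpha, method=method)
    return reject
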
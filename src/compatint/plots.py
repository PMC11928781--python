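"""Plot rendering: forest plots with margins, compatibility graphs,
p-value/observed-power curves and p-value histograms.

Figures are deterministic in layout given their inputs; only the underlying
result tables, not image bytes, are contractual outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .equivalence import EquivalenceBounds
from .errors import CompatIntError, InvalidLevelError
from .estimates import RatioEstimate, consonance_curve, min_level_to_exclude
from .power import power_from_p
from .pset import PValueSet

__all__ = [
    "render_forest",
    "render_compatibility",
    "render_power_curve",
    "render_pvalue_hist",
]


def render_forest(
    estimates: list[RatioEstimate],
    bounds: EquivalenceBounds | None,
    path: str | Path,
) -> Path:
    """Horizontal CI segments on a log axis with reference and margin lines."""
    if not estimates:
        raise CompatIntError("nothing to plot: empty estimate list")
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.6 * len(estimates)))
    ys = np.arange(len(estimates))[::-1]
    for y, est in zip(ys, estimates):
        ax.plot([est.ci_lower, est.ci_upper], [y, y], color="black", lw=1.5)
        ax.plot(est.point, y, "o", color="black", ms=6)
    ax.axvline(1.0, color="grey", lw=1)
    if bounds is not None:
        for margin in (bounds.lower, bounds.upper):
            if margin is not None:
                ax.axvline(margin, color="orange", lw=1.5)
    ax.set_xscale("log")
    ax.set_yticks(ys)
    ax.set_yticklabels([e.label for e in estimates])
    ax.set_xlabel("ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_compatibility(
    estimate: RatioEstimate,
    path: str | Path,
    grid: np.ndarray | None = None,
    reference: float | None = None,
) -> Path:
    """Coverage level against candidate ratios, with the supported region shaded.

    A ``reference`` value (e.g. a margin of 1.25) is annotated with the
    minimal confidence level at which the interval excludes it.
    """
    curve = consonance_curve(estimate, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.thetas, curve.min_excluding_level, 1.0, alpha=0.3)
    ax.plot(curve.thetas, curve.min_excluding_level, color="black", lw=1)
    ax.axvline(1.0, color="grey", lw=1)
    if reference is not None:
        level = min_level_to_exclude(estimate, reference)
        ax.axvline(reference, color="orange", lw=1.5)
        ax.annotate(
            f"{reference:g} excluded from {level:.0%} CI",
            xy=(reference, level),
            xytext=(5, 5),
            textcoords="offset points",
        )
    ax.set_xscale("log")
    ax.set_ylim(0, 1)
    ax.set_xlabel("candidate ratio (log scale)")
    ax.set_ylabel("confidence interval coverage")
    ax.set_title(estimate.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_power_curve(
    alphas: list[float], path: str | Path, n_points: int = 400
) -> Path:
    """Observed power as a function of the p-value, one curve per alpha.

    Dashed guides mark p = alpha and power = 50%; each curve ends at
    (1, alpha) and passes within rounding of 50% power at p = alpha.
    """
    for alpha in alphas:
        if not (0.0 < alpha < 1.0):
            raise InvalidLevelError(f"alpha must lie in (0, 1); got {alpha!r}")
    ps = np.linspace(1e-6, 1.0, n_points)
    fig, ax = plt.subplots(figsize=(6, 4))
    for alpha in sorted(alphas):
        powers = [power_from_p(float(p), alpha).power for p in ps]
        ax.plot(ps, powers, label=f"alpha = {alpha:g}")
        ax.axvline(alpha, color="grey", ls="--", lw=0.8)
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("two-sided p-value")
    ax.set_ylabel("observed power")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_pvalue_hist(
    psets: list[PValueSet], path: str | Path, titles: list[str] | None = None
) -> Path:
    """Stacked histograms of one or more p-value sets over [0, 1]."""
    if not psets:
        raise CompatIntError("nothing to plot: empty p-value set list")
    fig, axes = plt.subplots(
        len(psets), 1, figsize=(6, 2.5 * len(psets)), squeeze=False
    )
    bins = np.linspace(0, 1, 21)
    for i, pset in enumerate(psets):
        ax = axes[i, 0]
        ax.hist(pset.p_values, bins=bins, color="steelblue", edgecolor="white")
        if titles and i < len(titles):
            ax.set_title(titles[i])
        ax.set_xlim(0, 1)
    axes[-1, 0].set_xlabel("p-value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
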
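"""Delimited-text input and output.

Estimate tables are comma-delimited with header
``label,estimate,ci_lower,ci_upper[,level]`` (missing ``level`` defaults to
0.95); p-value tables are ``label,p[,truth]`` with truth in {true, null}.
Row-level problems are reported with their file line numbers; valid rows
are kept.
"""

from __future__ import annotations

import io
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CompatIntError, TableFormatError
from .estimates import RatioEstimate
from .pset import NULL, TRUE_EFFECT, PValueSet

__all__ = ["read_estimates", "read_pvalues", "write_table", "estimates_frame"]

logger = logging.getLogger("compatint")

_ESTIMATE_COLUMNS = ["label", "estimate", "ci_lower", "ci_upper"]
_TRUTH_ALIASES = {"true": TRUE_EFFECT, "true_effect": TRUE_EFFECT, "null": NULL}


def read_estimates(
    path: str | Path | io.TextIOBase, on_error: str = "warn"
) -> tuple[list[RatioEstimate], list[str]]:
    """Read ratio estimates from a delimited table.

    Returns ``(estimates, errors)`` where ``errors`` holds one message per
    rejected row, each naming its 1-based file line. ``on_error="raise"``
    turns the first row problem into an exception; the default logs them
    and preserves the valid rows.
    """
    if on_error not in ("warn", "raise"):
        raise ValueError(f"on_error must be 'warn' or 'raise'; got {on_error!r}")
    frame = pd.read_csv(
        path,
        dtype={"label": str},
        skipinitialspace=True,
        keep_default_na=False,
        na_values=[""],
    )
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _ESTIMATE_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"estimate table must have header label,estimate,ci_lower,ci_upper"
            f"[,level]; missing {missing}"
        )
    if frame.empty:
        logger.warning("estimate table has a header but no data rows")
        return [], []

    estimates: list[RatioEstimate] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # 1-based, after the header line
        try:
            level = row.get("level", np.nan)
            level = 0.95 if pd.isna(level) else float(level)
            estimates.append(
                RatioEstimate(
                    label=str(row["label"]),
                    point=float(row["estimate"]),
                    ci_lower=float(row["ci_lower"]),
                    ci_upper=float(row["ci_upper"]),
                    level=level,
                )
            )
        except (CompatIntError, TypeError, ValueError) as exc:
            message = f"line {line}: {exc}"
            if on_error == "raise":
                raise TableFormatError(message) from exc
            errors.append(message)
            logger.warning("skipping invalid row — %s", message)
    return estimates, errors


def read_pvalues(path: str | Path | io.TextIOBase) -> PValueSet:
    """Read a p-value set from a ``label,p[,truth]`` table."""
    # keep_default_na: "null" is a truth label here, not a missing value
    frame = pd.read_csv(
        path,
        dtype={"label": str},
        skipinitialspace=True,
        keep_default_na=False,
        na_values=[""],
    )
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if "p" not in frame.columns or "label" not in frame.columns:
        raise TableFormatError("p-value table must have header label,p[,truth]")
    truth = None
    if "truth" in frame.columns:
        raw = [str(t).strip().lower() for t in frame["truth"]]
        unknown = sorted(set(raw) - set(_TRUTH_ALIASES))
        if unknown:
            raise TableFormatError(f"unknown truth labels: {unknown}")
        truth = np.array([_TRUTH_ALIASES[t] for t in raw], dtype=object)
    return PValueSet(
        p_values=frame["p"].to_numpy(dtype=float),
        truth=truth,
        labels=list(frame["label"]),
    )


def estimates_frame(estimates: list[RatioEstimate]) -> pd.DataFrame:
    """Input-mirroring DataFrame, one row per estimate."""
    return pd.DataFrame(
        {
            "label": [e.label for e in estimates],
            "estimate": [e.point for e in estimates],
            "ci_lower": [e.ci_lower for e in estimates],
            "ci_upper": [e.ci_upper for e in estimates],
            "level": [e.level for e in estimates],
        }
    )


def write_table(frame: pd.DataFrame, out: str | Path | None) -> None:
    """Write a result table as CSV to ``out``, or stdout when None/'-'.

    Floats are written with 17 significant digits so the values parse back
    bit-for-bit.
    """
    target = sys.stdout if out is None or out == "-" else out
    frame.to_csv(target, index=False, float_format="%.17g")
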
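"""Behavioral statistics for the grammaticality-judgment task.

Accuracy scoring against 50% chance, the explicit-vs-implicit group
comparison, and the age-controlled partial correlation between judgment
accuracy and working-memory capacity.  The t statistics are computed from
summary statistics (mean, SD, n) so that printed group summaries can be
fed in directly; raw-data paths reduce to the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grammar import TestItem

__all__ = [
    "TTestResult",
    "judgment_accuracy",
    "one_sample_t",
    "two_sample_t",
    "partial_correlation",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False  # both groups constant and equal


def judgment_accuracy(responses: Sequence[tuple[TestItem, bool]]) -> float:
    """Fraction of grammaticality answers matching the item's truth."""
    if not responses:
        raise ValueError("need at least one response")
    hits = sum(1 for item, answer in responses if bool(answer) == item.truth)
    return hits / len(responses)


def one_sample_t(mean: float, sd: float, n: int, mu0: float = 0.5) -> TTestResult:
    """t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, two-sided p."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0 for a defined t statistic")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p_value=float(p))


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Independent two-sample t from group summaries.

    ``pooled`` is the classical equal-variance test with df = n1 + n2 - 2
    (the convention implied by a reported df of n1+n2-2); ``welch`` uses
    the Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TTestResult(t=0.0, df=n1 + n2 - 2, p_value=1.0, degenerate=True)
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df: float = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_value=float(p))


def partial_correlation(x, y, z) -> tuple[float, int]:
    """Correlation of x and y after partialling the covariate z out of both.

    Computed from residuals of the least-squares regressions of x and y
    on z; equal to the closed form
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).  Returns
    (r, df) with df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"{name} is constant")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, n - 3
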
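"""Fold-level statistics: descriptives, Student-t confidence intervals, and
the paired t-test comparing mean pseudo-Dice with final-epoch pseudo-Dice.

Conventions (chosen so that the statistics are the standard small-sample
ones for k-fold scores): sample standard deviation (divisor n-1) throughout;
95% confidence intervals use the Student-t critical value with n-1 degrees
of freedom, mean ± t(0.975, n-1) · sd/√n, not the normal approximation;
p-values are two-sided. Report tables round half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, ZeroVarianceError

__all__ = [
    "StatReport",
    "FoldSummary",
    "PairedTResult",
    "describe",
    "ci95",
    "paired_t",
    "round_half_up",
]


@dataclass(frozen=True)
class FoldSummary:
    """One cross-validation fold's two headline scores."""

    fold_id: int
    mean_pds: float
    pds_at_final: float


@dataclass(frozen=True)
class StatReport:
    """Descriptive statistics of a score sequence (sample sd, divisor n-1)."""

    mean: float
    sd: float
    median: float
    ci95: tuple[float, float] | None
    n: int

    def to_text(self, label: str = "scores", decimals: int = 2) -> str:
        r = lambda x: round_half_up(x, decimals)
        lines = [
            f"{label}: n={self.n}, mean {r(self.mean)}, sd {r(self.sd)}, median {r(self.median)}"
        ]
        if self.ci95 is not None:
            lines.append(f"  95% CI ({r(self.ci95[0])}, {r(self.ci95[1])})")
        return "\n".join(lines)


class PairedTResult(NamedTuple):
    t_statistic: float
    p_value: float
    df: int


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, the convention of the report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _values(values, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError("values contain non-finite entries")
    return arr


def _sample_sd(arr: np.ndarray) -> float:
    """Sample sd (divisor n-1), snapped to exactly 0 when the spread is pure
    floating-point jitter (below 1e-12 of the data scale)."""
    sd = float(arr.std(ddof=1))
    if sd <= 1e-12 * max(float(np.abs(arr).max()), 1.0):
        return 0.0
    return sd


def ci95(values) -> tuple[float, float]:
    """mean ± t(0.975, n-1) · sd/√n with the Student-t critical value."""
    arr = _values(values)
    sd = _sample_sd(arr)
    if sd == 0:
        raise ZeroVarianceError("confidence interval degenerate: zero sample variance")
    half = sps.t.ppf(0.975, arr.size - 1) * sd / np.sqrt(arr.size)
    mean = arr.mean()
    return (float(mean - half), float(mean + half))


def describe(values) -> StatReport:
    """Mean, sample sd, median, n, plus the 95% t-interval when sd > 0."""
    arr = _values(values)
    sd = _sample_sd(arr)
    interval = ci95(arr) if sd > 0 else None
    return StatReport(
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        ci95=interval,
        n=int(arr.size),
    )


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test on matched score sequences.

    t = mean(d) / (sd(d)/√n) with d = x - y and sample sd; df = n-1.
    Raises :class:`ZeroVarianceError` when all differences are identical
    (up to floating-point jitter at 1e-12 of the data scale, so that a
    mathematically constant trace does not yield a spurious t).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"paired sequences differ in length: {x.size} vs {y.size}")
    _values(x)
    d = x - y
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if d.std(ddof=1) <= 1e-12 * scale:
        raise ZeroVarianceError("paired t-test degenerate: all differences identical")
    res = sps.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), float(res.pvalue), int(x.size - 1))
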
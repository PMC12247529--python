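"""Overlap metrics: Dice, pseudo-Dice, and trace summaries.

Let A be the predicted lesion voxel set and B the ground truth. The Dice
similarity coefficient is

    DSC = 2|A ∩ B| / (|A| + |B|),

undefined when both masks are empty. For very small or empty lesions the
pseudo-Dice score (PDS) stabilizes the ratio with a small ε. Two placements
of ε are implemented:

``as_printed`` (default)
    PDS = 2(|A ∩ B| + ε) / (|A| + |B| + ε).
    Note this is *not* bounded by 1: it equals 2 for two empty masks and
    slightly exceeds 1 at perfect overlap; its supremum is 2. It is kept as
    the default because it is the variant this evaluation protocol defines.
``standard_smooth``
    PDS = (2|A ∩ B| + ε) / (|A| + |B| + ε), the conventional smoothed Dice,
    bounded in [0, 1] and equal to 1 for two empty masks.

Both variants converge to DSC as ε → 0 whenever |A| + |B| > 0.

A :class:`ScoreTrace` is an ordered sequence of per-epoch (or per-sample)
PDS values; ``mean_pds`` averages it and ``moving_average_pds`` gives the
window-w trailing mean at epoch t, used to monitor training stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError
from .io import LesionMask

__all__ = [
    "MetricConfig",
    "ScoreTrace",
    "dice",
    "pseudo_dice",
    "mean_pds",
    "moving_average_pds",
]


@dataclass
class MetricConfig:
    """ε, ε-placement variant, and the moving-average window."""

    epsilon: float = 1e-5
    pds_variant: str = "as_printed"  # as_printed | standard_smooth
    window: int = 10

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.pds_variant not in ("as_printed", "standard_smooth"):
            raise ValueError(f"unknown pds_variant {self.pds_variant!r}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")


@dataclass
class ScoreTrace:
    """Ordered per-epoch (or per-sample) pseudo-Dice values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace must be a non-empty 1-D sequence")
        if not np.isfinite(self.values).all():
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def _as_binary(x) -> np.ndarray:
    data = x.data if isinstance(x, LesionMask) else np.asarray(x)
    return data.astype(bool)


def _counts(a, b) -> tuple[int, int, int]:
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return (
        int(np.count_nonzero(a & b)),
        int(np.count_nonzero(a)),
        int(np.count_nonzero(b)),
    )


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) in [0, 1].

    Raises :class:`UndefinedMetricError` when both masks are empty.
    """
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks (0/0)")
    return 2.0 * inter / (na + nb)


def pseudo_dice(a, b, cfg: MetricConfig | None = None) -> float:
    """ε-stabilized Dice; total (defined for empty masks). See module docs."""
    cfg = cfg or MetricConfig()
    inter, na, nb = _counts(a, b)
    eps = cfg.epsilon
    if cfg.pds_variant == "as_printed":
        return 2.0 * (inter + eps) / (na + nb + eps)
    return (2.0 * inter + eps) / (na + nb + eps)


def _trace_values(trace) -> np.ndarray:
    values = trace.values if isinstance(trace, ScoreTrace) else np.asarray(trace, dtype=float)
    if values.size == 0:
        raise ValueError("empty score trace")
    return values


def mean_pds(trace) -> float:
    """Arithmetic mean of a score trace."""
    return float(_trace_values(trace).mean())


def moving_average_pds(trace, w: int, t: int) -> float:
    """Trailing mean of the w most recent values at (1-based) epoch t.

    Equals ``mean(values[t-w+1 .. t])`` inclusive; requires 1 <= w <= t.
    """
    values = _trace_values(trace)
    if t > values.size:
        raise IndexError(f"epoch t={t} beyond trace length {values.size}")
    if w < 1 or t < 1 or w > t:
        raise ValueError(f"need 1 <= w <= t, got w={w}, t={t}")
    return float(values[t - w : t].mean())
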
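"""Pooled Pearson correlation and Bland-Altman limits of agreement.

All subject curves for a condition pair are pooled over subjects, cycle
nodes and anatomical directions into two aligned vectors (for a full
16-subject cohort: 16 x 101 x 3 = 4848 paired points).  Agreement is
computed on accelerations in physical units (m/s^2); no outlier removal is
performed.  Limits of agreement are ``bias +/- 1.96 * SD`` of the paired
differences (sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cycles import NormalizedCycleSet
from .errors import DataError, StatisticError

__all__ = [
    "PooledPairs",
    "BlandAltmanResult",
    "pool_points",
    "pearson",
    "bland_altman",
    "LOA_FACTOR",
]

#: the conventional 95 % limits-of-agreement multiplier
LOA_FACTOR = 1.96


@dataclass
class PooledPairs:
    a: np.ndarray
    b: np.ndarray
    pair_label: tuple[str, str]
    direction_labels: np.ndarray = field(default=None)  # per-point direction, for plotting

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.a.shape != self.b.shape:
            raise DataError(f"pooled vectors differ in length: {self.a.size} vs {self.b.size}")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class BlandAltmanResult:
    bias: float          # mean of a - b, m/s^2
    sd: float            # sample SD of the differences
    loa_lower: float     # bias - 1.96 sd
    loa_upper: float     # bias + 1.96 sd
    n: int
    means: np.ndarray = field(repr=False, default=None)        # (a+b)/2 per point
    differences: np.ndarray = field(repr=False, default=None)  # a-b per point


def pool_points(
    cycles: NormalizedCycleSet,
    conditions: tuple[str, str],
    direction: str | None = None,
) -> PooledPairs:
    """Flatten a condition pair into aligned vectors over subjects x nodes x directions.

    ``direction`` restricts the pooling to a single anatomical direction
    (used for the per-direction breakdowns); the default pools all three.
    """
    for cond in conditions:
        if cond not in cycles.conditions:
            raise DataError(f"condition {cond!r} not present in cycle set {cycles.conditions}")
    a3 = cycles.condition(conditions[0])  # (S, nodes, 3)
    b3 = cycles.condition(conditions[1])
    if direction is not None:
        d = cycles.directions.index(direction)
        a3, b3 = a3[..., d : d + 1], b3[..., d : d + 1]
        dirs = np.full(a3.size, direction, dtype=object)
    else:
        dirs = np.broadcast_to(np.asarray(cycles.directions, dtype=object), a3.shape).ravel()
    return PooledPairs(a=a3.ravel(), b=b3.ravel(), pair_label=conditions,
                       direction_labels=np.asarray(dirs))


def pearson(pairs: PooledPairs) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform (n-2 dof)."""
    if pairs.n < 3:
        raise StatisticError(f"need n >= 3 for a correlation, got {pairs.n}")
    if np.std(pairs.a) == 0.0 or np.std(pairs.b) == 0.0:
        raise StatisticError("zero variance in a pooled vector")
    r, p = stats.pearsonr(pairs.a, pairs.b)
    return float(r), float(p)


def bland_altman(pairs: PooledPairs) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, SD of differences, and 95 % limits."""
    if pairs.n < 2:
        raise StatisticError(f"need n >= 2 for limits of agreement, got {pairs.n}")
    diff = pairs.a - pairs.b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - LOA_FACTOR * sd,
        loa_upper=bias + LOA_FACTOR * sd,
        n=pairs.n,
        means=0.5 * (pairs.a + pairs.b),
        differences=diff,
    )
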
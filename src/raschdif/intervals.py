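"""Class intervals: bins of persons with adjacent latent-trait estimates.

Fit statistics and the residual ANOVA compare groups of persons at similar
locations; intervals are formed at empirical quantiles of the non-extreme
person estimates so counts are near-equal, then adjacent under-filled
intervals are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .estimation import PersonEstimate

logger = logging.getLogger(__name__)

__all__ = ["ClassIntervalAssignment", "assign_class_intervals"]


class IntervalError(ValueError):
    pass


@dataclass
class ClassIntervalAssignment:
    """Interval index per person (-1 for extreme/excluded persons)."""

    n_intervals: int
    index: np.ndarray  # per person, aligned with the estimates passed in
    boundaries: np.ndarray  # inner boundaries in logits, length n_intervals-1
    counts: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.counts) == self.n_intervals


def assign_class_intervals(
    persons: list[PersonEstimate], n_intervals: int = 10, min_size: int = 30
) -> ClassIntervalAssignment:
    """Bin non-extreme persons into ``n_intervals`` quantile-based intervals.

    Persons tied at a boundary value always share an interval; intervals
    falling below ``min_size`` are merged with their smaller neighbour.  If
    all estimates coincide a single interval results, with a warning.
    """
    eligible = np.array(
        [not (e.extreme or e.excluded) for e in persons], dtype=bool
    )
    betas = np.array([e.beta if ok else np.nan for e, ok in zip(persons, eligible)])
    n_ok = int(eligible.sum())
    if n_intervals < 1:
        raise IntervalError("n_intervals must be >= 1")
    if n_ok < n_intervals * min_size:
        raise IntervalError(
            f"{n_ok} usable persons cannot fill {n_intervals} intervals "
            f"of >= {min_size}"
        )
    b = betas[eligible]
    edges = np.unique(np.quantile(b, np.arange(1, n_intervals) / n_intervals))
    idx_ok = np.searchsorted(edges, b, side="left")
    # renumber to contiguous non-empty bins
    nonempty, idx_ok = np.unique(idx_ok, return_inverse=True)
    counts = np.bincount(idx_ok)
    # merge under-filled intervals into the smaller adjacent neighbour
    while len(counts) > 1 and counts.min() < min_size:
        c = int(np.argmin(counts))
        if c == 0:
            nb = 1
        elif c == len(counts) - 1:
            nb = c - 1
        else:
            nb = c - 1 if counts[c - 1] <= counts[c + 1] else c + 1
        lo, hi = min(c, nb), max(c, nb)
        idx_ok = np.where(idx_ok == hi, lo, np.where(idx_ok > hi, idx_ok - 1, idx_ok))
        counts = np.bincount(idx_ok)
        logger.info("merged class interval %d into %d (size below %d)", c, nb, min_size)
    k = len(counts)
    if k == 1 and n_intervals > 1:
        logger.warning("degenerate person estimates: single class interval")
    # boundaries: midpoint between adjacent intervals' extreme betas
    bounds = []
    for c in range(k - 1):
        bounds.append((b[idx_ok == c].max() + b[idx_ok == c + 1].min()) / 2)
    index = np.full(len(persons), -1, dtype=int)
    index[eligible] = idx_ok
    return ClassIntervalAssignment(k, index, np.array(bounds), counts)
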
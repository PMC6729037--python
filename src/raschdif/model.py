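"""Polytomous Rasch (partial credit) model primitives.

The model gives the probability that person ``v`` with latent location
``beta`` responds in category ``x`` of item ``i`` with location ``delta``
and thresholds ``tau_1 .. tau_m``:

    Pr{X = x} = exp(-tau_1 - ... - tau_x + x*(beta - delta)) / gamma

where ``gamma`` normalises over x = 0..m and the empty threshold sum applies
for x = 0.  Thresholds are the points on the latent continuum where two
adjacent categories are equally probable; they are kept centred per item
(sum(tau) == 0) so that ``delta`` is the mean of the absolute threshold
locations ``delta + tau_x``.

Internally a higher category score always means more frequent problems;
any "higher = better health" orientation is applied only at the reporting
stage, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ItemParameters",
    "category_probabilities",
    "expected_value",
    "response_variance",
    "threshold_points",
]

_TAU_CENTER_TOL = 1e-8


class InvalidParameterError(ValueError):
    """Raised when item or person parameters are malformed or non-finite."""


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of one partial-credit item.

    Parameters
    ----------
    item_id : str
        Identifier; resolved (group-specific) copies carry a suffixed id.
    delta : float
        Item location in logits.
    tau : tuple of float
        ``m`` centred threshold offsets (sum to zero) in logits.
    group_tag : str or None
        Group label for a resolved item; ``None`` for a common item.
    """

    item_id: str
    delta: float
    tau: tuple[float, ...]
    group_tag: str | None = None

    def __post_init__(self) -> None:
        tau = tuple(float(t) for t in self.tau)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "delta", float(self.delta))
        if len(tau) < 1:
            raise InvalidParameterError(
                f"item {self.item_id!r}: needs at least one threshold (m >= 1)"
            )
        if not np.isfinite(self.delta) or not np.all(np.isfinite(tau)):
            raise InvalidParameterError(
                f"item {self.item_id!r}: non-finite delta or tau"
            )
        if abs(sum(tau)) > _TAU_CENTER_TOL * max(1.0, max(abs(t) for t in tau)):
            raise InvalidParameterError(
                f"item {self.item_id!r}: thresholds must be centred "
                f"(sum(tau) = {sum(tau):.3g})"
            )

    @property
    def m(self) -> int:
        """Maximum category score (number of thresholds)."""
        return len(self.tau)

    @property
    def cumulative_tau(self) -> np.ndarray:
        """``[0, tau_1, tau_1+tau_2, ...]`` — length m+1."""
        return np.concatenate([[0.0], np.cumsum(self.tau)])

    @property
    def threshold_locations(self) -> np.ndarray:
        """Absolute threshold locations ``delta + tau_x``."""
        return self.delta + np.asarray(self.tau)

    @classmethod
    def from_thresholds(
        cls, item_id: str, thresholds, group_tag: str | None = None
    ) -> "ItemParameters":
        """Build from absolute threshold locations ``delta + tau_x``."""
        thr = np.asarray(thresholds, dtype=float)
        delta = float(thr.mean())
        return cls(item_id, delta, tuple(thr - delta), group_tag=group_tag)


def _check_beta(beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise InvalidParameterError("person location beta must be finite")
    return beta


def category_logits(beta, item: ItemParameters) -> np.ndarray:
    """Unnormalised log-probabilities, shape ``beta.shape + (m+1,)``."""
    beta = _check_beta(beta)
    x = np.arange(item.m + 1)
    return -item.cumulative_tau + np.multiply.outer(beta - item.delta, x)


def category_probabilities(beta, item: ItemParameters) -> np.ndarray:
    """Category probability distribution(s) at person location(s) ``beta``.

    Returns an array of shape ``beta.shape + (m+1,)`` summing to one over
    the last axis.  Computed via log-sum-exp so large ``|beta - delta|``
    cannot overflow.
    """
    logits = category_logits(beta, item)
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


def expected_value(beta, item: ItemParameters) -> np.ndarray | float:
    """Model-expected item score ``sum x * P(x)``; the expected value curve."""
    p = category_probabilities(beta, item)
    return p @ np.arange(item.m + 1.0)


def response_variance(beta, item: ItemParameters) -> np.ndarray | float:
    """Variance of the item score; also the slope dE/dbeta of the EVC."""
    p = category_probabilities(beta, item)
    x = np.arange(item.m + 1.0)
    ex = p @ x
    return p @ (x**2) - ex**2


def threshold_points(item: ItemParameters) -> np.ndarray:
    """Absolute threshold locations ``delta + tau_x`` for x = 1..m.

    At each returned point the two adjacent categories are equally probable.
    The points are returned in threshold order, not sorted: a non-increasing
    sequence signals disordered thresholds (see diagnostics).
    """
    return item.delta + np.asarray(item.tau)
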
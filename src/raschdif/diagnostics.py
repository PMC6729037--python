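"""Scale-level diagnostics: threshold ordering, category collapsing,
item-fit chi-square, and expected value curve (EVC) data.

Disordered thresholds — absolute threshold locations that are not strictly
increasing — indicate response categories that do not work as intended; the
remedy examined here is collapsing adjacent categories.  Item fit is
assessed by a chi-square over class intervals comparing observed and
model-expected interval score totals, optionally rescaled to a notional
sample size so fit statistics remain comparable across analyses of
different sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditional import conditional_moments
from .data import ItemSpec, ResponseMatrix
from .estimation import PersonEstimate
from .intervals import ClassIntervalAssignment
from .model import ItemParameters, expected_value, response_variance, threshold_points

logger = logging.getLogger(__name__)

__all__ = [
    "CollapseMap",
    "ThresholdReport",
    "ItemFitReport",
    "EVCData",
    "check_threshold_ordering",
    "suggest_collapse",
    "collapse_categories",
    "item_fit_chisquare",
    "evc_data",
]


class InvalidMapError(ValueError):
    pass


@dataclass(frozen=True)
class CollapseMap:
    """Order-preserving surjection of categories ``0..m`` onto ``0..m'``."""

    item_id: str
    mapping: tuple[int, ...]

    def __post_init__(self) -> None:
        mp = tuple(int(v) for v in self.mapping)
        object.__setattr__(self, "mapping", mp)
        if len(mp) < 2:
            raise InvalidMapError(f"{self.item_id}: mapping needs >= 2 categories")
        if mp[0] != 0:
            raise InvalidMapError(f"{self.item_id}: mapping must start at 0")
        diffs = np.diff(mp)
        if np.any(diffs < 0):
            raise InvalidMapError(f"{self.item_id}: mapping must be monotone")
        if np.any(diffs > 1):
            raise InvalidMapError(f"{self.item_id}: mapping image has gaps")

    @property
    def new_m(self) -> int:
        return int(self.mapping[-1])


@dataclass(frozen=True)
class ThresholdReport:
    item_id: str
    ordered: bool
    thresholds: tuple[float, ...]  # absolute locations, threshold order


def check_threshold_ordering(items: list[ItemParameters]) -> list[ThresholdReport]:
    """Flag items whose thresholds are not strictly increasing.

    Tied thresholds count as disordered: equality already signals that a
    category is never the most probable response anywhere on the continuum.
    """
    out = []
    for it in items:
        pts = threshold_points(it)
        ordered = bool(np.all(np.diff(pts) > 0)) if it.m > 1 else True
        out.append(ThresholdReport(it.item_id, ordered, tuple(pts)))
    return out


def suggest_collapse(items: list[ItemParameters]) -> list[CollapseMap]:
    """Propose merges of adjacent categories at disordered thresholds.

    Suggest-only: the caller confirms the maps before applying them (the
    merge choice should rest on inspection of the threshold locations).
    For each item, every threshold not exceeding its predecessor merges the
    category above it into the category below.
    """
    maps = []
    for rep in check_threshold_ordering(items):
        if rep.ordered:
            continue
        pts = rep.thresholds
        mapping = [0]
        for x in range(1, len(pts) + 1):
            step = 1 if x == 1 or pts[x - 1] > pts[x - 2] else 0
            mapping.append(mapping[-1] + step)
        maps.append(CollapseMap(rep.item_id, tuple(mapping)))
    return maps


def collapse_categories(
    data: ResponseMatrix, maps: list[CollapseMap]
) -> ResponseMatrix:
    """Recode categories per item; missingness and other items untouched."""
    by_item = {}
    for cm in maps:
        if cm.item_id in by_item:
            raise InvalidMapError(f"duplicate collapse map for {cm.item_id!r}")
        by_item[cm.item_id] = cm
    unknown = set(by_item) - set(data.item_ids)
    if unknown:
        raise InvalidMapError(f"collapse maps for unknown items: {sorted(unknown)}")
    responses = data.responses.copy()
    items = []
    for j, spec in enumerate(data.items):
        cm = by_item.get(spec.item_id)
        if cm is None:
            items.append(spec)
            continue
        if len(cm.mapping) != spec.m + 1:
            raise InvalidMapError(
                f"{spec.item_id!r}: map covers {len(cm.mapping) - 1} categories, "
                f"item has {spec.m}"
            )
        lut = np.asarray(cm.mapping, dtype=np.int16)
        obs = data.observed[:, j]
        responses[obs, j] = lut[responses[obs, j]]
        items.append(ItemSpec(spec.item_id, cm.new_m, spec.group_tag))
    return ResponseMatrix(
        responses,
        data.observed.copy(),
        data.structural.copy(),
        items,
        data.group.copy(),
        data.person_id.copy(),
    )


# ---------------------------------------------------------------------------
# item fit
# ---------------------------------------------------------------------------


@dataclass
class ItemFitReport:
    """Per-item chi-square fit over class-interval (x group) cells.

    The overall probability combines the per-item p-values by Fisher's
    method (recorded in ``note``); ``adjusted_n`` rescales each item's
    chi-square by ``adjusted_n / n_used`` before the p-value.
    """

    table: pd.DataFrame  # columns: item_id, chisq, df, p, n_used
    overall_p: float
    adjusted_n: int | None
    note: str = "overall p: Fisher combination of per-item p-values"


def item_fit_chisquare(
    data: ResponseMatrix,
    items: list[ItemParameters],
    persons: list[PersonEstimate],
    intervals: ClassIntervalAssignment,
    adjusted_n: int | None = None,
    groups: np.ndarray | None = None,
    min_cell: int = 10,
) -> ItemFitReport:
    """Chi-square of cell residual totals against the conditional model.

    Observed responses are compared with their *conditional* expectation
    given each person's total score — an exact benchmark under the model,
    free of person-estimation bias — so ``z = sum(x - E_cond) /
    sqrt(sum V_cond)`` is asymptotically standard normal per cell.  Cells
    are class intervals, split further by ``groups`` when given; the group
    split makes between-group item misfit (DIF) visible that pooling would
    cancel.  ``chisq = sum z^2`` on ``n_cells - 1`` degrees of freedom.
    Cells with fewer than ``min_cell`` responses merge with a neighbouring
    interval (logged).
    """
    idx = intervals.index
    usable = idx >= 0
    E, V = conditional_moments(data, items)

    if groups is None:
        gcodes = np.zeros(data.n_persons, dtype=int)
        n_groups = 1
    else:
        gcodes, levels = pd.factorize(np.asarray(groups))
        n_groups = len(levels)

    rows = []
    for j, spec in enumerate(data.items):
        mask = usable & data.observed[:, j] & ~np.isnan(E[:, j])
        if not mask.any():
            continue
        ci = idx[mask]
        gi = gcodes[mask]
        resid = data.responses[mask, j] - E[mask, j]
        w = V[mask, j]
        shape = (n_groups, intervals.n_intervals)
        nc = np.zeros(shape)
        num = np.zeros(shape)
        den = np.zeros(shape)
        np.add.at(nc, (gi, ci), 1.0)
        np.add.at(num, (gi, ci), resid)
        np.add.at(den, (gi, ci), w)
        # merge sparse interval columns (per group row) into the left one
        c = shape[1] - 1
        while nc.shape[1] > 1 and c >= 0:
            present = nc[:, c] > 0
            if np.any(nc[present, c] < min_cell):
                tgt = c - 1 if c > 0 else 1
                nc[:, tgt] += nc[:, c]
                num[:, tgt] += num[:, c]
                den[:, tgt] += den[:, c]
                nc = np.delete(nc, c, axis=1)
                num = np.delete(num, c, axis=1)
                den = np.delete(den, c, axis=1)
                logger.info("item %s: merged sparse fit interval", spec.item_id)
            c -= 1
        cell = (nc > 0) & (den > 0)
        z = num[cell] / np.sqrt(den[cell])
        chisq = float(np.sum(z**2))
        df = max(int(cell.sum()) - 1, 1)
        n_used = int(mask.sum())
        scale = (adjusted_n / n_used) if adjusted_n else 1.0
        p = float(stats.chi2.sf(scale * chisq, df))
        rows.append((spec.item_id, chisq, df, p, n_used))
    table = pd.DataFrame(rows, columns=["item_id", "chisq", "df", "p", "n_used"])
    p_clip = np.clip(table["p"].to_numpy(), 1e-300, 1.0)
    fisher = -2.0 * np.log(p_clip).sum()
    overall = float(stats.chi2.sf(fisher, 2 * len(p_clip)))
    return ItemFitReport(table, overall, adjusted_n)


# ---------------------------------------------------------------------------
# expected value curves
# ---------------------------------------------------------------------------


@dataclass
class EVCData:
    """Model EVC on a beta grid plus observed group x interval means."""

    item_id: str
    grid: np.ndarray
    expected: np.ndarray
    observed: pd.DataFrame  # columns: group, interval, mean_beta, mean_score, count


def evc_data(
    data: ResponseMatrix,
    item: ItemParameters,
    persons: list[PersonEstimate],
    intervals: ClassIntervalAssignment,
    n_grid: int = 101,
) -> EVCData:
    j = data.item_index(item.item_id)
    idx = intervals.index
    betas = np.array([p.beta for p in persons])
    mask = (idx >= 0) & data.observed[:, j]
    lo = betas[mask].min() - 1.0
    hi = betas[mask].max() + 1.0
    grid = np.linspace(lo, hi, n_grid)
    curve = np.asarray(expected_value(grid, item))
    rows = []
    for g in data.groups:
        for c in range(intervals.n_intervals):
            cell = mask & (data.group == g) & (idx == c)
            if not cell.any():
                continue
            rows.append(
                (
                    g,
                    c,
                    float(betas[cell].mean()),
                    float(data.responses[cell, j].mean()),
                    int(cell.sum()),
                )
            )
    obs = pd.DataFrame(
        rows, columns=["group", "interval", "mean_beta", "mean_score", "count"]
    )
    return EVCData(item.item_id, grid, curve, obs)
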
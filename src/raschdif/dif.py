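"""Differential item functioning: detection, resolution, quantification.

Detection is a two-way fixed-effects analysis of variance of the
standardized response residuals on group, class interval, and their
interaction, run item by item.  A significant group main effect indicates
uniform DIF (a constant group offset along the trait); a significant
group x interval interaction indicates non-uniform DIF.

Because the residual constraints of the procedure let real DIF favouring
one group in one item induce compensating (artificial) DIF in the other
items, significant items are dealt with *sequentially*: the item with the
largest F is taken as real DIF, resolved into group-specific items
(responses of all other groups become structurally missing), the model is
refitted, and the ANOVA repeated until nothing is significant.  Resolving a
real DIF item moves the group person-mean difference; resolving an
artificial one does not — which is how the two are told apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ItemSpec, ResponseMatrix
from .diagnostics import item_fit_chisquare
from .estimation import (
    EstimationSettings,
    PersonEstimate,
    fit_items,
    estimate_persons,
    person_separation_index,
)
from .intervals import ClassIntervalAssignment, assign_class_intervals
from .model import ItemParameters, expected_value, response_variance

logger = logging.getLogger(__name__)

__all__ = [
    "DIFSettings",
    "DIFTable",
    "TraceState",
    "ResolutionStep",
    "ResolutionTrace",
    "ResolvedItemComparison",
    "GroupComparisonReport",
    "assign_class_intervals",
    "subsample_equal_groups",
    "standardized_residuals",
    "two_way_anova",
    "dif_anova",
    "rank_dif",
    "resolve_item",
    "sequential_resolution",
    "quantify_resolved_item",
    "group_comparison",
    "comparison_from_means",
]


class DIFError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------


def subsample_equal_groups(
    data: ResponseMatrix, target_n: int, seed: int
) -> ResponseMatrix:
    """Draw a simple random sample of ``target_n`` persons from every group.

    Mirrors equalising unbalanced comparison groups once, before any DIF
    analysis.  Reproducible: the same seed yields the same subsample.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for g in data.groups:
        idx = np.flatnonzero(data.group == g)
        if len(idx) < target_n:
            raise DIFError(
                f"group {g!r} has {len(idx)} persons < target {target_n}; "
                f"use target_n = {min(np.bincount(pd.factorize(data.group)[0]))} "
                "(the smallest group)"
            )
        keep.append(rng.choice(idx, size=target_n, replace=False))
    keep = np.sort(np.concatenate(keep))
    return data.take_persons(keep)


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def standardized_residuals(
    data: ResponseMatrix,
    items: list[ItemParameters],
    persons: list[PersonEstimate],
) -> np.ndarray:
    """``z = (x - E) / sqrt(V)`` per person x item; NaN where unusable.

    Extreme-score and excluded persons carry no residuals (their expected
    values are degenerate), nor do missing cells.
    """
    by_id = {it.item_id: it for it in items}
    n, k = data.responses.shape
    z = np.full((n, k), np.nan)
    betas = np.array([p.beta for p in persons])
    usable = np.array([not (p.extreme or p.excluded) for p in persons])
    for j, spec in enumerate(data.items):
        it = by_id[spec.item_id]
        mask = usable & data.observed[:, j]
        if not mask.any():
            continue
        e = expected_value(betas[mask], it)
        v = response_variance(betas[mask], it)
        ok = v > 0
        if not ok.all():
            logger.warning(
                "item %s: %d zero-variance cells dropped", spec.item_id,
                int((~ok).sum()),
            )
        vals = np.full(mask.sum(), np.nan)
        vals[ok] = (data.responses[mask, j][ok] - e[ok]) / np.sqrt(v[ok])
        z[mask, j] = vals
    return z


# ---------------------------------------------------------------------------
# two-way ANOVA (Type II sums of squares, unbalanced cells allowed)
# ---------------------------------------------------------------------------


def two_way_anova(y, fa, fb, scale: float = 1.0) -> dict:
    """Fixed-effects two-way ANOVA of ``y`` on factors ``fa`` and ``fb``.

    Type II sums of squares; effect SS are multiplied by ``scale`` before
    F and p (the residual mean square, a variance estimate, is not), which
    implements evaluation at a notional sample size ``scale * n``.
    Returns F, p and df for 'a', 'b' and 'ab'.
    """
    y = np.asarray(y, dtype=float)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    G = int(fa.max()) + 1
    C = int(fb.max()) + 1
    N = len(y)
    cell = fa * C + fb
    n_c = np.bincount(cell, minlength=G * C).astype(float)
    s_c = np.bincount(cell, weights=y, minlength=G * C)
    sq = float(y @ y)
    nonempty = n_c > 0
    rss_full = sq - float((s_c[nonempty] ** 2 / n_c[nonempty]).sum())

    def rss_oneway(f, levels):
        n_l = np.bincount(f, minlength=levels).astype(float)
        s_l = np.bincount(f, weights=y, minlength=levels)
        ok = n_l > 0
        return sq - float((s_l[ok] ** 2 / n_l[ok]).sum())

    rss_a = rss_oneway(fa, G)
    rss_b = rss_oneway(fb, C)

    # additive model: weighted LS on the non-empty cell means
    cells = np.flatnonzero(nonempty)
    ybar = s_c[cells] / n_c[cells]
    ca, cb = cells // C, cells % C
    X = np.zeros((len(cells), 1 + (G - 1) + (C - 1)))
    X[:, 0] = 1.0
    for g in range(1, G):
        X[ca == g, g] = 1.0
    for c in range(1, C):
        X[cb == c, G - 1 + c] = 1.0
    w = np.sqrt(n_c[cells])
    coef, *_ = np.linalg.lstsq(X * w[:, None], ybar * w, rcond=None)
    lack = float(((ybar - X @ coef) ** 2 * n_c[cells]).sum())
    rss_add = rss_full + lack

    ss_a = max(rss_b - rss_add, 0.0)
    ss_b = max(rss_a - rss_add, 0.0)
    ss_ab = max(rss_add - rss_full, 0.0)
    df_a, df_b = G - 1, C - 1
    df_ab = len(cells) - (G + C - 1)
    df_res = N - len(cells)
    ms_res = rss_full / df_res
    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        if df <= 0 or ms_res <= 0:
            out[f"F_{name}"], out[f"p_{name}"], out[f"df_{name}"] = np.nan, np.nan, df
            continue
        F = scale * ss / df / ms_res
        out[f"F_{name}"] = float(F)
        out[f"p_{name}"] = float(stats.f.sf(F, df, df_res))
        out[f"df_{name}"] = df
    out["df_res"] = df_res
    return out


# ---------------------------------------------------------------------------
# DIF table
# ---------------------------------------------------------------------------


@dataclass
class DIFTable:
    """Per-item F/p for group (uniform DIF), interaction (non-uniform DIF)
    and class interval main effect; only common items are tested (resolved
    copies have data from a single group)."""

    table: pd.DataFrame  # item_id, F_group, p_group, F_class, p_class,
    #                      F_interaction, p_interaction, n_used
    adjusted_n: int | None
    notes: list[str] = field(default_factory=list)

    @property
    def item_ids(self) -> list[str]:
        return list(self.table["item_id"])


def _merge_for_cells(fa, fb, n_groups, n_intervals, min_cell):
    """Merge adjacent intervals until every group x interval cell holds at
    least ``min_cell`` persons; returns recoded interval codes.

    The score lattices of different groups need not interleave evenly, so
    narrow quantile intervals can miss a group entirely; widening by merging
    restores a full two-way layout.
    """
    counts = np.zeros((n_groups, n_intervals), dtype=int)
    np.add.at(counts, (fa, fb), 1)
    blocks = [[c] for c in range(n_intervals)]
    cols = [counts[:, c].copy() for c in range(n_intervals)]
    while len(cols) > 1:
        mins = [c.min() for c in cols]
        worst = int(np.argmin(mins))
        if mins[worst] >= min_cell:
            break
        if worst == 0:
            nb = 1
        elif worst == len(cols) - 1:
            nb = worst - 1
        else:
            nb = worst - 1 if cols[worst - 1].sum() <= cols[worst + 1].sum() else worst + 1
        lo, hi = min(worst, nb), max(worst, nb)
        cols[lo] += cols[hi]
        blocks[lo].extend(blocks[hi])
        del cols[hi], blocks[hi]
    remap = np.empty(n_intervals, dtype=int)
    for new, block in enumerate(blocks):
        remap[block] = new
    return remap[fb], len(blocks), int(min(c.min() for c in cols))


def dif_anova(
    residuals: np.ndarray,
    groups: np.ndarray,
    intervals: ClassIntervalAssignment,
    adjusted_n: int | None = None,
    item_ids: list[str] | None = None,
    group_specific: list[str | None] | None = None,
    min_cell: int = 10,
) -> DIFTable:
    """Two-way residual ANOVA per item: group x class interval.

    ``residuals`` is persons x items (NaN = unusable).  The group main
    effect tests uniform DIF, the interaction non-uniform DIF.  Effect sums
    of squares are rescaled to ``adjusted_n`` observations before p-values.
    Adjacent intervals are merged until every group x interval cell holds
    ``min_cell`` persons; if a cell is still empty after merging (a group
    with no usable residuals) an error names it.
    """
    n, k = residuals.shape
    if item_ids is None:
        item_ids = [f"item_{j + 1}" for j in range(k)]
    gcodes, glevels = pd.factorize(groups)
    idx = intervals.index
    rows = []
    for j in range(k):
        if group_specific is not None and group_specific[j] is not None:
            continue  # resolved copy: single-group data, nothing to test
        mask = (idx >= 0) & ~np.isnan(residuals[:, j])
        y = residuals[mask, j]
        fa = gcodes[mask]
        fb = idx[mask]
        fb, n_iv, smallest = _merge_for_cells(
            fa, fb, len(glevels), intervals.n_intervals, min_cell
        )
        if smallest == 0:
            g = int(np.argmin(np.bincount(fa, minlength=len(glevels))))
            raise DIFError(
                f"item {item_ids[j]!r}: empty cell for group {glevels[g]!r} "
                "even after merging all intervals"
            )
        n_used = int(mask.sum())
        scale = (adjusted_n / n_used) if adjusted_n else 1.0
        res = two_way_anova(y, fa, fb, scale=scale)
        rows.append(
            (
                item_ids[j],
                res["F_a"], res["p_a"],
                res["F_b"], res["p_b"],
                res["F_ab"], res["p_ab"],
                n_used,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "item_id",
            "F_group", "p_group",
            "F_class", "p_class",
            "F_interaction", "p_interaction",
            "n_used",
        ],
    )
    return DIFTable(table, adjusted_n)


def rank_dif(
    table: DIFTable, alpha: float = 0.05, correction: str | None = "bonferroni"
) -> list[str]:
    """Significant DIF items, worst first.

    An item is significant when ``min(p_group, p_interaction)`` falls below
    ``alpha`` Bonferroni-corrected for all tests in the pass (two tests —
    uniform and non-uniform — per tested item).  Ranking is by
    ``max(F_group, F_interaction)`` descending, the F magnitude standing in
    for the magnitude of DIF; exact F ties keep item order (noted).
    """
    t = table.table
    if len(t) == 0:
        return []
    k = len(t)
    if correction == "bonferroni":
        thresh = alpha / (2 * k)
    elif correction in (None, "none"):
        thresh = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    pmin = np.minimum(t["p_group"], t["p_interaction"])
    fmax = np.maximum(t["F_group"], t["F_interaction"]).to_numpy()
    sig = np.flatnonzero(pmin.to_numpy() < thresh)
    if len(sig) == 0:
        return []
    order = sig[np.argsort(-fmax[sig], kind="stable")]
    ranked_f = fmax[order]
    if len(order) > 1 and np.any(np.diff(ranked_f) == 0):
        note = "tied F values: rank falls back to item order"
        table.notes.append(note)
        logger.info(note)
    return [t["item_id"].iloc[i] for i in order]


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------


def resolve_item(
    data: ResponseMatrix,
    item_id: str,
    grouping: np.ndarray | None = None,
    levels: list[str] | None = None,
    sep: str = "::",
) -> ResponseMatrix:
    """Split ``item_id`` into one group-specific copy per group level.

    Each person's response moves to their own group's copy; on every other
    copy the cell becomes structurally missing.  Observed responses are
    conserved.  A copy is tagged with its group and named
    ``"<item_id><sep><group>"``.
    """
    j = data.item_index(item_id)
    spec = data.items[j]
    if spec.group_tag is not None:
        raise DIFError(f"item {item_id!r} is already resolved ({spec.group_tag!r})")
    grouping = data.group if grouping is None else np.asarray(grouping, dtype=object)
    if levels is None:
        levels = list(pd.unique(grouping))
    if len(levels) < 2:
        raise DIFError("grouping must have at least two levels")
    for g in levels:
        if not np.any(grouping == g):
            raise DIFError(f"grouping level {g!r} is empty")

    others = [c for c in range(data.n_items) if c != j]
    resp = [data.responses[:, others]]
    obs = [data.observed[:, others]]
    struct = [data.structural[:, others]]
    items = [data.items[c] for c in others]
    for g in levels:
        in_g = grouping == g
        resp.append(data.responses[:, [j]])
        obs.append((data.observed[:, j] & in_g)[:, None])
        struct.append((~in_g)[:, None])
        items.append(ItemSpec(f"{item_id}{sep}{g}", spec.m, group_tag=str(g)))
    return ResponseMatrix(
        np.hstack(resp),
        np.hstack(obs),
        np.hstack(struct),
        items,
        data.group.copy(),
        data.person_id.copy(),
    )


# ---------------------------------------------------------------------------
# sequential procedure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DIFSettings:
    """Knobs of the sequential DIF procedure (defaults mirror the intended
    survey-scale analysis: 10 quantile class intervals merged below 30
    persons, alpha 0.05 Bonferroni-corrected, fit statistics evaluated at a
    notional sample size of 1500)."""

    n_intervals: int = 10
    min_interval_size: int = 30
    alpha: float = 0.05
    correction: str | None = "bonferroni"
    adjusted_n: int | None = 1500
    max_steps: int | None = None
    estimation: EstimationSettings = field(default_factory=EstimationSettings)


@dataclass
class TraceState:
    """One fitted item set within the sequential procedure."""

    label: str
    items: list[ItemParameters]
    persons: list[PersonEstimate]
    dif_table: DIFTable
    psi: float
    overall_fit_p: float
    group_means: dict[str, float]  # mean beta per group, problems orientation
    data: ResponseMatrix


@dataclass
class ResolutionStep:
    item_resolved: str
    created_items: list[str]
    state_after: TraceState


@dataclass
class ResolutionTrace:
    initial: TraceState
    steps: list[ResolutionStep]
    stopping_reason: str

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def states(self) -> list[TraceState]:
        return [self.initial] + [s.state_after for s in self.steps]

    @property
    def resolved_items(self) -> list[str]:
        return [s.item_resolved for s in self.steps]


def _evaluate_state(
    data: ResponseMatrix, label: str, settings: DIFSettings
) -> TraceState:
    items = fit_items(data, settings.estimation)
    persons = estimate_persons(data, items, settings.estimation)
    intervals = assign_class_intervals(
        persons, settings.n_intervals, settings.min_interval_size
    )
    resid = standardized_residuals(data, items, persons)
    table = dif_anova(
        resid,
        data.group,
        intervals,
        adjusted_n=settings.adjusted_n,
        item_ids=data.item_ids,
        group_specific=[s.group_tag for s in data.items],
    )
    psi = person_separation_index(persons)
    fit_rep = item_fit_chisquare(
        data, items, persons, intervals,
        adjusted_n=settings.adjusted_n, groups=data.group,
    )
    means = {}
    for g in data.groups:
        sel = [
            p.beta
            for p, in_g in zip(persons, data.group == g)
            if in_g and not p.excluded
        ]
        means[g] = float(np.mean(sel))
    return TraceState(
        label, items, persons, table, psi, fit_rep.overall_p, means, data
    )


def sequential_resolution(
    data: ResponseMatrix,
    settings: DIFSettings | None = None,
    grouping: np.ndarray | None = None,
) -> ResolutionTrace:
    """Fit — test — resolve the worst DIF item — repeat.

    Stops when no item is significant (real and artificial DIF are then
    fully separated), when ``max_steps`` is reached, or when a refit fails
    (trace truncated with the reason).
    """
    settings = settings or DIFSettings()
    max_steps = settings.max_steps
    if max_steps is None:
        max_steps = data.n_items
    state = _evaluate_state(data, "set1", settings)
    trace = ResolutionTrace(state, [], "")
    while True:
        sig = rank_dif(state.dif_table, settings.alpha, settings.correction)
        if not sig:
            trace.stopping_reason = "no significant DIF"
            break
        if len(trace.steps) >= max_steps:
            trace.stopping_reason = f"max_steps ({max_steps}) reached"
            break
        worst = sig[0]
        new_data = resolve_item(state.data, worst, grouping=grouping)
        created = [
            s.item_id
            for s in new_data.items
            if s.group_tag is not None and s.item_id == f"{worst}::{s.group_tag}"
        ]
        try:
            state = _evaluate_state(
                new_data, f"set{len(trace.steps) + 2}", settings
            )
        except Exception as exc:  # refit failure truncates the trace
            trace.stopping_reason = f"refit after resolving {worst!r} failed: {exc}"
            logger.error(trace.stopping_reason)
            break
        trace.steps.append(ResolutionStep(worst, created, state))
    return trace


# ---------------------------------------------------------------------------
# quantification and group comparison
# ---------------------------------------------------------------------------


@dataclass
class ResolvedItemComparison:
    """Group-specific parameters of one resolved item.

    ``slope`` is the derivative of the expected value curve at the group's
    item location divided by m — an EVC steepness summary, since the Rasch
    model itself carries no discrimination parameter.
    """

    item_id: str
    delta: dict[str, float]
    slope: dict[str, float]
    delta_differences: dict[tuple[str, str], float]


def quantify_resolved_item(
    state: TraceState, item_id: str, sep: str = "::"
) -> ResolvedItemComparison:
    """Compare location and EVC slope of a resolved item across its groups."""
    copies = [
        it
        for it in state.items
        if it.group_tag is not None and it.item_id == f"{item_id}{sep}{it.group_tag}"
    ]
    if not copies:
        raise DIFError(f"item {item_id!r} is not resolved in this item set")
    delta = {it.group_tag: it.delta for it in copies}
    slope = {
        it.group_tag: float(response_variance(it.delta, it)) / it.m for it in copies
    }
    groups = list(delta)
    diffs = {
        (a, b): delta[a] - delta[b]
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
    }
    return ResolvedItemComparison(item_id, delta, slope, diffs)


@dataclass
class GroupComparisonReport:
    """Group person-means per item set with differences and
    difference-in-differences, on the reporting scale (higher = better
    health, the sign-flip of the internal problems orientation)."""

    sets: list[str]
    group_means: dict[str, dict[str, float]]  # set -> group -> mean
    differences: dict[str, dict[tuple[str, str], float]]
    difference_in_differences: dict[
        tuple[str, str], dict[tuple[str, str], float]
    ]
    psi: dict[str, float]
    overall_fit_p: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per quantity, one column per set."""
        rows = {}
        groups = list(next(iter(self.group_means.values())))
        for g in groups:
            rows[g] = {s: self.group_means[s][g] for s in self.sets}
        for pair in self.differences[self.sets[0]]:
            rows[f"Difference {pair[0]}-{pair[1]}"] = {
                s: self.differences[s][pair] for s in self.sets
            }
        rows["PSI"] = self.psi
        rows["Overall item fit p"] = self.overall_fit_p
        return pd.DataFrame(rows).T[self.sets]


def comparison_from_means(
    means_by_set: dict[str, dict[str, float]],
    psi: dict[str, float] | None = None,
    fit_p: dict[str, float] | None = None,
) -> GroupComparisonReport:
    """Differences and difference-in-differences from per-set group means.

    Pure arithmetic on the supplied means (already on the reporting scale):
    ``difference(g1, g2) = mean(g1) - mean(g2)`` within a set and
    ``difference-in-difference(A, B) = difference_A - difference_B`` across
    sets, by exact subtraction.
    """
    sets = list(means_by_set)
    groups = list(next(iter(means_by_set.values())))
    pairs = [(a, groups[i + 1]) for i, a in enumerate(groups[:-1])]
    diffs = {
        s: {p: means_by_set[s][p[0]] - means_by_set[s][p[1]] for p in pairs}
        for s in sets
    }
    dind = {}
    for i, sa in enumerate(sets):
        for sb in sets[i + 1 :]:
            dind[(sa, sb)] = {p: diffs[sa][p] - diffs[sb][p] for p in pairs}
    return GroupComparisonReport(
        sets,
        means_by_set,
        diffs,
        dind,
        psi or {s: np.nan for s in sets},
        fit_p or {s: np.nan for s in sets},
    )


def group_comparison(trace: ResolutionTrace) -> GroupComparisonReport:
    """Group comparison across the item sets of a resolution trace.

    Person means are reported with the sign flipped so that higher values
    represent better health (fewer problems).
    """
    means = {
        st.label: {g: -m for g, m in st.group_means.items()}
        for st in trace.states
    }
    psi = {st.label: st.psi for st in trace.states}
    fitp = {st.label: st.overall_fit_p for st in trace.states}
    return comparison_from_means(means, psi, fitp)
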
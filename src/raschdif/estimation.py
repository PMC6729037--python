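"""Item and person parameter estimation for the partial credit model.

Items are estimated by *conditional maximum likelihood* (CML): the total
score over a person's observed items is sufficient for the person
parameter, so the likelihood of the responses conditional on that total is
free of ``beta`` and consistent for the thresholds alone.  Persons are
grouped by observation pattern; each pattern's score-generating
(elementary symmetric) coefficients are built by convolving per-item
category weights, which makes the approach equally at home with incidental
and structural missingness — a resolved item simply gives each group its
own pattern.  Extreme (zero/perfect) totals carry no conditional
information and drop out, as they must.

Persons are then estimated by maximum likelihood given the items; by
sufficiency, persons with equal totals on the same observed items receive
identical estimates.  Zero and perfect raw scores have no finite ML
estimate and are extrapolated by a configurable score adjustment (default
0.3 score points) for reporting; they are flagged ``extreme`` and excluded
from reliability and residual analyses.

Standard errors are plain inverse information; no sandwich correction is
applied, so item SEs are approximate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data import ResponseMatrix
from .model import ItemParameters, expected_value, response_variance

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationSettings",
    "PersonEstimate",
    "FitResult",
    "fit_items",
    "estimate_persons",
    "fit",
    "person_separation_index",
    "item_location_standard_errors",
]


class EstimationError(RuntimeError):
    pass


class NullCategoryError(EstimationError):
    """A category of an item was never observed; estimation is impossible."""


class DisconnectedDesignError(EstimationError):
    """No chain of shared respondents links all items."""


class UndefinedReliabilityError(EstimationError):
    pass


@dataclass(frozen=True)
class EstimationSettings:
    """Knobs for item and person estimation.

    ``max_iter``/``tol`` bound the conditional-likelihood optimiser (tol is the gradient
    infinity-norm); ``extreme_adjust`` is the score-point adjustment used to
    extrapolate person locations at zero/perfect raw scores.
    """

    max_iter: int = 500
    tol: float = 1e-8
    extreme_adjust: float = 0.3


@dataclass(frozen=True)
class PersonEstimate:
    person_id: str
    beta: float
    se: float
    extreme: bool
    total_score: int
    max_possible: int
    excluded: bool = False


@dataclass
class FitResult:
    item_parameters: list[ItemParameters]
    person_estimates: list[PersonEstimate]
    converged: bool
    iterations: int
    log_note: str = ""


# ---------------------------------------------------------------------------
# conditional maximum likelihood item estimation
# ---------------------------------------------------------------------------


def _check_categories(data: ResponseMatrix) -> None:
    for j, spec in enumerate(data.items):
        obs = data.observed[:, j]
        seen = np.zeros(spec.m + 1, dtype=bool)
        seen[np.unique(data.responses[obs, j])] = True
        if not seen.all():
            missing = int(np.argmin(seen))
            raise NullCategoryError(
                f"item {spec.item_id!r}: category {missing} never observed; "
                "collapse categories before fitting"
            )


def _check_connected(data: ResponseMatrix) -> None:
    k = data.n_items
    obs = data.observed.astype(np.int64)
    adj = obs.T @ obs  # co-observation counts
    np.fill_diagonal(adj, 0)
    n_comp, _ = connected_components(csr_matrix(adj > 0), directed=False)
    if n_comp > 1:
        raise DisconnectedDesignError(
            "item design is disconnected: no persons link all item blocks"
        )


def _conditional_stats(data: ResponseMatrix):
    """Sufficient statistics of the conditional likelihood.

    Returns ``(S, patterns)`` where ``S[j][l-1] = #{v: x_vj >= l}`` over
    persons contributing conditional information, and ``patterns`` maps an
    observation-pattern key to ``(item indices, {total: count})`` —
    extreme totals are dropped (their conditional probability is one).
    """
    n, k = data.responses.shape
    S = [np.zeros(spec.m) for spec in data.items]
    patterns: dict[bytes, tuple[np.ndarray, dict[int, int]]] = {}
    totals = np.where(data.observed, data.responses, 0).sum(axis=1)
    for v in range(n):
        key = data.observed[v].tobytes()
        if key not in patterns:
            idx = np.flatnonzero(data.observed[v])
            patterns[key] = (idx, {})
        idx, counts = patterns[key]
        if len(idx) < 2:
            continue
        r = int(totals[v])
        max_r = int(sum(data.items[j].m for j in idx))
        if r == 0 or r == max_r:
            continue
        counts[r] = counts.get(r, 0) + 1
        for j in idx:
            x = data.responses[v, j]
            if x >= 1:
                S[j][:x] += 1.0
    return S, [p for p in patterns.values() if p[1]]


def _cml_negll_grad(theta, slices, S, patterns):
    """Negative conditional log-likelihood and gradient.

    ``theta`` concatenates the absolute threshold locations of all items;
    a quadratic penalty on the overall threshold sum pins the single
    direction the conditional likelihood cannot identify (a common shift
    of every threshold).
    """
    k = len(slices)
    lam = []
    shifts = np.zeros(k)  # exact log-scaling so gamma stays in range
    for j, sl in enumerate(slices):
        eta = np.concatenate([[0.0], np.cumsum(theta[sl])])
        a = eta.min()
        shifts[j] = a
        lam.append(np.exp(-(eta - a)))
    f = float(sum(np.dot(theta[sl], S[j][: len(theta[sl])]) for j, sl in enumerate(slices)))
    grad = np.concatenate([S[j] for j in range(k)]).astype(float)
    for idx, counts in patterns:
        # score-generating coefficients excluding each item in turn
        prefix = [np.array([1.0])]
        for j in idx:
            prefix.append(np.convolve(prefix[-1], lam[j]))
        suffix = [np.array([1.0])]
        for j in idx[::-1]:
            suffix.append(np.convolve(suffix[-1], lam[j]))
        gamma = prefix[-1]
        gms = [
            np.convolve(prefix[pos], suffix[len(idx) - 1 - pos])
            for pos in range(len(idx))
        ]
        log_shift = -float(shifts[idx].sum())
        for r, n_r in counts.items():
            g_r = gamma[r]
            if not np.isfinite(g_r) or g_r <= 0:
                return np.inf, grad
            f += n_r * (np.log(g_r) + log_shift)
            for pos, j in enumerate(idx):
                gm = gms[pos]
                m_j = len(lam[j]) - 1
                xs = np.arange(max(0, r - (len(gm) - 1)), min(m_j, r) + 1)
                w = lam[j][xs] * gm[r - xs]
                w /= w.sum()
                # Pr(X_j >= l | r): tail sums of the conditional distribution
                tail = np.cumsum(w[::-1])[::-1]
                pr_ge = np.zeros(m_j)
                for li, l in enumerate(range(1, m_j + 1)):
                    sel = xs >= l
                    pr_ge[li] = tail[np.argmax(sel)] if sel.any() else 0.0
                grad[slices[j]] -= n_r * pr_ge
    s = theta.sum()
    f += s * s
    grad += 2.0 * s
    return f, grad


def fit_items(
    data: ResponseMatrix, settings: EstimationSettings | None = None
) -> list[ItemParameters]:
    """Estimate item thresholds by conditional maximum likelihood.

    Deterministic given data and settings.  Item locations are centred to
    mean zero over the common (non-resolved) items, or over all items if
    every item is group-specific.
    """
    settings = settings or EstimationSettings()
    if data.n_items < 2:
        raise EstimationError("need at least two items")
    _check_categories(data)
    _check_connected(data)
    S, patterns = _conditional_stats(data)
    if not patterns:
        raise EstimationError("no person carries conditional information")

    slices, pos = [], 0
    for spec in data.items:
        slices.append(slice(pos, pos + spec.m))
        pos += spec.m
    theta0 = np.zeros(pos)
    res = optimize.minimize(
        _cml_negll_grad,
        theta0,
        args=(slices, S, patterns),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-15.0, 15.0)] * pos,
        options={"maxiter": settings.max_iter, "ftol": 1e-12, "gtol": settings.tol},
    )
    theta = res.x
    # centre item locations on the common items (scale anchor)
    deltas = np.array([theta[sl].mean() for sl in slices])
    anchor = [j for j, spec in enumerate(data.items) if spec.group_tag is None]
    if not anchor:
        anchor = list(range(data.n_items))
    theta = theta - deltas[anchor].mean()
    if not res.success:
        warnings.warn(
            f"conditional estimation did not fully converge: {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    items = [
        ItemParameters.from_thresholds(spec.item_id, theta[sl], group_tag=spec.group_tag)
        for spec, sl in zip(data.items, slices)
    ]
    fit_items.last_result = (bool(res.success), int(res.nit), str(res.message))
    return items


def item_location_standard_errors(
    data: ResponseMatrix, items: list[ItemParameters]
) -> dict[str, float]:
    """Approximate SEs of item locations from the conditional information.

    The Hessian of the penalised conditional log-likelihood is differenced
    numerically from the analytic gradient; the SE of an item's location is
    that of the mean of its thresholds.  No sandwich correction: treat these
    as approximate.
    """
    S, patterns = _conditional_stats(data)
    slices, pos = [], 0
    for spec in data.items:
        slices.append(slice(pos, pos + spec.m))
        pos += spec.m
    theta = np.concatenate([np.asarray(it.threshold_locations) for it in items])
    eps = 1e-5
    H = np.zeros((pos, pos))
    for a in range(pos):
        tp, tm = theta.copy(), theta.copy()
        tp[a] += eps
        tm[a] -= eps
        _, gp = _cml_negll_grad(tp, slices, S, patterns)
        _, gm = _cml_negll_grad(tm, slices, S, patterns)
        H[a] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    cov = np.linalg.pinv(H)
    out = {}
    for it, sl in zip(items, slices):
        a = np.zeros(pos)
        a[sl] = 1.0 / it.m
        out[it.item_id] = float(np.sqrt(max(a @ cov @ a, 0.0)))
    return out


# ---------------------------------------------------------------------------
# person estimation
# ---------------------------------------------------------------------------


def _solve_beta(items_subset: list[ItemParameters], target: float) -> float:
    """Root of sum_i E_i(beta) = target; E is strictly increasing."""

    def g(b):
        return sum(float(expected_value(b, it)) for it in items_subset) - target

    lo, hi = -10.0, 10.0
    while g(lo) > 0 and lo > -60:
        lo *= 2
    while g(hi) < 0 and hi < 60:
        hi *= 2
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def estimate_persons(
    data: ResponseMatrix,
    items: list[ItemParameters],
    settings: EstimationSettings | None = None,
) -> list[PersonEstimate]:
    """ML person locations given item parameters.

    Returns one estimate per data row, in row order.  Persons with no
    observed responses are flagged ``excluded`` (beta/se NaN) with a logged
    warning.  Extreme (zero or perfect) scores are extrapolated using the
    settings' score adjustment and flagged.
    """
    settings = settings or EstimationSettings()
    by_id = {it.item_id: it for it in items}
    missing = [s.item_id for s in data.items if s.item_id not in by_id]
    if missing:
        raise EstimationError(f"no parameters for items {missing}")
    cols = [by_id[s.item_id] for s in data.items]

    cache: dict[tuple, tuple[float, float]] = {}
    out = []
    obs = data.observed
    resp = data.responses
    for v in range(data.n_persons):
        ov = obs[v]
        if not ov.any():
            logger.warning("person %s has no observed responses; excluded",
                           data.person_id[v])
            out.append(
                PersonEstimate(str(data.person_id[v]), np.nan, np.nan, False, 0, 0,
                               excluded=True)
            )
            continue
        idx = np.flatnonzero(ov)
        total = int(resp[v, idx].sum())
        max_possible = int(sum(cols[j].m for j in idx))
        extreme = total == 0 or total == max_possible
        target = float(total)
        if total == 0:
            target = settings.extreme_adjust
        elif total == max_possible:
            target = max_possible - settings.extreme_adjust
        key = (idx.tobytes(), total)
        if key not in cache:
            subset = [cols[j] for j in idx]
            beta = _solve_beta(subset, target)
            info = sum(float(response_variance(beta, it)) for it in subset)
            cache[key] = (beta, 1.0 / np.sqrt(info))
        beta, se = cache[key]
        out.append(
            PersonEstimate(
                str(data.person_id[v]), beta, se, extreme, total, max_possible
            )
        )
    return out


def fit(
    data: ResponseMatrix, settings: EstimationSettings | None = None
) -> FitResult:
    """Convenience wrapper: items then persons, with convergence bookkeeping."""
    settings = settings or EstimationSettings()
    items = fit_items(data, settings)
    converged, iterations, message = fit_items.last_result
    persons = estimate_persons(data, items, settings)
    return FitResult(items, persons, converged, iterations, message)


def person_separation_index(estimates: list[PersonEstimate]) -> float:
    """Rasch reliability: share of observed person variance not due to error.

    ``PSI = (var(beta) - mean(se^2)) / var(beta)`` over non-extreme,
    non-excluded persons (population variance).
    """
    use = [e for e in estimates if not e.extreme and not e.excluded]
    if len(use) < 2:
        raise UndefinedReliabilityError("need >= 2 non-extreme persons")
    betas = np.array([e.beta for e in use])
    se2 = np.array([e.se**2 for e in use])
    var = float(np.var(betas))
    if var <= 0:
        raise UndefinedReliabilityError("person estimates have zero variance")
    return (var - float(se2.mean())) / var
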
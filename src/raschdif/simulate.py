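"""Synthetic ordinal questionnaire data with controllable DIF.

The generator draws person locations from group-specific normal latent
distributions and samples polytomous responses from the partial credit
model.  DIF is injected at generation time only:

* *uniform* DIF — the designated group answers the item at a shifted
  location (``delta + shift``), a constant offset along the whole trait;
* *non-uniform* DIF — the group's exponent on ``beta - delta`` is scaled by
  a discrimination multiplier, so its expected value curve crosses the
  common one.  The fitted model remains strictly Rasch; a multiplier != 1
  therefore appears as misfit concentrated in the group x interval
  interaction, exactly how non-uniform DIF presents in real data.

The presets emulate an 8-item psychosomatic symptom checklist answered by
three comparison groups (boys, girls before menarche, girls after), with
five response categories collapsible to three.  Internally higher category
scores mean more frequent problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ItemSpec, ResponseMatrix
from .diagnostics import CollapseMap

__all__ = [
    "GroupSpec",
    "ItemDesign",
    "DIFInjection",
    "SimulationDesign",
    "TruthRecord",
    "simulate",
    "hbsc_like_preset",
    "five_category_preset",
    "standard_collapse_maps",
    "HBSC_ITEMS",
]

# short names for the eight symptom-checklist complaints
HBSC_ITEMS = [
    "headache",
    "stomach_ache",
    "backache",
    "felt_low",
    "irritable",
    "nervous",
    "sleep_difficulties",
    "dizzy",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    mean: float  # latent mean, problems orientation (higher = more problems)
    sd: float = 1.0


@dataclass(frozen=True)
class ItemDesign:
    item_id: str
    delta: float
    tau: tuple[float, ...]  # centred thresholds

    @property
    def m(self) -> int:
        return len(self.tau)


@dataclass(frozen=True)
class DIFInjection:
    item_id: str
    group: str
    shift: float = 0.0  # uniform DIF: group answers at delta + shift
    discrimination: float = 1.0  # non-uniform DIF: multiplier on (beta - delta)


@dataclass
class SimulationDesign:
    groups: list[GroupSpec]
    items: list[ItemDesign]
    injections: list[DIFInjection] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.groups:
            problems.append("groups: empty")
        if len(self.items) < 2:
            problems.append("items: need at least 2")
        for g in self.groups:
            if g.n < 1:
                problems.append(f"group {g.label!r}: n < 1")
            if g.sd <= 0:
                problems.append(f"group {g.label!r}: sd <= 0")
        labels = {g.label for g in self.groups}
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            problems.append("items: duplicate ids")
        for inj in self.injections:
            if inj.item_id not in ids:
                problems.append(f"injection: unknown item {inj.item_id!r}")
            if inj.group not in labels:
                problems.append(f"injection: unknown group {inj.group!r}")
            if inj.discrimination <= 0:
                problems.append(
                    f"injection {inj.item_id!r}: discrimination <= 0"
                )
        if not 0 <= self.missing_rate < 1:
            problems.append("missing_rate: outside [0, 1)")
        if problems:
            raise DesignError("; ".join(problems))


@dataclass
class TruthRecord:
    """The design plus everything realised during generation."""

    design: SimulationDesign
    betas: np.ndarray
    group: np.ndarray
    # (group, item_id) -> dict(delta, tau, discrimination) actually generating
    generating_parameters: dict

    def to_json(self) -> str:
        payload = {
            "design": asdict(self.design),
            "betas": self.betas.tolist(),
            "group": self.group.tolist(),
            "generating_parameters": {
                f"{g}|{i}": v for (g, i), v in self.generating_parameters.items()
            },
        }
        return json.dumps(payload, indent=2)


def _category_probs(beta, delta, cumtau, disc):
    """Generator-side category probabilities (allows a discrimination)."""
    x = np.arange(len(cumtau))
    logits = -cumtau + disc * np.multiply.outer(beta - delta, x)
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


def simulate(design: SimulationDesign, seed: int | None = None):
    """Draw a response matrix (and the generating truth) from a design.

    Fully determined by the seed (``design.seed`` unless overridden):
    independent substreams drive the latent draws, the responses and the
    incidental missingness, so e.g. raising the missing rate does not
    change the underlying responses.
    """
    design.validate()
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    rng_beta, rng_resp, rng_miss = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    betas = []
    group = []
    for g in design.groups:
        betas.append(rng_beta.normal(g.mean, g.sd, size=g.n))
        group.extend([g.label] * g.n)
    betas = np.concatenate(betas)
    group = np.array(group, dtype=object)
    n = len(betas)

    inj = {(i.group, i.item_id): i for i in design.injections}
    responses = np.zeros((n, len(design.items)), dtype=np.int16)
    gen_params = {}
    for j, item in enumerate(design.items):
        cumtau = np.concatenate([[0.0], np.cumsum(item.tau)])
        u = rng_resp.random(n)
        for g in design.groups:
            inj_gi = inj.get((g.label, item.item_id))
            delta = item.delta + (inj_gi.shift if inj_gi else 0.0)
            disc = inj_gi.discrimination if inj_gi else 1.0
            gen_params[(g.label, item.item_id)] = {
                "delta": delta,
                "tau": list(item.tau),
                "discrimination": disc,
            }
            rows = group == g.label
            p = _category_probs(betas[rows], delta, cumtau, disc)
            responses[rows, j] = (p.cumsum(axis=1) < u[rows, None]).sum(axis=1)

    observed = np.ones((n, len(design.items)), dtype=bool)
    if design.missing_rate > 0:
        observed &= rng_miss.random(observed.shape) >= design.missing_rate

    items = [ItemSpec(it.item_id, it.m) for it in design.items]
    data = ResponseMatrix.from_observed(
        responses, items, group, observed=observed
    )
    return data, TruthRecord(design, betas, group, gen_params)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_DELTAS = {
    "headache": -1.0,
    "stomach_ache": 0.2,
    "backache": 1.0,
    "felt_low": -0.5,
    "irritable": -1.5,
    "nervous": -0.2,
    "sleep_difficulties": 0.5,
    "dizzy": 1.5,
}

_GROUPS = [
    # boys report the fewest problems, girls after menarche the most;
    # the gaps emulate large true group differences that persist after
    # any DIF has been taken into account
    GroupSpec("boys", 3500, -0.45, 1.0),
    GroupSpec("girls_no_period", 3500, -0.30, 1.0),
    GroupSpec("girls_period", 3500, 0.50, 1.0),
]

_INJECTIONS = [
    # two uniform DIF items of unequal magnitude for the post-menarche
    # group; negative shift = the item is endorsed more easily by that
    # group (more frequent problems) at any trait location
    DIFInjection("felt_low", "girls_period", shift=-0.8),
    DIFInjection("stomach_ache", "girls_period", shift=-0.5),
]


def hbsc_like_preset(seed: int = 0) -> SimulationDesign:
    """Eight 3-category items, three groups of 3500, two uniform DIF items.

    Emulates the collapsed symptom checklist: item locations spread over
    +/-1.5 logits, thresholds +/-0.7 around each location, and DIF of 0.8
    and 0.5 logits injected into 'felt_low' and 'stomach_ache' for the
    post-menarche group, in that magnitude order.
    """
    items = [ItemDesign(i, _DELTAS[i], (-0.7, 0.7)) for i in HBSC_ITEMS]
    return SimulationDesign(list(_GROUPS), items, list(_INJECTIONS), 0.0, seed)


def null_preset(seed: int = 0, n_per_group: int = 3500) -> SimulationDesign:
    """The same design with no DIF injected (for calibration studies)."""
    items = [ItemDesign(i, _DELTAS[i], (-0.7, 0.7)) for i in HBSC_ITEMS]
    groups = [GroupSpec(g.label, n_per_group, g.mean, g.sd) for g in _GROUPS]
    return SimulationDesign(groups, items, [], 0.0, seed)


# five-category thresholds emulating category pairs that barely separate
# (the respondents hardly distinguish within each pair); on the flagged
# items each pair is swapped outright, i.e. disordered by construction
_TAU5_ORDERED = (-0.7, -0.5, 0.5, 0.7)
_TAU5_DISORDERED = (-0.5, -0.7, 0.7, 0.5)
_DISORDERED_ITEMS = ("stomach_ache", "dizzy")


def five_category_preset(seed: int = 0) -> SimulationDesign:
    """As :func:`hbsc_like_preset` but with five response categories and
    deliberately disordered thresholds on two items, to exercise the
    collapsing workflow."""
    items = [
        ItemDesign(
            i,
            _DELTAS[i],
            _TAU5_DISORDERED if i in _DISORDERED_ITEMS else _TAU5_ORDERED,
        )
        for i in HBSC_ITEMS
    ]
    return SimulationDesign(list(_GROUPS), items, list(_INJECTIONS), 0.0, seed)


def standard_collapse_maps(item_ids=HBSC_ITEMS) -> list[CollapseMap]:
    """The standard 5-to-3 collapse: merge the two most frequent pairs.

    With category 4 = 'about every day' down to 0 = 'seldom or never', the
    pairs (4, 3) and (2, 1) merge, leaving three ordered categories.
    """
    return [CollapseMap(i, (0, 1, 1, 2, 2)) for i in item_ids]
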
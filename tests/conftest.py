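import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raschdif.data import ItemSpec, ResponseMatrix
from raschdif.estimation import PersonEstimate
from raschdif.simulate import (
    DIFInjection,
    GroupSpec,
    ItemDesign,
    SimulationDesign,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ITEM_DELTAS = {
    "headache": -1.0,
    "stomach_ache": 0.2,
    "backache": 1.0,
    "felt_low": -0.5,
    "irritable": -1.5,
    "nervous": -0.2,
    "sleep_difficulties": 0.5,
    "dizzy": 1.5,
}


def two_group_design(seed, n=1500, shift=0.0, dif_item="dizzy", disc=1.0):
    """Boys/girls design with one optionally DIF-injected item."""
    items = [ItemDesign(i, d, (-0.7, 0.7)) for i, d in ITEM_DELTAS.items()]
    groups = [GroupSpec("boys", n, -0.2), GroupSpec("girls", n, 0.2)]
    injections = []
    if shift != 0.0 or disc != 1.0:
        injections = [DIFInjection(dif_item, "girls", shift=shift, discrimination=disc)]
    return SimulationDesign(groups, items, injections, 0.0, seed)


def make_persons(betas, ses=None, extreme=None):
    """PersonEstimate list from raw arrays (for interval/PSI unit tests)."""
    betas = np.asarray(betas, dtype=float)
    ses = np.full(len(betas), 0.5) if ses is None else np.asarray(ses, dtype=float)
    extreme = np.zeros(len(betas), bool) if extreme is None else np.asarray(extreme)
    return [
        PersonEstimate(f"p{i}", float(b), float(s), bool(e), 0, 1)
        for i, (b, s, e) in enumerate(zip(betas, ses, extreme))
    ]


def tiny_matrix(X, m=1, group=None):
    """ResponseMatrix from a dense integer array, single default group."""
    X = np.asarray(X, dtype=np.int16)
    n, k = X.shape
    if group is None:
        group = np.array(["g"] * n, dtype=object)
    items = [ItemSpec(f"i{j}", m) for j in range(k)]
    return ResponseMatrix.from_observed(X, items, np.asarray(group, dtype=object))


@pytest.fixture(scope="session")
def fitted_null():
    """One medium null fit shared by diagnostics/DIF unit tests."""
    import raschdif as rd

    data, truth = rd.simulate(rd.null_preset(seed=77, n_per_group=700))
    res = rd.fit(data)
    return data, truth, res
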
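"""Residual ANOVA DIF detection, ranking, resolution, group comparison."""

import numpy as np
import pandas as pd
import pytest

import raschdif as rd
from raschdif.dif import (
    DIFError,
    DIFSettings,
    DIFTable,
    assign_class_intervals,
    comparison_from_means,
    dif_anova,
    quantify_resolved_item,
    rank_dif,
    resolve_item,
    sequential_resolution,
    standardized_residuals,
    subsample_equal_groups,
    two_way_anova,
)
from raschdif.intervals import IntervalError
from raschdif.model import ItemParameters

from conftest import make_persons, tiny_matrix, two_group_design


# -- subsampling -----------------------------------------------------------


def test_subsample_equalises_unbalanced_groups():
    from raschdif.simulate import GroupSpec, ItemDesign, SimulationDesign

    items = [ItemDesign(f"q{j}", 0.1 * j - 0.15, (-0.5, 0.5)) for j in range(4)]
    groups = [
        GroupSpec("boys", 9153, -0.4),
        GroupSpec("girls_no_period", 3676, -0.3),
        GroupSpec("girls_period", 5446, 0.4),
    ]
    data, _ = rd.simulate(SimulationDesign(groups, items, [], 0.0, 1))
    sub = subsample_equal_groups(data, 3500, seed=11)
    assert sub.n_persons == 10500
    counts = pd.Series(sub.group).value_counts()
    assert (counts == 3500).all()
    # reproducible
    again = subsample_equal_groups(data, 3500, seed=11)
    np.testing.assert_array_equal(sub.person_id, again.person_id)
    with pytest.raises(DIFError, match="smallest group"):
        subsample_equal_groups(data, 4000, seed=1)


def test_subsample_with_target_equal_to_group_size_is_identity():
    data = tiny_matrix([[0, 1]] * 6, group=["a", "a", "a", "b", "b", "b"])
    sub = subsample_equal_groups(data, 3, seed=0)
    assert sorted(sub.person_id) == sorted(data.person_id)


# -- class intervals -------------------------------------------------------


def test_intervals_near_equal_counts_on_continuous_betas():
    rng = np.random.default_rng(8)
    persons = make_persons(rng.normal(0, 1, 1000))
    iv = assign_class_intervals(persons, 10, min_size=30)
    assert iv.n_intervals == 10
    assert iv.counts.min() >= 90 and iv.counts.max() <= 110
    assert iv.counts.sum() == 1000


def test_single_interval_and_degenerate_betas():
    persons = make_persons(np.linspace(-1, 1, 50))
    iv = assign_class_intervals(persons, 1, min_size=10)
    assert iv.n_intervals == 1 and iv.counts[0] == 50
    tied = make_persons(np.zeros(100))
    iv = assign_class_intervals(tied, 10, min_size=5)
    assert iv.n_intervals == 1  # all estimates identical: one interval


def test_intervals_exclude_extremes_and_require_enough_persons():
    betas = np.linspace(-2, 2, 100)
    extreme = np.zeros(100, bool)
    extreme[:10] = True
    iv = assign_class_intervals(make_persons(betas, extreme=extreme), 3, min_size=10)
    assert (iv.index[:10] == -1).all()
    assert iv.counts.sum() == 90
    with pytest.raises(IntervalError):
        assign_class_intervals(make_persons(betas), 10, min_size=30)


# -- residuals -------------------------------------------------------------


def test_standardized_residual_values():
    item = ItemParameters("i0", 0.0, (0.0,))
    # m=1, beta=delta: E=0.5, V=0.25 -> residual of a 1 is (1-.5)/.5 = 1
    data = tiny_matrix([[1, 0], [0, 1]])
    items = [item, ItemParameters("i1", 0.0, (0.0,))]
    persons = make_persons([0.0, 0.0])
    z = standardized_residuals(data, items, persons)
    np.testing.assert_allclose(z, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)


def test_residuals_standardised_under_the_model(fitted_null):
    """Mean about zero; variance about 1 - V/I, the shrinkage induced by
    standardising against expected values at *estimated* person locations
    (a residual feeds the very estimate it is measured against)."""
    from raschdif.model import response_variance

    data, _, res = fitted_null
    z = standardized_residuals(data, res.item_parameters, res.person_estimates)
    betas = np.array([p.beta for p in res.person_estimates])
    V = np.column_stack(
        [response_variance(betas, it) for it in res.item_parameters]
    )
    info = V.sum(axis=1)
    n = data.n_persons
    for j in range(data.n_items):
        col = z[:, j]
        keep = ~np.isnan(col)
        col = col[keep]
        expected_var = float(np.mean(1.0 - V[keep, j] / info[keep]))
        assert abs(col.mean()) < 3 / np.sqrt(n)
        assert abs(col.var() - expected_var) < 5 / np.sqrt(n)


def test_residuals_missing_where_unusable():
    item = ItemParameters("i0", 0.0, (0.0,))
    data = tiny_matrix([[1], [1]])
    persons = make_persons([0.0, 3.0], extreme=[False, True])
    z = standardized_residuals(data, [item], persons)
    assert not np.isnan(z[0, 0]) and np.isnan(z[1, 0])


# -- two-way ANOVA ---------------------------------------------------------


def test_anova_matches_statsmodels_type2_unbalanced():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(12)
    n = 400
    fa = rng.integers(0, 3, n)
    fb = rng.integers(0, 4, n)
    y = rng.normal(0, 1, n) + 0.3 * fa + 0.1 * fb + 0.15 * fa * fb
    ours = two_way_anova(y, fa, fb)
    df = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    fitted = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    ref = sm.stats.anova_lm(fitted, typ=2)
    assert ours["F_a"] == pytest.approx(ref.loc["C(a)", "F"], abs=1e-10)
    assert ours["F_b"] == pytest.approx(ref.loc["C(b)", "F"], abs=1e-10)
    assert ours["F_ab"] == pytest.approx(ref.loc["C(a):C(b)", "F"], abs=1e-10)
    assert ours["p_a"] == pytest.approx(ref.loc["C(a)", "PR(>F)"], abs=1e-12)


def test_anova_balanced_table_closed_form():
    """Hand-sized balanced table: 2 groups x 2 intervals x 5 replicates,
    against the textbook balanced two-way decomposition computed inline."""
    rng = np.random.default_rng(4)
    y = rng.normal(0, 1, 20)
    fa = np.repeat([0, 1], 10)
    fb = np.tile(np.repeat([0, 1], 5), 2)
    ours = two_way_anova(y, fa, fb)
    gm = y.mean()
    ya = [y[fa == g].mean() for g in (0, 1)]
    yb = [y[fb == c].mean() for c in (0, 1)]
    ycell = {(g, c): y[(fa == g) & (fb == c)].mean() for g in (0, 1) for c in (0, 1)}
    ss_a = 10 * sum((m - gm) ** 2 for m in ya)
    ss_b = 10 * sum((m - gm) ** 2 for m in yb)
    ss_ab = 5 * sum(
        (ycell[g, c] - ya[g] - yb[c] + gm) ** 2 for g in (0, 1) for c in (0, 1)
    )
    ss_res = sum(
        ((y[(fa == g) & (fb == c)] - ycell[g, c]) ** 2).sum()
        for g in (0, 1) for c in (0, 1)
    )
    ms_res = ss_res / 16
    assert ours["F_a"] == pytest.approx(ss_a / 1 / ms_res, abs=1e-10)
    assert ours["F_b"] == pytest.approx(ss_b / 1 / ms_res, abs=1e-10)
    assert ours["F_ab"] == pytest.approx(ss_ab / 1 / ms_res, abs=1e-10)


def test_anova_scale_multiplies_f_not_p_shape():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, 200)
    fa = rng.integers(0, 2, 200)
    fb = rng.integers(0, 3, 200)
    base = two_way_anova(y, fa, fb, scale=1.0)
    half = two_way_anova(y, fa, fb, scale=0.5)
    assert half["F_a"] == pytest.approx(base["F_a"] * 0.5, rel=1e-12)
    assert half["p_a"] >= base["p_a"]


# -- DIF table and ranking -------------------------------------------------


def _residual_fixture(seed=0, n=600, k=4, n_groups=2):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, (n, k))
    groups = np.array(["g0", "g1", "g2"][:n_groups] * (n // n_groups), dtype=object)
    persons = make_persons(rng.normal(0, 1, n))
    iv = assign_class_intervals(persons, 5, min_size=20)
    return z, groups, iv


def test_constant_group_offset_dominates_f_group():
    z, groups, iv = _residual_fixture(seed=3)
    z[groups == "g1", 2] += 0.4  # uniform offset on item 3 for one group
    table = dif_anova(z, groups, iv)
    t = table.table.set_index("item_id")
    assert t["F_group"].idxmax() == "item_3"
    assert rank_dif(table)[0] == "item_3"


def test_no_signal_gives_empty_ranking():
    z, groups, iv = _residual_fixture(seed=10)
    table = dif_anova(z, groups, iv)
    assert rank_dif(table, alpha=0.01) == []


def test_tied_f_values_keep_item_order_with_note():
    t = pd.DataFrame(
        {
            "item_id": ["a", "b"],
            "F_group": [8.0, 8.0],
            "p_group": [1e-6, 1e-6],
            "F_class": [1.0, 1.0],
            "p_class": [0.5, 0.5],
            "F_interaction": [1.0, 1.0],
            "p_interaction": [0.5, 0.5],
            "n_used": [100, 100],
        }
    )
    table = DIFTable(t, None)
    assert rank_dif(table) == ["a", "b"]
    assert any("tied" in n for n in table.notes)


def test_empty_group_cell_raises_after_merging():
    z, groups, iv = _residual_fixture(seed=11)
    z[groups == "g1", 1] = np.nan  # one group contributes nothing to item 2
    with pytest.raises(DIFError, match="item_2.*g1"):
        dif_anova(z, groups, iv)


def test_injected_dif_item_ranked_first_in_power_simulation():
    hits = 0
    reps = 30
    for rep in range(reps):
        data, _ = rd.simulate(two_group_design(8000 + rep, n=1000, shift=-0.5))
        res = rd.fit(data)
        iv = assign_class_intervals(res.person_estimates)
        z = standardized_residuals(data, res.item_parameters, res.person_estimates)
        table = dif_anova(z, data.group, iv, item_ids=data.item_ids)
        ranked = rank_dif(table)
        if ranked and ranked[0] == "dizzy":
            hits += 1
    assert hits >= int(0.95 * reps)


# -- resolution ------------------------------------------------------------


def test_resolve_item_splits_and_conserves_observations(fitted_null):
    data, _, _ = fitted_null
    before = int(data.observed.sum())
    out = resolve_item(data, "felt_low")
    assert out.n_items == 10  # 7 common + 3 group-specific
    assert int(out.observed.sum()) == before
    tags = {s.group_tag for s in out.items if s.group_tag}
    assert tags == set(data.groups)
    # each copy observed only inside its group
    for s in out.items:
        if s.group_tag:
            j = out.item_index(s.item_id)
            assert not out.observed[out.group != s.group_tag, j].any()
    with pytest.raises(DIFError, match="already resolved"):
        resolve_item(out, "felt_low::boys")


def test_resolve_rejects_degenerate_grouping(fitted_null):
    data, _, _ = fitted_null
    with pytest.raises(DIFError, match="empty"):
        resolve_item(data, "dizzy", levels=["boys", "no_such_group"])
    with pytest.raises(DIFError, match="two levels"):
        resolve_item(data, "dizzy", grouping=np.array(["x"] * data.n_persons))


def test_sequential_resolution_single_dif_item():
    """One real uniform DIF item: one resolution step, then clean."""
    data, _ = rd.simulate(two_group_design(901, n=1500, shift=-0.6))
    trace = sequential_resolution(data)
    assert trace.resolved_items == ["dizzy"]
    assert trace.stopping_reason == "no significant DIF"
    assert rank_dif(trace.states[-1].dif_table) == []


def test_sequential_resolution_resolves_in_magnitude_order():
    data, _ = rd.simulate(rd.hbsc_like_preset(seed=42))
    trace = sequential_resolution(data)
    assert trace.resolved_items == ["felt_low", "stomach_ache"]
    # resolved copies never reappear in later DIF tables
    for st in trace.states[1:]:
        assert "felt_low" not in st.dif_table.item_ids


def test_max_steps_truncates_the_loop():
    data, _ = rd.simulate(rd.hbsc_like_preset(seed=42))
    trace = sequential_resolution(data, DIFSettings(max_steps=1))
    assert len(trace) == 1
    assert "max_steps" in trace.stopping_reason


# -- real vs artificial discriminator --------------------------------------


def test_resolving_real_dif_moves_group_means_null_item_does_not():
    real_shifts, null_shifts = [], []
    for rep in range(6):
        data, _ = rd.simulate(two_group_design(700 + rep, n=1500, shift=-0.6))
        settings = DIFSettings()
        from raschdif.dif import _evaluate_state

        base = _evaluate_state(data, "base", settings)
        d0 = base.group_means["boys"] - base.group_means["girls"]
        real = _evaluate_state(resolve_item(data, "dizzy"), "real", settings)
        d1 = real.group_means["boys"] - real.group_means["girls"]
        null = _evaluate_state(resolve_item(data, "backache"), "null", settings)
        d2 = null.group_means["boys"] - null.group_means["girls"]
        real_shifts.append(abs(d1 - d0))
        null_shifts.append(abs(d2 - d0))
    assert np.mean(real_shifts) > 0.05
    assert np.mean(null_shifts) < 0.02


# -- quantification --------------------------------------------------------


def test_quantify_null_resolved_item_shows_no_group_difference():
    data, _ = rd.simulate(rd.null_preset(seed=17, n_per_group=2000))
    trace_state_data = resolve_item(data, "nervous")
    items = rd.fit_items(trace_state_data)
    from raschdif.dif import TraceState

    state = TraceState("s", items, [], None, np.nan, np.nan, {}, trace_state_data)
    comp = quantify_resolved_item(state, "nervous")
    from raschdif.estimation import item_location_standard_errors

    ses = item_location_standard_errors(trace_state_data, items)
    for (a, b), diff in comp.delta_differences.items():
        joint = np.hypot(ses[f"nervous::{a}"], ses[f"nervous::{b}"])
        assert abs(diff) < 2.5 * joint


def test_quantify_nonuniform_dif_differs_in_slope_not_location():
    design = two_group_design(55, n=3000, dif_item="nervous", disc=1.6)
    data, _ = rd.simulate(design)
    resolved = resolve_item(data, "nervous")
    items = rd.fit_items(resolved)
    from raschdif.dif import TraceState

    state = TraceState("s", items, [], None, np.nan, np.nan, {}, resolved)
    comp = quantify_resolved_item(state, "nervous")
    # steeper generating curve for girls -> steeper fitted EVC summary
    assert comp.slope["girls"] > comp.slope["boys"] * 1.05
    assert abs(comp.delta["girls"] - comp.delta["boys"]) < 0.15


def test_quantify_requires_a_resolved_item(fitted_null):
    data, _, res = fitted_null
    from raschdif.dif import TraceState

    state = TraceState("s", res.item_parameters, [], None, 0.0, 0.0, {}, data)
    with pytest.raises(DIFError, match="not resolved"):
        quantify_resolved_item(state, "dizzy")


# -- group comparison arithmetic -------------------------------------------


def test_difference_in_difference_is_exact_subtraction():
    means = {
        "set1": {"A": 1.2, "B": 0.7, "C": 0.1},
        "set2": {"A": 1.1, "B": 0.75, "C": 0.2},
    }
    rep = comparison_from_means(means)
    assert rep.differences["set1"][("A", "B")] == 1.2 - 0.7
    d1 = rep.differences["set1"][("B", "C")]
    d2 = rep.differences["set2"][("B", "C")]
    assert rep.difference_in_differences[("set1", "set2")][("B", "C")] == d1 - d2


def test_identical_item_sets_give_zero_difference_in_differences():
    means = {"set1": {"A": 0.4, "B": 0.1}, "set2": {"A": 0.4, "B": 0.1}}
    rep = comparison_from_means(means)
    assert all(
        v == 0.0 for v in rep.difference_in_differences[("set1", "set2")].values()
    )
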
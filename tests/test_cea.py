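"""Incremental analysis, dominance classification and the bootstrap plane."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcua.cea import (
    ArmSummary,
    CostUtilityModel,
    bootstrap_cea,
    ce_plane_summary,
    ceac,
    icer,
    incremental,
    quadrant_of,
)
from trialcua.costing import default_cost_model


def _summary(arm, cost, q, n=10):
    return ArmSummary(arm=arm, n=n, mean_cost_naira=cost, mean_qaly=q)


def test_incremental_reproduces_published_pair():
    dc, de = incremental(_summary("TBMT", 22_200, 0.085), _summary("CBMT", 38_200, 0.084))
    assert dc == -16_000
    assert de == pytest.approx(0.001, abs=1e-12)


def test_incremental_identical_arms_is_zero():
    s = _summary("A", 1000.0, 0.05)
    assert incremental(s, s) == (0.0, 0.0)


@pytest.mark.parametrize(
    "dc, de, value, label",
    [
        (-16_000, 0.001, None, "dominant"),
        (16_000, -0.001, None, "dominated"),
        (1_000, 0.01, 100_000, "tradeoff_NE"),
        (-1_000, -0.01, 100_000, "tradeoff_SW"),
        (5_000, 0.0, None, "indeterminate"),
        (-5_000, 0.0, None, "indeterminate"),
        (0.0, 0.0, None, "indeterminate"),
        (0.0, 0.01, 0.0, "tradeoff_NE"),
        (0.0, -0.01, 0.0, "tradeoff_SW"),
    ],
)
def test_icer_classification_exhaustive(dc, de, value, label):
    res = icer(dc, de)
    assert res.label == label
    if value is None:
        assert res.value is None
    else:
        assert res.value == pytest.approx(value)


@given(dc=st.floats(-1e6, 1e6), de=st.floats(-1.0, 1.0))
@settings(derandomize=True, max_examples=200)
def test_icer_every_sign_pattern_has_an_outcome(dc, de):
    res = icer(dc, de)
    assert res.label in {"dominant", "dominated", "tradeoff_NE", "tradeoff_SW", "indeterminate"}
    assert (res.label == "dominant") == (dc < 0 and de > 0)
    assert (res.label == "dominated") == (dc > 0 and de < 0)
    assert (res.value is not None) == res.label.startswith("tradeoff")


@pytest.mark.parametrize(
    "de, dc, quadrant",
    [
        (1, 1, "NE"),
        (1, -1, "SE"),
        (-1, -1, "SW"),
        (-1, 1, "NW"),
        # axis ties: assigned to the next quadrant sweeping clockwise
        (0, 1, "NE"),
        (1, 0, "SE"),
        (0, -1, "SW"),
        (-1, 0, "NW"),
        (0, 0, "NE"),
    ],
)
def test_plane_quadrant_convention(de, dc, quadrant):
    assert quadrant_of(de, dc) == quadrant


def test_bootstrap_degenerate_cohort_collapses(degenerate_cohort):
    res = bootstrap_cea(degenerate_cohort, reps=200, seed=5)
    assert res.delta_cost == pytest.approx(-16_000)
    assert res.delta_effect == pytest.approx(0.001)
    assert res.icer.label == "dominant"
    assert res.delta_cost_ci == (pytest.approx(-16_000), pytest.approx(-16_000))
    assert res.delta_effect_ci[1] - res.delta_effect_ci[0] == pytest.approx(0.0, abs=1e-15)
    assert (res.replicates["delta_cost"] == -16_000).all()
    assert res.quadrant_proportions["SE"] == 1.0


def test_bootstrap_deterministic_for_fixed_seed(default_cohort):
    model = CostUtilityModel.from_cohort(default_cohort)
    a = model.fit(reps=300, seed=42)
    b = model.fit(reps=300, seed=42)
    pd.testing.assert_frame_equal(a.replicates, b.replicates)
    c = model.fit(reps=300, seed=43)
    assert not a.replicates.equals(c.replicates)


def test_bootstrap_replicate_means_near_point_estimates(default_cohort):
    model = CostUtilityModel.from_cohort(default_cohort)
    res = model.fit(reps=5000, seed=9)
    for col, point in (("delta_cost", res.delta_cost), ("delta_effect", res.delta_effect)):
        reps = res.replicates[col]
        mc_se = reps.std(ddof=1) / np.sqrt(len(reps))
        # protocol costs are constant within arm, so delta_cost has zero spread
        assert abs(reps.mean() - point) <= max(3 * mc_se, 1e-12)


def test_bootstrap_quadrants_sum_to_one(default_cohort):
    model = CostUtilityModel.from_cohort(default_cohort)
    res = model.fit(reps=1000, seed=2)
    assert sum(res.quadrant_proportions.values()) == pytest.approx(1.0, abs=1e-12)


def test_bootstrap_uniform_dominance_fills_one_quadrant(rng):
    # new arm cheaper and more effective for every participant
    rows = []
    for i in range(15):
        rows.append({"participant_id": f"N{i}", "arm": "TBMT", "cost_naira": 100 + rng.uniform(0, 5), "qaly": 0.09 + rng.uniform(0, 0.005)})
        rows.append({"participant_id": f"R{i}", "arm": "CBMT", "cost_naira": 500 + rng.uniform(0, 5), "qaly": 0.05 + rng.uniform(0, 0.005)})
    res = bootstrap_cea(pd.DataFrame(rows), reps=500, seed=1)
    assert res.quadrant_proportions["SE"] == 1.0
    assert res.icer.label == "dominant"


def test_bootstrap_input_validation(degenerate_cohort):
    with pytest.raises(ValueError):
        bootstrap_cea(degenerate_cohort, reps=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_cea(degenerate_cohort[degenerate_cohort["arm"] == "TBMT"], reps=10, seed=1)
    with pytest.raises(ValueError):
        bootstrap_cea(degenerate_cohort, reps=10, seed=1, ci_method="magic")


def test_cost_scaling_leaves_labels_and_quadrants_invariant(default_cohort):
    model = CostUtilityModel.from_cohort(default_cohort)
    base = model.fit(reps=400, seed=8)
    scaled_df = model.data.copy()
    scaled_df["cost_naira"] *= 3.0
    scaled = CostUtilityModel(scaled_df).fit(reps=400, seed=8)
    assert scaled.delta_cost == pytest.approx(3.0 * base.delta_cost)
    assert scaled.icer.label == base.icer.label
    assert scaled.quadrant_proportions == base.quadrant_proportions
    if base.icer.value is not None:
        assert scaled.icer.value == pytest.approx(3.0 * base.icer.value)


def test_bca_interval_runs_and_brackets_point(default_cohort):
    model = CostUtilityModel.from_cohort(default_cohort)
    res = model.fit(reps=1000, seed=4, ci_method="bca")
    lo, hi = res.delta_effect_ci
    assert lo < res.delta_effect < hi


def test_ce_plane_summary_symmetric_cloud(rng):
    reps = pd.DataFrame(
        {"delta_cost": rng.standard_normal(20_000), "delta_effect": rng.standard_normal(20_000)}
    )
    props = ce_plane_summary(reps)
    for q in ("NE", "SE", "SW", "NW"):
        assert props[q] == pytest.approx(0.25, abs=0.02)
    with pytest.raises(ValueError):
        ce_plane_summary(reps.iloc[:0])


def test_plane_plot_written(tmp_path, degenerate_cohort):
    res = bootstrap_cea(degenerate_cohort, reps=50, seed=3)
    out = tmp_path / "plane.png"
    res.plot_plane(path=out)
    assert out.exists() and out.stat().st_size > 0


def test_ceac_probabilities(degenerate_cohort):
    res = bootstrap_cea(degenerate_cohort, reps=100, seed=3)
    curve = res.ceac([0, 1_000, 1_000_000])
    # dominant cloud: cost-effective at every threshold (NMB = wtp*dE + 16,000 > 0)
    assert (curve["p_cost_effective"] == 1.0).all()


def test_summary_and_dict_report(default_cohort):
    res = CostUtilityModel.from_cohort(default_cohort).fit(reps=200, seed=6)
    text = res.summary()
    assert "Incremental cost" in text and "ICER" in text
    d = res.to_dict()
    assert d["delta_cost"] == res.delta_cost
    assert set(d["quadrant_proportions"]) == {"NE", "SE", "SW", "NW"}


def test_from_cohort_fills_protocol_costs(default_cohort):
    cohort = default_cohort.drop(columns=["cost_naira"])
    model = CostUtilityModel.from_cohort(cohort, cost_model=default_cost_model())
    costs = model.data.groupby("arm")["cost_naira"].unique()
    assert costs["TBMT"].tolist() == [22_200.0]
    assert costs["CBMT"].tolist() == [38_200.0]


def test_model_rejects_missing_columns(default_cohort):
    with pytest.raises(ValueError):
        CostUtilityModel(default_cohort.drop(columns=["cost_naira"]))
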
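"""Synthetic cohort generator: calibration, determinism, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialcua.synthetic import (
    ArmParams,
    CohortConfig,
    cohort_to_long,
    default_config,
    derive_sd_from_ci,
    generate_cohort,
    read_cohort,
    write_cohort,
)


@pytest.mark.parametrize(
    "halfwidth, n, expected",
    [
        ((18.57 - 12.85) / 2, 21, 2.86 * np.sqrt(21) / 2.0859634),  # t(0.975, 20)
        ((18.36 - 10.63) / 2, 26, 3.865 * np.sqrt(26) / 2.0595386),  # t(0.975, 25)
    ],
)
def test_sd_back_derived_from_t_interval(halfwidth, n, expected):
    assert derive_sd_from_ci(halfwidth, n) == pytest.approx(expected, rel=1e-5)


def test_sd_back_derivation_limits_and_errors():
    assert derive_sd_from_ci(0.0, 10) == 0.0
    with pytest.raises(ValueError):
        derive_sd_from_ci(1.0, 1)
    with pytest.raises(ValueError):
        derive_sd_from_ci(-1.0, 5)


def test_default_cohort_arm_sizes(default_cohort):
    assert len(default_cohort) == 47
    counts = default_cohort["arm"].value_counts()
    assert counts["TBMT"] == 21 and counts["CBMT"] == 26


def test_cohort_reproducible_for_fixed_seed():
    a = generate_cohort(seed=77)
    b = generate_cohort(seed=77)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(seed=78)
    assert not a.equals(c)


def test_degenerate_sds_give_exact_means():
    params = ArmParams(
        n=4,
        age=(45.0, 0.0),
        weight_kg=(75.0, 0.0),
        height_m=(1.7, 0.0),
        pain_duration_months=(9.0, 0.0),
        baseline_odi=(55.0, 0.0),
        change_week4=(10.0, 0.0),
        change_week8=(15.0, 0.0),
    )
    config = CohortConfig(arms={"TBMT": params})
    cohort = generate_cohort(config, seed=0)
    assert (cohort["age"] == 45.0).all()
    assert (cohort["odi_baseline"] == 55.0).all()
    assert (cohort["odi_week4"] == 45.0).all()
    assert (cohort["odi_week8"] == 40.0).all()


def test_eligibility_and_score_bounds(default_cohort):
    assert default_cohort["age"].between(20, 65).all()
    for col in ("odi_baseline", "odi_week4", "odi_week8"):
        assert default_cohort[col].between(0, 100).all()


def test_bmi_consistent(default_cohort):
    assert np.allclose(default_cohort["bmi"], default_cohort["weight_kg"] / default_cohort["height_m"] ** 2)


def test_protocol_costs_attached(default_cohort):
    by_arm = default_cohort.groupby("arm")["cost_naira"].unique()
    assert by_arm["TBMT"].tolist() == [22_200.0]
    assert by_arm["CBMT"].tolist() == [38_200.0]


def test_parameter_recovery_at_large_n():
    """Large-cohort means recover the configured generating parameters."""
    config = default_config()
    big_arms = {
        label: dataclasses.replace(p, n=500) for label, p in config.arms.items()
    }
    big = dataclasses.replace(config, arms=big_arms)
    cohort = generate_cohort(big, seed=4)
    for label, p in config.arms.items():
        sub = cohort[cohort["arm"] == label]
        for col, (mean, sd) in (
            ("age", p.age),
            ("odi_baseline", p.baseline_odi),
        ):
            se = sd / np.sqrt(500)
            assert abs(sub[col].mean() - mean) <= 3.5 * se
        change8 = sub["odi_baseline"] - sub["odi_week8"]
        se8 = p.change_week8[1] / np.sqrt(500)
        assert abs(change8.mean() - p.change_week8[0]) <= 3.5 * se8


def test_week4_week8_changes_positively_correlated(default_cohort):
    c4 = default_cohort["odi_baseline"] - default_cohort["odi_week4"]
    c8 = default_cohort["odi_baseline"] - default_cohort["odi_week8"]
    # baseline noise induces extra correlation on top of the configured 0.7
    assert np.corrcoef(c4, c8)[0, 1] > 0.2


def test_cohort_round_trip(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    write_cohort(default_cohort, path)
    loaded = read_cohort(path)
    pd.testing.assert_frame_equal(loaded, default_cohort, check_exact=False)
    with pytest.raises(ValueError):
        write_cohort(default_cohort.iloc[:0], tmp_path / "empty.csv")


def test_long_format_conversion(default_cohort):
    long = cohort_to_long(default_cohort)
    assert len(long) == 3 * len(default_cohort)
    assert set(long["timepoint"]) == {"baseline", "week4", "week8"}
    base = long[long["timepoint"] == "baseline"].set_index("participant_id")["odi"]
    assert np.allclose(
        base.loc[default_cohort["participant_id"]].to_numpy(), default_cohort["odi_baseline"]
    )


def test_config_yaml_round_trip(tmp_path):
    config = default_config()
    path = tmp_path / "cohort.yaml"
    config.to_yaml(path)
    loaded = CohortConfig.from_yaml(path)
    assert loaded.change_correlation == config.change_correlation
    assert set(loaded.arms) == set(config.arms)
    for label in config.arms:
        assert loaded.arms[label].n == config.arms[label].n
        assert loaded.arms[label].change_week8 == pytest.approx(config.arms[label].change_week8)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(arms={})
    params = default_config().arms["TBMT"]
    with pytest.raises(ValueError):
        CohortConfig(arms={"TBMT": params}, change_correlation=1.5)
    with pytest.raises(ValueError):
        ArmParams(
            n=1,
            age=(45, 1),
            weight_kg=(70, 1),
            height_m=(1.7, 0.1),
            pain_duration_months=(9, 1),
            baseline_odi=(50, 5),
            change_week4=(10, 2),
            change_week8=(15, 2),
        )


def test_identical_arm_configs_centre_delta_effect_at_zero():
    """With both arms generated identically the incremental effect is pure noise.

    Averaged over repeated cohorts the estimated dE is centred at 0 and the
    bootstrap mass on the positive-dE side of the plane averages one half.
    """
    from trialcua.cea import CostUtilityModel

    config = default_config()
    tbmt = config.arms["TBMT"]
    same = {
        "TBMT": dataclasses.replace(tbmt, n=150),
        "CBMT": dataclasses.replace(tbmt, n=150),
    }
    sym_config = dataclasses.replace(config, arms=same)
    deltas, positive_side = [], []
    for i in range(40):
        cohort = generate_cohort(sym_config, seed=5000 + i)
        res = CostUtilityModel.from_cohort(cohort).fit(reps=200, seed=i)
        deltas.append(res.delta_effect)
        positive_side.append(res.quadrant_proportions["NE"] + res.quadrant_proportions["SE"])
    deltas = np.asarray(deltas)
    mc_se = deltas.std(ddof=1) / np.sqrt(deltas.size)
    assert abs(deltas.mean()) <= 3 * mc_se
    assert np.mean(positive_side) == pytest.approx(0.5, abs=0.15)
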
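"""Parameter types, derivation rules, and fixture tables."""

import pytest
from hypothesis import given, settings as hsettings, strategies as st

from mammocea.params import (
    AGE_BANDS,
    STAGES,
    BetaParam,
    DerivationError,
    GammaParam,
    ParameterError,
    StageDistribution,
    TunnelSchedule,
    beta_mean,
    derive_age_detection,
    derive_interval_risk,
    expected_readings_per_exam,
    load_table2,
    reading_unit_cost,
)


@pytest.mark.parametrize(
    "alpha,beta,printed_pct,decimals",
    [
        (222, 36169, 0.61, 2),  # AI-assisted biennial detection
        (203, 39576, 0.51, 2),  # conventional biennial detection
        (4541, 125208, 3.5, 1),  # recall proportion 40-54
        (2341, 91297, 2.5, 1),  # recall proportion 55-74
        (1475, 35403, 4.0, 1),  # conference proportion, AI arm
        (1404, 34590, 3.9, 1),  # conference proportion, conventional
        (1, 1, 50.0, 1),  # symmetric Beta
    ],
)
def test_beta_mean_reproduces_printed_percentages(alpha, beta, printed_pct, decimals):
    assert round(100 * beta_mean(BetaParam(alpha, beta)), decimals) == printed_pct


def test_beta_param_rejects_nonpositive_shapes():
    with pytest.raises(ParameterError):
        BetaParam(0, 5)
    with pytest.raises(ParameterError):
        BetaParam(5, -1)


def test_beta_from_mean_cv_moments():
    p = BetaParam.from_mean_cv(0.018, 0.20)
    assert p.mean == pytest.approx(0.018, rel=1e-12)
    var = p.alpha * p.beta / ((p.alpha + p.beta) ** 2 * (p.alpha + p.beta + 1))
    assert var**0.5 == pytest.approx(0.20 * 0.018, rel=1e-9)


def test_gamma_param_shape_scale():
    g = GammaParam(2.7, 0.5)
    assert g.shape * g.scale == pytest.approx(2.7)
    assert g.shape * g.scale**2 == pytest.approx(0.25)
    assert GammaParam(2.7, 0.0).sd == 0  # degenerate allowed


@pytest.mark.parametrize(
    "overall,factor,expected_pct",
    [
        (222 / 36391, 0.53, 0.32),  # AI arm, ages 40-54
        (203 / 39779, 0.53, 0.27),  # conventional arm, ages 40-54
        (222 / 36391, 1.0, 0.61),  # identity factor
    ],
)
def test_age_split_detection(overall, factor, expected_pct):
    assert round(100 * derive_age_detection(overall, factor), 2) == expected_pct


def test_age_split_rejects_bad_inputs():
    with pytest.raises(ParameterError):
        derive_age_detection(0.0, 0.53)
    with pytest.raises(DerivationError):
        derive_age_detection(0.9, 1.4)  # result above 1


@pytest.mark.parametrize(
    "cdm,strat,expected_pct",
    [
        (203 / 39779 * 0.53, 222 / 36391 * 0.53, 0.03),  # 40-54, AI arm
        (203 / 39779 * 0.53, 203 / 39779 * 0.53, 0.06),  # 40-54, conventional
        (0.0072, 0.0086, 0.08),  # 55-74, AI arm
        (0.0072, 0.0072, 0.15),  # 55-74, conventional
    ],
)
def test_interval_risk_subtraction_reproduces_printed(cdm, strat, expected_pct):
    assert round(100 * derive_interval_risk(cdm, strat, 0.295), 2) == expected_pct


def test_interval_risk_zero_share_zero_risk():
    # with no interval share, a strategy detecting the full total leaves none
    for x in (0.001, 0.004, 0.009):
        assert derive_interval_risk(x, x, 0.0) == 0.0


def test_interval_risk_negative_raises_unless_clamped():
    with pytest.raises(DerivationError):
        derive_interval_risk(0.004, 0.02, 0.295)
    assert derive_interval_risk(0.004, 0.02, 0.295, clamp=True) == 0.0


@hsettings(max_examples=50, derandomize=True)
@given(
    cdm=st.floats(0.001, 0.01),
    share=st.floats(0.0, 0.6),
    s1=st.floats(0.0, 0.01),
    s2=st.floats(0.0, 0.01),
)
def test_interval_risk_antitone_in_strategy_detection(cdm, share, s1, s2):
    """More screen detection means fewer interval cancers."""
    lo, hi = sorted([s1, s2])
    r_lo = derive_interval_risk(cdm, lo, share, clamp=True)
    r_hi = derive_interval_risk(cdm, hi, share, clamp=True)
    assert r_hi <= r_lo


@pytest.mark.parametrize(
    "hourly,per_hour,expected",
    [(79.0, 29, 2.7), (79.0, 1, 79.0), (58.0, 29, 2.0)],
)
def test_reading_unit_cost(hourly, per_hour, expected):
    assert reading_unit_cost(hourly, per_hour) == expected


def test_reading_unit_cost_zero_throughput():
    with pytest.raises(ParameterError):
        reading_unit_cost(79.0, 0)


@pytest.mark.parametrize(
    "double,conf,human,expected",
    [
        (1.0, 0.039, 1.0, 2.078),  # conventional double reading
        (0.30, 0.040, 1.0, 1.380),  # AI triage, 30% double read
        (0.0, 0.0, 1.0, 1.0),  # single reading, no conferences
    ],
)
def test_expected_readings_per_exam(double, conf, human, expected):
    assert expected_readings_per_exam(double, conf, human) == pytest.approx(expected)


def test_stage_distributions_normalise_and_sum_to_one(cancer):
    for (mode, band), dist in cancer.stage_distributions.items():
        assert sum(dist.probs) == pytest.approx(1.0, abs=1e-12)


def test_stage_distribution_rejects_far_from_one():
    with pytest.raises(ParameterError):
        StageDistribution("screening", "40_54", (0.5, 0.2, 0.1, 0.1, 0.05))


def test_raw_stage_probs_sum_close_to_one_before_normalisation():
    t2 = load_table2()
    for key, by_stage in t2["stage_dist"].items():
        assert abs(sum(by_stage.values()) - 1.0) <= 0.005, key


def test_stage0_tunnel_has_zero_metastasis_risk(cancer):
    sched = cancer.tunnel("0")
    assert all(sched.metastasis_risk(t) == 0 for t in range(1, 15))


def test_tunnel_carry_forward_rules(cancer):
    s3 = cancer.tunnel("III")
    assert s3.metastasis_risk(12) == s3.metastasis_risk(9) == 0.019
    assert s3.qol_decrement(12) == 0.077
    assert s3.cost(9) == 3489 and s3.cost(10) == 0.0  # follow-up cost ends
    iv = cancer.tunnel("IV")
    assert iv.bc_death_risk(12) == iv.bc_death_risk(9) == 0.039
    assert iv.cost(12) == 22752  # metastatic cost applies for all years


def test_tunnel_schedule_validation():
    with pytest.raises(ParameterError):
        TunnelSchedule("0", (0.1,) * 9, (0.0,) * 9, (0.0,) * 9)  # stage 0 risk
    with pytest.raises(ParameterError):
        TunnelSchedule("I", (1.5,) * 9, (0.0,) * 9, (0.0,) * 9)  # risk > 1


def test_screening_params_detection_chain(screening):
    det = screening.detection_biennial("aidm")
    assert round(100 * det["40_54"], 2) == 0.32
    assert det["55_74"] == 0.0086  # carried as printed
    interval = screening.interval_annual(det)
    assert round(100 * interval["40_54"], 2) == 0.03
    assert round(100 * interval["55_74"], 2) == 0.08


def test_cost_params_derived_reading_unit(costs):
    assert costs.screen_reading_unit == 2.7
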
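"""Base-case parameter values, age schedules, distribution assignments and
the YAML configuration round trip."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from endocea.parameters import (
    AgeSchedule,
    CALIBRATABLE,
    ConfigError,
    ParameterError,
    base_case_parameters,
    load_parameters,
    save_parameters,
    schedule_value,
)


@pytest.fixture(scope="module")
def base():
    return base_case_parameters()


@pytest.mark.parametrize(
    "name, expected",
    [
        ("p_progress_dys_to_endo12", 0.184),
        ("p_recurrence", 0.222),
        ("p_surgery_endo", 0.06),
        ("prop_otc_selfcare", 0.871),
        ("p_cure_dys", 0.80),
        ("p_cure_endo12", 0.40),
        ("p_cure_endo34", 0.80),
        ("or_develop_endo12", 0.40),
        ("or_progress_endo34", 0.10),
        ("u_dys", 0.637),
        ("u_endo12", 0.637),
        ("u_endo34", 0.549),
        ("u_cured", 1.000),
        ("discount_rate", 0.03),
        ("start_age", 12),
        ("horizon", 23),
    ],
)
def test_base_case_model_values(base, name, expected):
    mp, _, _ = base
    assert getattr(mp, name) == expected


@pytest.mark.parametrize(
    "name, expected",
    [
        ("visit_cost_dys", 7_529),
        ("visit_cost_endo", 11_291),
        ("visits_per_year", 4),
        ("inpatient_cost_annual", 207_661),
        ("surgery_cost_mild", 288_080),
        ("surgery_cost_complex", 456_667),
        ("prop_complex", 0.452),
        ("otc_cost_annual", 19_243),
        ("selfmed_cost_annual", 13_715),
        ("productivity_loss_halfyear_selfcare", 184_625),
        ("productivity_loss_halfyear_intervention", 39_546),
    ],
)
def test_base_case_cost_values(base, name, expected):
    _, cp, _ = base
    assert getattr(cp, name) == expected


def test_incidence_schedule_spans_published_range(base):
    mp, _, _ = base
    assert mp.incidence_dysmenorrhea(12) == pytest.approx(0.0008)
    assert mp.incidence_dysmenorrhea(30) == pytest.approx(0.007)
    assert mp.visit_prop_dys(12) == pytest.approx(0.03)
    assert mp.visit_prop_dys(30) == pytest.approx(0.5)
    assert mp.visit_prop_endo(12) == pytest.approx(0.0124)
    assert mp.visit_prop_endo(30) == pytest.approx(0.0307)


@pytest.mark.parametrize(
    "name, family",
    [
        ("p_progress_dys_to_endo12", "beta"),
        ("p_recurrence", "beta"),
        ("p_surgery_endo", "normal"),
        ("prop_otc_selfcare", "normal"),
        ("or_develop_endo12", "lognormal"),
        ("or_progress_endo34", "lognormal"),
        ("u_dys", "lognormal"),
        ("u_endo12", "lognormal"),
        ("u_endo34", "lognormal"),
        ("visit_cost_dys", "lognormal"),
        ("visit_cost_endo", "lognormal"),
        ("inpatient_cost_annual", "lognormal"),
        ("surgery_cost_mild", "lognormal"),
        ("surgery_cost_complex", "lognormal"),
        ("otc_cost_annual", "lognormal"),
        ("selfmed_cost_annual", "lognormal"),
        ("productivity_loss_halfyear_selfcare", "lognormal"),
        ("productivity_loss_halfyear_intervention", "lognormal"),
    ],
)
def test_distribution_families_match_published_column(base, name, family):
    _, _, dists = base
    assert dists[name].family == family
    assert dists[name].central == pytest.approx(
        getattr(base[0], name, None) or getattr(base[1], name)
    )


def test_calibratable_parameters_are_flagged(base):
    mp, _, dists = base
    for name in CALIBRATABLE:
        assert hasattr(mp, name)
        # calibrated assumptions carry no published uncertainty distribution
        assert name not in dists


# ---------------------------------------------------------------- schedules


def test_schedule_interpolation_and_clamping():
    s = AgeSchedule(((12, 0.0008), (30, 0.007)))
    assert schedule_value(s, 12) == pytest.approx(0.0008)
    assert schedule_value(s, 21) == pytest.approx(0.0039)  # midpoint
    assert schedule_value(s, 40) == pytest.approx(0.007)  # clamped
    assert schedule_value(s, 5) == pytest.approx(0.0008)  # clamped below


def test_schedule_step_mode():
    s = AgeSchedule(((12, 0.1), (20, 0.4)), interpolation="step")
    assert s(12) == 0.1
    assert s(19.9) == 0.1
    assert s(20) == 0.4
    assert s(25) == 0.4


@given(
    a1=st.floats(12, 20),
    a2=st.floats(20.01, 35),
    v1=st.floats(0, 1),
    v2=st.floats(0, 1),
    q=st.floats(0, 1),
)
@settings(deadline=None)
def test_schedule_monotone_between_anchors(a1, a2, v1, v2, q):
    """Linear interpolation is monotone and bounded between anchor values."""
    s = AgeSchedule(((a1, v1), (a2, v2)))
    age = a1 + q * (a2 - a1)
    val = s(age)
    lo, hi = sorted((v1, v2))
    assert lo - 1e-12 <= val <= hi + 1e-12


@pytest.mark.parametrize(
    "anchors",
    [((30, 0.1), (12, 0.2)), ((12, 0.1), (12, 0.2)), ((12, 1.5),), ()],
)
def test_schedule_invalid_anchors(anchors):
    with pytest.raises(ParameterError):
        AgeSchedule(anchors)


def test_negative_age_rejected():
    s = AgeSchedule(((12, 0.5),))
    with pytest.raises(ParameterError):
        schedule_value(s, -1)


# ------------------------------------------------------------------- config


def test_yaml_round_trip_reproduces_base_case(base, tmp_path):
    mp, cp, _ = base
    path = tmp_path / "config.yaml"
    save_parameters(path, mp, cp)
    mp2, cp2 = load_parameters(path)
    assert mp2 == mp
    assert cp2 == cp


def test_empty_config_is_base_case(base, tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    mp, cp = load_parameters(path)
    assert mp == base[0]
    assert cp == base[1]


def test_single_key_override(base, tmp_path):
    path = tmp_path / "override.yaml"
    path.write_text("model:\n  discount_rate: 0.05\n")
    mp, cp = load_parameters(path)
    assert mp.discount_rate == 0.05
    assert dataclasses.replace(mp, discount_rate=0.03) == base[0]
    assert cp == base[1]


def test_unknown_key_rejected_by_name(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("model:\n  discount_rat: 0.05\n")
    with pytest.raises(ConfigError, match="discount_rat"):
        load_parameters(path)


def test_out_of_domain_value_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("model:\n  u_dys: 1.2\n")
    with pytest.raises(ConfigError, match="u_dys"):
        load_parameters(path)
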
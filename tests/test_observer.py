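"""Bayesian observer model: noise law, SVV error, scenarios, decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svvdrift import (
    ObserverParams,
    ScenarioSchedule,
    apply_scenario,
    bayes_weight,
    initial_state,
    response_probability,
    scenario_summary,
    scenario_time_course,
    sensory_sd,
    simulate_response,
    svv_error,
)
from svvdrift.errors import ConfigurationError, InvalidInputError


@pytest.mark.parametrize(
    "alpha0, alpha1, head, expected",
    [(2.0, 0.1, 0.0, 2.0), (2.0, 0.1, -20.0, 4.0), (1.5, 0.05, 60.0, 4.5)],
)
def test_sensory_noise_grows_linearly_with_tilt_magnitude(alpha0, alpha1, head, expected):
    p = ObserverParams(alpha0=alpha0, alpha1=alpha1)
    assert sensory_sd(p, head) == pytest.approx(expected)


@given(head=st.floats(-180, 180), alpha1=st.floats(0, 1))
@settings(max_examples=50, derandomize=True)
def test_sensory_noise_is_even_and_positive(head, alpha1):
    p = ObserverParams(alpha0=1.3, alpha1=alpha1)
    assert sensory_sd(p, head) == sensory_sd(p, -head) > 0


def test_sensory_noise_rejects_non_finite_head():
    with pytest.raises(InvalidInputError):
        sensory_sd(ObserverParams(), float("nan"))


def test_params_validation():
    with pytest.raises(InvalidInputError):
        ObserverParams(sigma_prior=-1.0)
    with pytest.raises(InvalidInputError):
        ObserverParams(lapse_rate=0.5)


def test_svv_error_weighted_head_term():
    p = ObserverParams(sigma_prior=10.0, alpha0=5.0, alpha1=0.0, delta_EH=0.0)
    assert svv_error(p, 0.0) == pytest.approx(0.0)
    assert svv_error(p, 20.0) == pytest.approx(4.0)  # w = 25/125


def test_svv_error_uncompensated_torsion_term():
    p = ObserverParams(sigma_prior=10.0, alpha0=5.0, alpha1=0.0, delta_EH=10.0)
    assert svv_error(p, 20.0) == pytest.approx(4.0 - 10.0 * math.sin(math.radians(20.0)), abs=1e-9)
    assert svv_error(p, 20.0) == pytest.approx(0.5798, abs=5e-4)


@given(
    sigma_prior=st.floats(0.5, 30),
    alpha0=st.floats(0.2, 10),
    alpha1=st.floats(0, 0.5),
    delta=st.floats(-20, 20),
    head=st.floats(-90, 90),
)
@settings(max_examples=100, derandomize=True)
def test_unbiased_error_reduces_to_two_term_form(sigma_prior, alpha0, alpha1, delta, head):
    """With zero prior mean and unbiased sensors the error is exactly
    w*H - delta*sin(H)."""
    p = ObserverParams(sigma_prior=sigma_prior, alpha0=alpha0, alpha1=alpha1, delta_EH=delta)
    w = bayes_weight(p, head)
    expected = w * head - delta * math.sin(math.radians(head))
    assert svv_error(p, head) == pytest.approx(expected, abs=1e-12)


def test_flat_prior_limit_leaves_only_torsion_term():
    p = ObserverParams(sigma_prior=1e9, alpha0=2.0, delta_EH=8.0)
    expected = -8.0 * math.sin(math.radians(30.0))
    assert svv_error(p, 30.0) == pytest.approx(expected, rel=1e-6)


def test_vanishing_sensory_noise_kills_the_weighting_term():
    p = ObserverParams(sigma_prior=5.0, alpha0=1e-9, alpha1=0.0, delta_EH=0.0)
    assert svv_error(p, 40.0) == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("tilt", [20.0, -20.0])
@pytest.mark.parametrize(
    "kind, slope_sign, offset_sign",
    [("sensory_drift", +1, +1), ("prior_drift", -1, None), ("noise_growth", +1, 0)],
)
def test_scenario_drift_and_aftereffect_signatures(kind, slope_sign, offset_sign, tilt):
    """Sensory adaptation drifts toward the tilt with a same-signed
    aftereffect; prior drift goes the other way; noise growth drifts toward
    the tilt but leaves no aftereffect."""
    sig = scenario_summary(scenario_time_course(kind, tilt_angle=tilt))
    assert np.sign(sig["tilt_slope_per_min"]) == slope_sign * np.sign(tilt)
    if offset_sign == 0:
        assert sig["posttilt_offset"] == pytest.approx(0.0, abs=1e-9)
    elif offset_sign is not None:
        assert np.sign(sig["posttilt_offset"]) == offset_sign * np.sign(tilt)


def test_identity_schedule_changes_nothing_but_time(default_params):
    state = initial_state(default_params, 20.0)
    out = apply_scenario(state, ScenarioSchedule(), default_params, 120.0, "tilt", 20.0)
    assert out.t == 120.0
    assert out.sensed_head_bias == state.sensed_head_bias == 0.0
    assert out.mu_svv == pytest.approx(svv_error(default_params, 20.0))


def test_apply_scenario_rejects_time_reversal(default_params):
    state = initial_state(default_params)
    state = apply_scenario(state, ScenarioSchedule(), default_params, 10.0, "baseline", 0.0)
    with pytest.raises(InvalidInputError):
        apply_scenario(state, ScenarioSchedule(), default_params, 5.0, "baseline", 0.0)


def test_schedule_validation():
    with pytest.raises(ConfigurationError):
        ScenarioSchedule(kind="frobnicate")
    with pytest.raises(ConfigurationError):
        ScenarioSchedule(kind="composite")  # needs sub-schedules


def test_mu_recomputation_is_idempotent(default_params):
    sched = ScenarioSchedule(kind="sensory_drift", tilt_rate=-0.4)
    state = initial_state(default_params, 0.0, sched)
    for t, seg, head in [(10, "baseline", 0.0), (100, "tilt", 20.0), (400, "tilt", 20.0)]:
        state = apply_scenario(state, sched, default_params, t, seg, head)
        recomputed = svv_error(
            default_params,
            state.head_angle,
            state.sensed_head_bias,
            state.effective_prior_mean,
            state.effective_alpha1,
        )
        assert state.mu_svv == pytest.approx(recomputed, abs=1e-12)


def test_response_probability_pse_and_monotonicity(default_params):
    state = initial_state(default_params, 20.0)
    assert response_probability(state, default_params, state.mu_svv) == pytest.approx(0.5)
    grid = np.linspace(-89.0, 89.0, 181)
    probs = [response_probability(state, default_params, d) for d in grid]
    assert np.all(np.diff(probs) >= 0)
    assert probs[-1] > 0.999


def test_response_probability_75_percent_point():
    """The 75 % point lies exactly scale*ln3 above the PSE."""
    p = ObserverParams(decision_scale=1.0)
    sched = ScenarioSchedule(kind="sensory_drift", bias_baseline=3.9 / (1 - bayes_weight(p, 0.0)))
    state = initial_state(p, 0.0, sched)
    assert state.mu_svv == pytest.approx(-3.9)
    assert response_probability(state, p, -3.9 + math.log(3.0)) == pytest.approx(0.75)
    assert response_probability(state, p, -2.801) == pytest.approx(0.75, abs=1e-3)


def test_response_probability_rejects_out_of_range(default_params):
    state = initial_state(default_params)
    with pytest.raises(InvalidInputError):
        response_probability(state, default_params, 120.0)
    with pytest.raises(InvalidInputError):
        response_probability(state, default_params, -90.0)


def test_lapse_floor_and_ceiling():
    p = ObserverParams(lapse_rate=0.1, decision_scale=0.5)
    state = initial_state(p)
    assert response_probability(state, p, 89.0) == pytest.approx(0.95, abs=1e-6)
    assert response_probability(state, p, -89.0) == pytest.approx(0.05, abs=1e-6)


def test_simulated_response_frequencies(default_params):
    rng = np.random.default_rng(11)
    p = ObserverParams(decision_scale=1.0)
    sched = ScenarioSchedule(
        kind="sensory_drift", bias_baseline=-2.0 / (1 - bayes_weight(p, 0.0))
    )
    state = initial_state(p, 0.0, sched)
    assert state.mu_svv == pytest.approx(2.0)

    n = 10_000
    at_pse = sum(simulate_response(state, p, 2.0, rng)[0] == "right" for _ in range(n))
    assert at_pse / n == pytest.approx(0.5, abs=0.02)
    above = sum(simulate_response(state, p, 3.0, rng)[0] == "right" for _ in range(n))
    assert above / n == pytest.approx(0.731, abs=0.02)


def test_reaction_times_respect_response_window(default_params):
    rng = np.random.default_rng(3)
    state = initial_state(default_params)
    rts = np.array(
        [simulate_response(state, default_params, 1.0, rng, 660.0)[1] for _ in range(2000)]
    )
    assert rts.min() >= 300.0 and rts.max() <= 1500.0
    assert rts.mean() == pytest.approx(660.0, rel=0.05)
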
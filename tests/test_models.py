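"""Value functions, softmax rule and session likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridchoice import models
from hybridchoice.models import ModelParams, choice_prob, negloglik
from hybridchoice.task import generate_schedule, simulate_agent

weights = st.floats(0.0, 1.0)
probs = st.floats(0.01, 0.99)
mags = st.floats(0.1, 1.0)


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (models.sv_multiplicative, (0.5, 1.0), 0.5),
        (models.sv_multiplicative, (0.30, 0.70), 0.21),
        (models.sv_additive, (0.4, 0.6, 0.5), 0.5),
        (models.sv_additive, (0.7, 0.9, 1.0), 0.7),
        (models.sv_additive, (0.70, 0.30, 0.82), 0.628),
        (models.sv_hybrid, (0.70, 0.30, 0.49, 0.82), 0.49 * 0.21 + 0.51 * 0.628),
    ],
)
def test_subjective_value_hand_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-12)


def test_value_functions_reject_out_of_range():
    with pytest.raises(ValueError):
        models.sv_multiplicative(1.5, 0.5)
    with pytest.raises(ValueError):
        models.sv_additive(0.5, 0.5, 1.2)
    with pytest.raises(ValueError):
        models.pt_probability_weight(0.5, -1.0)
    with pytest.raises(ValueError):
        models.sv_prospect(0.5, 4.0, variant="nope")


@settings(derandomize=True, max_examples=60)
@given(P=probs, M=mags, op=weights)
def test_hybrid_reduces_to_pure_strategies(P, M, op):
    assert models.sv_hybrid(P, M, 1.0, op) == pytest.approx(
        models.sv_multiplicative(P, M), abs=1e-15)
    assert models.sv_hybrid(P, M, 0.0, op) == pytest.approx(
        models.sv_additive(P, M, op), abs=1e-15)


@settings(derandomize=True, max_examples=60)
@given(P=probs, M=st.floats(1.0, 10.0))
def test_prospect_reduces_to_raw_ev_at_unit_exponents(P, M):
    assert models.sv_prospect(P, M, 1.0, 1.0, "pt_both") == pytest.approx(
        P * M, rel=1e-12)
    # magnitude of 1 is a fixed point of the power distortion
    assert models.sv_prospect(P, 1.0, alpha=2.3, variant="pt_magnitude") \
        == pytest.approx(P, rel=1e-12)


def test_probability_weighting_endpoints_and_value():
    assert models.pt_probability_weight(0.0, 0.6) == 0.0
    assert models.pt_probability_weight(1.0, 0.6) == pytest.approx(1.0)
    assert models.pt_probability_weight(0.3, 1.0) == pytest.approx(0.3)
    g = 0.6
    expected = 0.5**g / (0.5**g + 0.5**g) ** (1 / g)
    assert models.pt_probability_weight(0.5, g) == pytest.approx(expected, rel=1e-12)
    assert models.sv_prospect(0.5, 4.0, alpha=0.8, variant="pt_magnitude") \
        == pytest.approx(0.5 * 4**0.8, rel=1e-12)


def test_choice_prob_values_and_limits():
    assert choice_prob(0.0, 5.0) == pytest.approx(0.5)
    assert choice_prob(2.0, 0.0) == pytest.approx(0.5)
    assert choice_prob(0.1, 14.56) == pytest.approx(1 / (1 + math.exp(-1.456)))
    # numerically safe at extreme arguments
    assert choice_prob(1e4, 100.0) == 1.0
    assert choice_prob(-1e4, 100.0) == 0.0
    with pytest.raises(ValueError):
        choice_prob(0.1, -1.0)


@settings(derandomize=True, max_examples=60)
@given(dsv=st.floats(-5, 5), tau=st.floats(0.0, 50.0))
def test_choice_prob_symmetry_and_monotonicity(dsv, tau):
    p, q = choice_prob(dsv, tau), choice_prob(-dsv, tau)
    assert p + q == pytest.approx(1.0, abs=1e-12)
    if tau > 0:
        assert choice_prob(dsv + 0.5, tau) >= p


@settings(derandomize=True, max_examples=60)
@given(P=probs, M=mags, om=weights, op=weights)
def test_hybrid_monotone_in_both_attributes(P, M, om, op):
    base = models.sv_hybrid(P, M, om, op)
    assert models.sv_hybrid(min(P + 0.01, 1.0), M, om, op) >= base - 1e-15
    assert models.sv_hybrid(P, min(M + 0.01, 1.0), om, op) >= base - 1e-15


def _oracle_negloglik(session, params):
    """Independent per-trial loop in plain Python floats."""
    tot = 0.0
    sc = session.schedule
    for t in range(session.n_trials):
        svl = (params.omega_mult * sc.prob_left[t] * sc.mag_left[t] / 10
               + (1 - params.omega_mult)
               * (params.omega_p * sc.prob_left[t]
                  + (1 - params.omega_p) * sc.mag_left[t] / 10))
        svr = (params.omega_mult * sc.prob_right[t] * sc.mag_right[t] / 10
               + (1 - params.omega_mult)
               * (params.omega_p * sc.prob_right[t]
                  + (1 - params.omega_p) * sc.mag_right[t] / 10))
        x = (svl - svr) * params.tau
        p_left = 1.0 / (1.0 + math.exp(-x))
        p = p_left if session.choices_left[t] else 1.0 - p_left
        tot -= math.log(min(max(p, 1e-12), 1 - 1e-12))
    return tot


def test_negloglik_matches_loop_oracle_and_noise_floor():
    rng = np.random.default_rng(5)
    sched = generate_schedule(60, seed=3)
    for _ in range(20):
        params = ModelParams(omega_mult=rng.uniform(), omega_p=rng.uniform(),
                             tau=rng.uniform(0, 30))
        sess = simulate_agent(sched, params, seed=int(rng.integers(2**31)))
        assert negloglik(sess, "hybrid", params) == pytest.approx(
            _oracle_negloglik(sess, params), rel=1e-10)
    # tau = 0: every choice has probability 1/2
    sess = simulate_agent(sched, ModelParams(tau=0.0), seed=1)
    assert negloglik(sess, "hybrid", ModelParams(tau=0.0)) == pytest.approx(
        60 * math.log(2))


def test_negloglik_prefers_generating_parameters():
    true = ModelParams(omega_mult=0.49, omega_p=0.82, tau=14.56)
    wrong = ModelParams(omega_mult=0.9, omega_p=0.1, tau=1.0)
    diffs = []
    for seed in range(10):
        sched = generate_schedule(200, seed=seed)
        sess = simulate_agent(sched, true, seed=seed + 100)
        diffs.append(negloglik(sess, "hybrid", wrong)
                     - negloglik(sess, "hybrid", true))
    assert np.mean(diffs) > 0


def test_negloglik_finite_under_extreme_parameters(study_session):
    # tau at its bound with deterministic-looking data must stay finite
    val = negloglik(study_session, "hybrid",
                    ModelParams(omega_mult=1.0, omega_p=0.5, tau=100.0))
    assert np.isfinite(val) and val >= 0


def test_repetition_bias_enters_likelihood():
    sched = generate_schedule(100, seed=9)
    params = ModelParams(omega_mult=0.5, omega_p=0.8, tau=5.0, bias=2.0)
    sess = simulate_agent(sched, params, model="hybrid_repbias", seed=4)
    with_bias = negloglik(sess, "hybrid_repbias", params)
    no_bias = negloglik(sess, "hybrid_repbias",
                        ModelParams(omega_mult=0.5, omega_p=0.8, tau=5.0, bias=0.0))
    assert with_bias < no_bias  # the agent really repeats
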
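"""Schedule constraints, outcome sampling, agents and cohorts."""

import numpy as np
import pytest
from scipy.special import expit

from hybridchoice import (
    DrugShifts,
    GroupParams,
    ModelParams,
    generate_schedule,
    make_cohort,
    sample_outcomes,
    simulate_agent,
)
from hybridchoice.models import choice_prob, delta_sv
from hybridchoice.task import DRUGS, ScheduleConstraintError


def test_schedule_reproducible_bit_for_bit():
    a = generate_schedule(200, seed=77)
    b = generate_schedule(200, seed=77)
    for attr in ("mag_left", "mag_right", "prob_left", "prob_right"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))
    assert a.corr_report == b.corr_report


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("n", [120, 500])
def test_schedule_constraints_hold(seed, n):
    s = generate_schedule(n, seed=seed)
    assert not np.any(s.mag_left == s.mag_right)
    assert not np.any(s.prob_left == s.prob_right)
    assert s.n_nobrainer <= int(np.ceil(0.178 * n))
    # independent one-line Pearson oracle on the EV correlation
    r = np.corrcoef(s.prob_left * s.mag_left, s.prob_right * s.mag_right)[0, 1]
    assert abs(r) <= 0.1 + 1e-9
    for v in s.corr_report.values():
        assert abs(v) <= 0.1 + 1e-9


def test_schedule_grids_respected():
    s = generate_schedule(150, seed=3)
    assert set(s.mag_left) <= set(range(1, 11))
    assert set(np.round(s.prob_left, 2)) <= set(np.round(np.arange(0.10, 0.951, 0.05), 2))


def test_schedule_infeasible_constraint_raises():
    with pytest.raises(ScheduleConstraintError, match="corr"):
        generate_schedule(200, corr_cap=1e-6, seed=0, max_iter=200)
    with pytest.raises(ValueError):
        generate_schedule(100, magnitude_grid=[5], seed=0)


def test_outcomes_are_bernoulli_and_independent(rng):
    s = generate_schedule(500, seed=10)
    # pool many outcome draws of the same schedule
    rl, rr = [], []
    for k in range(20):
        out = sample_outcomes(s, seed=k)
        rl.append(out.rewarded_left)
        rr.append(out.rewarded_right)
    rl, rr = np.concatenate(rl), np.concatenate(rr)
    p = np.tile(s.prob_left, 20)
    # empirical rate within 3 binomial SEs, per probability level
    for level in np.unique(p):
        m = p == level
        se = np.sqrt(level * (1 - level) / m.sum())
        assert abs(rl[m].mean() - level) < 3.5 * se
    # outcomes of the two options are uncorrelated
    assert abs(np.corrcoef(rl, rr)[0, 1]) < 0.03


def test_agent_matches_per_trial_loop_oracle():
    s = generate_schedule(500, seed=5)
    params = ModelParams(omega_mult=0.49, omega_p=0.82, tau=14.56)
    sess = simulate_agent(s, params, seed=99)
    # independent loop with the same draw stream
    rng = np.random.default_rng(99)
    u = rng.random(s.n_trials)
    dsv = delta_sv("hybrid", params, s.mag_left, s.mag_right,
                   s.prob_left, s.prob_right)
    expected = np.array([u[t] < choice_prob(dsv[t], params.tau)
                         for t in range(s.n_trials)])
    assert np.array_equal(sess.choices_left, expected)
    assert sess.truth is params


def test_agent_softmax_limits():
    s = generate_schedule(300, seed=2)
    greedy = simulate_agent(s, ModelParams(omega_mult=1.0, tau=1e6),
                            model="multiplicative", seed=1)
    nontie = np.abs(s.ev_left - s.ev_right) > 1e-9
    assert np.array_equal(greedy.choices_left[nontie],
                          (s.ev_left > s.ev_right)[nontie])
    noisy = simulate_agent(s, ModelParams(tau=0.0), seed=1)
    assert abs(noisy.choices_left.mean() - 0.5) < 0.1


def test_cohort_shape_and_latin_square():
    cohort = make_cohort(n_subjects=6, n_trials=40, seed=0)
    assert len(cohort.sessions) == 18
    assert sum(s.n_trials for s in cohort.sessions) == 18 * 40
    cohort.validate()
    by_subject = {}
    for s in cohort.sessions:
        by_subject.setdefault(s.subject_id, {})[s.session_order] = s.drug
    orders = [tuple(v[k] for k in sorted(v)) for v in by_subject.values()]
    # every subject has all three drugs; orders are balanced across subjects
    assert all(sorted(o) == sorted(DRUGS) for o in orders)
    assert len(set(orders)) == 3


def test_zero_shifts_share_parameters_within_subject():
    cohort = make_cohort(n_subjects=3, n_trials=30, seed=1,
                         shifts=DrugShifts())
    by_subject = {}
    for s in cohort.sessions:
        by_subject.setdefault(s.subject_id, []).append(s.truth.to_dict())
    for truths in by_subject.values():
        assert truths[0] == truths[1] == truths[2]


def test_degenerate_group_sigma_collapses_subjects():
    g = GroupParams(sigma_mult=1e-12, sigma_p=1e-12, sigma_beta=1e-12)
    cohort = make_cohort(n_subjects=4, n_trials=30, seed=3, group=g)
    oms = {round(s.truth.omega_mult, 6) for s in cohort.sessions}
    assert len(oms) == 1
    assert oms.pop() == pytest.approx(expit(g.x_mult), abs=1e-6)


def test_latent_shifts_move_natural_parameters():
    shifts = DrugShifts(amisulpride=(0.0, 0.0, -0.5), ldopa=(0.0, 0.0, 0.5))
    cohort = make_cohort(n_subjects=4, n_trials=30, seed=3, shifts=shifts)
    for subj in cohort.subjects:
        taus = {s.drug: s.truth.tau for s in cohort.sessions
                if s.subject_id == subj}
        assert taus["amisulpride"] == pytest.approx(
            taus["placebo"] * np.exp(-0.5), rel=1e-9)
        assert taus["ldopa"] == pytest.approx(
            taus["placebo"] * np.exp(0.5), rel=1e-9)
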
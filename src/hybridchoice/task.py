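"""Synthetic task: constrained reward schedules, outcomes, agents, cohorts.

The task presents two options per trial, each defined by a reward magnitude
(integer, 1-10) and a reward probability (percentage).  Schedules are
generated before any "experiment" under three constraints:

* no attribute ties — the two options never share a magnitude or a
  probability;
* dominated ("no-brainer") trials, where one option is strictly higher on
  both attributes, are capped (default 17.8% of trials, i.e. 89 of 500);
* left/right option attributes and expected values are kept decorrelated
  (default |Pearson r| <= 0.1), by rejection/resampling.

Agents choose via the softmax rule over a subjective-value model from
:mod:`hybridchoice.models`; cohorts draw subject-level parameters from group
distributions on a latent scale (logit for the weights, log for the inverse
temperature) with additive per-drug latent shifts, mirroring the hierarchical
model that later estimates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .models import ModelParams, choice_prob, delta_sv, get_spec

__all__ = [
    "DRUGS",
    "Schedule",
    "SessionData",
    "CohortData",
    "GroupParams",
    "DrugShifts",
    "ScheduleConstraintError",
    "generate_schedule",
    "sample_outcomes",
    "simulate_agent",
    "make_cohort",
]

DRUGS = ("placebo", "amisulpride", "ldopa")

DEFAULT_MAGNITUDE_GRID = tuple(range(1, 11))
DEFAULT_PROBABILITY_GRID = tuple(np.round(np.arange(0.10, 0.951, 0.05), 2))


class ScheduleConstraintError(RuntimeError):
    """Raised when schedule constraints stay infeasible after resampling."""


@dataclass
class Schedule:
    """A constrained sequence of two-option trials (arrays indexed by trial)."""

    mag_left: np.ndarray
    mag_right: np.ndarray
    prob_left: np.ndarray
    prob_right: np.ndarray
    rewarded_left: np.ndarray | None = None
    rewarded_right: np.ndarray | None = None
    corr_report: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.mag_left)

    @property
    def ev_left(self) -> np.ndarray:
        """Expected value with scaled magnitudes (0.10-1.00)."""
        return self.prob_left * self.mag_left / 10.0

    @property
    def ev_right(self) -> np.ndarray:
        return self.prob_right * self.mag_right / 10.0

    @property
    def dominated(self) -> np.ndarray:
        """Per-trial indicator of a 'no-brainer': one option strictly higher
        on both attributes (ties are impossible by construction)."""
        left_dom = (self.mag_left > self.mag_right) & (self.prob_left > self.prob_right)
        right_dom = (self.mag_right > self.mag_left) & (self.prob_right > self.prob_left)
        return left_dom | right_dom

    @property
    def n_nobrainer(self) -> int:
        return int(self.dominated.sum())

    def validate(self) -> None:
        if np.any(self.mag_left == self.mag_right):
            raise ValueError("attribute tie: equal magnitudes on some trial")
        if np.any(self.prob_left == self.prob_right):
            raise ValueError("attribute tie: equal probabilities on some trial")


@dataclass
class SessionData:
    """One subject x drug session: a schedule plus the per-trial choices.

    ``choices_left`` is boolean (True = left chosen).  ``truth`` carries the
    generating parameters for simulated sessions and is absent for real data.
    """

    subject_id: str
    drug: str
    session_order: int
    schedule: Schedule
    choices_left: np.ndarray
    truth: ModelParams | None = None
    model: str = "hybrid"

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"invalid drug label {self.drug!r}; expected one of {DRUGS}")
        if len(self.choices_left) != self.schedule.n_trials:
            raise ValueError("one choice per trial required")

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials


@dataclass
class CohortData:
    """All sessions of a within-subject cohort (each subject x each drug)."""

    sessions: list[SessionData]
    group_truth: "tuple[GroupParams, DrugShifts] | None" = None

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def validate(self) -> None:
        per_subject: dict[str, list[str]] = {}
        for s in self.sessions:
            per_subject.setdefault(s.subject_id, []).append(s.drug)
        for subj, drugs in per_subject.items():
            if sorted(drugs) != sorted(DRUGS):
                raise ValueError(
                    f"subject {subj} must have exactly one session per drug, got {drugs}"
                )


@dataclass
class GroupParams:
    """Group-level distribution of subject parameters on the latent scale.

    Subject latents are Normal(mean, sigma); the weights map through an
    inverse logit and the inverse temperature through an exponential.
    Defaults place the group medians at omega_mult = 0.49, omega_p = 0.82,
    tau = 14.56 with moderate between-subject spread.
    """

    x_mult: float = math.log(0.49 / 0.51)
    x_p: float = math.log(0.82 / 0.18)
    x_beta: float = math.log(14.56)
    sigma_mult: float = 0.8
    sigma_p: float = 0.8
    sigma_beta: float = 0.4

    def validate(self) -> None:
        if min(self.sigma_mult, self.sigma_p, self.sigma_beta) <= 0:
            raise ValueError("group sigmas must be > 0")


@dataclass
class DrugShifts:
    """Additive latent-scale shifts for the two active drugs (six numbers)."""

    amisulpride: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (mult, p, tau)
    ldopa: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def for_drug(self, drug: str) -> tuple[float, float, float]:
        if drug == "placebo":
            return (0.0, 0.0, 0.0)
        return getattr(self, drug)


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------

def _sample_pairs(rng, grid, n):
    """n tie-free (left, right) pairs drawn uniformly from a grid."""
    grid = np.asarray(grid)
    g = len(grid)
    i = rng.integers(0, g, size=n)
    j = (i + 1 + rng.integers(0, g - 1, size=n)) % g
    return grid[i], grid[j]

_CORR_KEYS = ("magnitude", "probability", "ev")


def _correlations(ml, mr, pl, pr):
    ev_l = pl * ml / 10.0
    ev_r = pr * mr / 10.0
    return {
        "magnitude": float(np.corrcoef(ml, mr)[0, 1]),
        "probability": float(np.corrcoef(pl, pr)[0, 1]),
        "ev": float(np.corrcoef(ev_l, ev_r)[0, 1]),
    }


def generate_schedule(
    n_trials: int = 500,
    magnitude_grid: Sequence[int] = DEFAULT_MAGNITUDE_GRID,
    probability_grid: Sequence[float] = DEFAULT_PROBABILITY_GRID,
    nobrainer_cap: float = 0.178,
    corr_cap: float = 0.1,
    seed: int | None = None,
    max_iter: int = 20000,
) -> Schedule:
    """Generate a constrained schedule, deterministic in ``seed``.

    Attribute pairs are sampled uniformly without within-trial ties; excess
    dominated trials are converted to anti-dominated ones by swapping that
    trial's probability pair.  Because capping dominance couples the two
    options' expected values, the left/right correlation constraints are
    then enforced by greedy local search over constraint-preserving moves:
    swapping the (unordered) probability pairs of two trials, or mirroring a
    whole trial left/right — both keep tie-freedom and the dominance count
    intact.  Raises :class:`ScheduleConstraintError` naming the violated
    constraint if the search budget is exhausted.
    """
    if len(magnitude_grid) < 2 or len(probability_grid) < 2:
        raise ValueError("attribute grids need at least 2 elements")
    if not 0 < nobrainer_cap < 1:
        raise ValueError("nobrainer_cap must be in (0, 1)")
    rng = np.random.default_rng(seed)
    max_dominated = math.floor(nobrainer_cap * n_trials)

    ml, mr = _sample_pairs(rng, magnitude_grid, n_trials)
    pl, pr = _sample_pairs(rng, probability_grid, n_trials)
    ml, mr, pl, pr = (np.asarray(a, dtype=float) for a in (ml, mr, pl, pr))

    dom = ((ml > mr) & (pl > pr)) | ((ml < mr) & (pl < pr))
    excess = int(dom.sum()) - max_dominated
    if excess > 0:
        idx = rng.choice(np.flatnonzero(dom), size=excess, replace=False)
        pl[idx], pr[idx] = pr[idx].copy(), pl[idx].copy()
    dominated = ((ml > mr) & (pl > pr)) | ((ml < mr) & (pl < pr))

    def penalty():
        c = _correlations(ml, mr, pl, pr)
        return sum(max(0.0, abs(v) - 0.9 * corr_cap) for v in c.values()), c

    def orient_probs(i):
        """Point trial i's probability pair to preserve its dominance flag."""
        want_same_side = bool(dominated[i])
        prob_side_left = pl[i] > pr[i]
        mag_side_left = ml[i] > mr[i]
        if (prob_side_left == mag_side_left) != want_same_side:
            pl[i], pr[i] = pr[i], pl[i]

    pgrid = np.asarray(probability_grid, dtype=float)
    mgrid = np.asarray(magnitude_grid, dtype=float)
    pen, corr = penalty()
    it = 0
    while pen > 0 and it < max_iter:
        it += 1
        move = rng.random()
        if move < 0.4:
            # exchange the probability pairs of two trials
            a, b = rng.integers(0, n_trials, size=2)
            if a == b:
                continue
            old = (pl[a], pr[a], pl[b], pr[b])
            pl[a], pr[a], pl[b], pr[b] = pl[b], pr[b], pl[a], pr[a]
            orient_probs(a)
            orient_probs(b)
            new_pen, new_corr = penalty()
            if new_pen < pen:
                pen, corr = new_pen, new_corr
            else:
                pl[a], pr[a], pl[b], pr[b] = old
        elif move < 0.55:
            # draw a fresh magnitude pair for one trial
            a = int(rng.integers(0, n_trials))
            old = (ml[a], mr[a])
            i = int(rng.integers(0, len(mgrid)))
            j = (i + 1 + int(rng.integers(0, len(mgrid) - 1))) % len(mgrid)
            ml[a], mr[a] = mgrid[i], mgrid[j]
            orient_probs(a)
            new_pen, new_corr = penalty()
            if new_pen < pen:
                pen, corr = new_pen, new_corr
            else:
                ml[a], mr[a] = old
                orient_probs(a)
        elif move < 0.75:
            # mirror a whole trial left/right
            a = int(rng.integers(0, n_trials))
            ml[a], mr[a] = mr[a], ml[a]
            pl[a], pr[a] = pr[a], pl[a]
            new_pen, new_corr = penalty()
            if new_pen < pen:
                pen, corr = new_pen, new_corr
            else:
                ml[a], mr[a] = mr[a], ml[a]
                pl[a], pr[a] = pr[a], pl[a]
        else:
            # draw a fresh probability pair for one trial
            a = int(rng.integers(0, n_trials))
            old = (pl[a], pr[a])
            i = int(rng.integers(0, len(pgrid)))
            j = (i + 1 + int(rng.integers(0, len(pgrid) - 1))) % len(pgrid)
            pl[a], pr[a] = pgrid[i], pgrid[j]
            orient_probs(a)
            new_pen, new_corr = penalty()
            if new_pen < pen:
                pen, corr = new_pen, new_corr
            else:
                pl[a], pr[a] = old

    bad = {k: v for k, v in corr.items() if abs(v) > corr_cap}
    if bad:
        worst = max(bad, key=lambda k: abs(bad[k]))
        raise ScheduleConstraintError(
            f"could not satisfy |corr(left, right)| <= {corr_cap} for "
            f"{worst!r} (got {bad[worst]:+.3f}) within {max_iter} search steps"
        )
    sched = Schedule(ml, mr, pl, pr, corr_report=corr)
    sched.validate()
    assert sched.n_nobrainer <= max_dominated
    return sched


def sample_outcomes(schedule: Schedule, seed: int | None = None) -> Schedule:
    """Independent Bernoulli reward outcomes for both options of each trial."""
    rng = np.random.default_rng(seed)
    rl = rng.random(schedule.n_trials) < schedule.prob_left
    rr = rng.random(schedule.n_trials) < schedule.prob_right
    return replace(schedule, rewarded_left=rl, rewarded_right=rr)


# ---------------------------------------------------------------------------
# Agents and cohorts
# ---------------------------------------------------------------------------

def simulate_agent(
    schedule: Schedule,
    params: ModelParams,
    model: str = "hybrid",
    seed: int | None = None,
    subject_id: str = "sim",
    drug: str = "placebo",
    session_order: int = 1,
) -> SessionData:
    """Simulate one session of softmax choices with known parameters.

    With the repetition-bias extension the bias feeds on the agent's own
    previous simulated choice, so trials are drawn sequentially; models
    without the bias vectorize over trials with an identical draw stream.
    """
    spec = get_spec(model)
    rng = np.random.default_rng(seed)
    dsv = delta_sv(
        spec, params, schedule.mag_left, schedule.mag_right,
        schedule.prob_left, schedule.prob_right,
    )
    u = rng.random(schedule.n_trials)
    if spec.name == "hybrid_repbias" and params.bias != 0.0:
        choices = np.empty(schedule.n_trials, dtype=bool)
        prev = 0.0
        for t in range(schedule.n_trials):
            p = float(choice_prob(dsv[t], params.tau, prev, params.bias))
            choices[t] = u[t] < p
            prev = 1.0 if choices[t] else -1.0
    else:
        choices = u < choice_prob(dsv, params.tau)
    sched = sample_outcomes(schedule, seed=rng.integers(2**31))
    return SessionData(
        subject_id=subject_id,
        drug=drug,
        session_order=session_order,
        schedule=sched,
        choices_left=choices,
        truth=params,
        model=spec.name,
    )


def _latin_square_orders(n_subjects: int) -> list[tuple[str, str, str]]:
    """Balanced 3-condition Latin-square drug orders cycled across subjects."""
    square = [
        ("placebo", "amisulpride", "ldopa"),
        ("amisulpride", "ldopa", "placebo"),
        ("ldopa", "placebo", "amisulpride"),
    ]
    return [square[i % 3] for i in range(n_subjects)]


def make_cohort(
    n_subjects: int = 31,
    group: GroupParams | None = None,
    shifts: DrugShifts | None = None,
    n_trials: int = 500,
    seed: int | None = None,
    model: str = "hybrid",
    corr_cap: float = 0.1,
) -> CohortData:
    """Simulate a full within-subject cohort.

    Subject latents are drawn from the group Normals; each session adds the
    drug's latent shift before the inverse-logit/exponential transforms; drug
    order follows a balanced Latin square.  One fresh schedule is generated
    per session.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    group = group or GroupParams()
    group.validate()
    shifts = shifts or DrugShifts()
    rng = np.random.default_rng(seed)
    orders = _latin_square_orders(n_subjects)
    sessions: list[SessionData] = []
    for s in range(n_subjects):
        lat = np.array([
            rng.normal(group.x_mult, group.sigma_mult),
            rng.normal(group.x_p, group.sigma_p),
            rng.normal(group.x_beta, group.sigma_beta),
        ])
        for order, drug in enumerate(orders[s], start=1):
            d = np.asarray(shifts.for_drug(drug))
            lm, lp, lb = lat + d
            params = ModelParams(
                omega_mult=float(expit(lm)),
                omega_p=float(expit(lp)),
                tau=float(np.exp(lb)),
            )
            sched = generate_schedule(
                n_trials=n_trials, corr_cap=corr_cap, seed=int(rng.integers(2**31))
            )
            sessions.append(
                simulate_agent(
                    sched, params, model=model, seed=int(rng.integers(2**31)),
                    subject_id=f"S{s + 1:02d}", drug=drug, session_order=order,
                )
            )
    cohort = CohortData(sessions=sessions, group_truth=(group, shifts))
    cohort.validate()
    return cohort
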
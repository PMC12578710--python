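"""Subjective-value models and the softmax choice rule.

Two-attribute risky options carry a reward magnitude (displayed on a 1-10
scale) and a reward probability.  A decision maker may integrate the two
attributes multiplicatively into an expected value, compare them additively
with a relative probability weight, or mix both strategies.  This module
implements that model family as pure, vectorized functions:

* ``sv_multiplicative`` — expected value, ``P * M``.
* ``sv_additive`` — weighted attribute comparison,
  ``omega_p * P + (1 - omega_p) * M``.
* ``sv_hybrid`` — convex mixture of the two, arbitrated by ``omega_mult``.
* ``sv_prospect`` — Prospect-Theory variants with power distortion of the
  magnitude (exponent ``alpha``) and/or the canonical single-parameter
  probability-weighting function (exponent ``gamma``).
* ``choice_prob`` — softmax (logistic) choice rule with inverse temperature
  ``tau`` and an optional previous-choice repetition bias.
* ``negloglik`` — per-session negative log-likelihood of a choice sequence.

Conventions fixed repo-wide: subjective-value differences are *left minus
right* and ``choice_prob`` returns the probability of choosing the left
option.  Magnitudes are divided by 10 (range 0.10-1.00, commensurate with
probabilities) for the multiplicative/additive/hybrid family and used raw
(1-10) for the Prospect-Theory family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "ModelSpec",
    "MODEL_SPECS",
    "PARAM_BOUNDS",
    "get_spec",
    "sv_multiplicative",
    "sv_additive",
    "sv_hybrid",
    "pt_probability_weight",
    "sv_prospect",
    "subjective_values",
    "delta_sv",
    "choice_prob",
    "repetition_terms",
    "negloglik",
]

#: Box bounds used for maximum-likelihood optimization and random restarts.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "omega_mult": (0.0, 1.0),
    "omega_p": (0.0, 1.0),
    "tau": (0.0, 100.0),
    "bias": (-5.0, 5.0),
    "alpha": (0.01, 5.0),
    "gamma": (0.01, 5.0),
}

#: Probability clipping applied inside ``negloglik`` to keep logs finite.
DEFAULT_EPS = 1e-12


@dataclass
class ModelParams:
    """Parameter set for any model in the family.

    Fields irrelevant to a given :class:`ModelSpec` are ignored by the value
    functions for that model.
    """

    omega_mult: float = 0.5
    omega_p: float = 0.5
    tau: float = 1.0
    bias: float = 0.0
    alpha: float = 1.0
    gamma: float = 1.0

    def to_dict(self) -> dict[str, float]:
        return {
            "omega_mult": self.omega_mult,
            "omega_p": self.omega_p,
            "tau": self.tau,
            "bias": self.bias,
            "alpha": self.alpha,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__})

    def validate(self, spec: "ModelSpec | None" = None) -> None:
        names = spec.free_params if spec is not None else tuple(PARAM_BOUNDS)
        for name in names:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class ModelSpec:
    """A named model: which parameters are free and how magnitudes scale."""

    name: str
    free_params: tuple[str, ...]
    scale_magnitude: bool  # True: displayed magnitude / 10; False: raw 1-10

    @property
    def k(self) -> int:
        """Number of free parameters (the BIC penalty count)."""
        return len(self.free_params)


MODEL_SPECS: dict[str, ModelSpec] = {
    "multiplicative": ModelSpec("multiplicative", ("tau",), True),
    "additive": ModelSpec("additive", ("omega_p", "tau"), True),
    "hybrid": ModelSpec("hybrid", ("omega_mult", "omega_p", "tau"), True),
    "hybrid_repbias": ModelSpec(
        "hybrid_repbias", ("omega_mult", "omega_p", "tau", "bias"), True
    ),
    "pt_magnitude": ModelSpec("pt_magnitude", ("alpha", "tau"), False),
    "pt_probability": ModelSpec("pt_probability", ("gamma", "tau"), False),
    "pt_both": ModelSpec("pt_both", ("alpha", "gamma", "tau"), False),
}


def get_spec(name: "str | ModelSpec") -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODEL_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; valid names: {sorted(MODEL_SPECS)}"
        ) from None


# ---------------------------------------------------------------------------
# Subjective-value functions
# ---------------------------------------------------------------------------

def _check_range(name, x, lo, hi, open_lo=False, open_hi=False):
    x = np.asarray(x, dtype=float)
    bad_lo = (x <= lo) if open_lo else (x < lo)
    bad_hi = (x >= hi) if open_hi else (x > hi)
    if np.any(bad_lo | bad_hi):
        raise ValueError(f"{name} outside admissible range ({lo}, {hi})")
    return x


def sv_multiplicative(P, M):
    """Expected value: ``P * M`` with magnitudes on the scaled 0.10-1.00 range."""
    P = _check_range("P", P, 0.0, 1.0)
    M = _check_range("M", M, 0.0, 1.0, open_lo=True)
    return P * M


def sv_additive(P, M, omega_p):
    """Weighted additive attribute comparison ``omega_p*P + (1-omega_p)*M``."""
    P = _check_range("P", P, 0.0, 1.0)
    M = _check_range("M", M, 0.0, 1.0, open_lo=True)
    omega_p = _check_range("omega_p", omega_p, 0.0, 1.0)
    return omega_p * P + (1.0 - omega_p) * M


def sv_hybrid(P, M, omega_mult, omega_p):
    """Convex mixture of the multiplicative and additive strategies."""
    P = _check_range("P", P, 0.0, 1.0)
    M = _check_range("M", M, 0.0, 1.0, open_lo=True)
    omega_mult = _check_range("omega_mult", omega_mult, 0.0, 1.0)
    omega_p = _check_range("omega_p", omega_p, 0.0, 1.0)
    return omega_mult * P * M + (1.0 - omega_mult) * (
        omega_p * P + (1.0 - omega_p) * M
    )


def pt_probability_weight(P, gamma):
    """One-parameter probability-weighting function.

    ``w(P) = P**gamma / (P**gamma + (1-P)**gamma) ** (1/gamma)``; ``gamma=1``
    is the identity, ``gamma<1`` produces the classic inverse-S overweighting
    of small probabilities.  Endpoints 0 and 1 are preserved.
    """
    if np.any(np.asarray(gamma, dtype=float) <= 0):
        raise ValueError("gamma must be > 0")
    P = _check_range("P", P, 0.0, 1.0)
    num = P**gamma
    return num / (num + (1.0 - P) ** gamma) ** (1.0 / gamma)


def sv_prospect(P, M_raw, alpha=1.0, gamma=1.0, variant="pt_both"):
    """Prospect-Theory subjective value on raw (1-10) magnitudes.

    ``variant`` selects which distortions are active: ``pt_magnitude`` warps
    only the magnitude (``M**alpha``), ``pt_probability`` only the
    probability, ``pt_both`` warps both.  Inactive exponents are pinned at 1.
    """
    if variant not in ("pt_magnitude", "pt_probability", "pt_both"):
        raise ValueError(f"invalid Prospect-Theory variant {variant!r}")
    P = _check_range("P", P, 0.0, 1.0)
    M_raw = np.asarray(M_raw, dtype=float)
    if np.any(M_raw <= 0):
        raise ValueError("magnitude must be positive")
    a = alpha if variant in ("pt_magnitude", "pt_both") else 1.0
    g = gamma if variant in ("pt_probability", "pt_both") else 1.0
    w = pt_probability_weight(P, g) if g != 1.0 else P
    return w * M_raw**a


# ---------------------------------------------------------------------------
# Model dispatch
# ---------------------------------------------------------------------------

def subjective_values(spec, params: ModelParams, magnitude, probability):
    """Subjective value of options under ``spec`` (vectorized, no validation
    of attribute ranges beyond what the underlying functions enforce)."""
    spec = get_spec(spec)
    M = np.asarray(magnitude, dtype=float)
    P = np.asarray(probability, dtype=float)
    if spec.scale_magnitude:
        M = M / 10.0
    name = spec.name
    if name == "multiplicative":
        return P * M
    if name == "additive":
        return params.omega_p * P + (1.0 - params.omega_p) * M
    if name in ("hybrid", "hybrid_repbias"):
        add = params.omega_p * P + (1.0 - params.omega_p) * M
        return params.omega_mult * P * M + (1.0 - params.omega_mult) * add
    if name in ("pt_magnitude", "pt_probability", "pt_both"):
        a = params.alpha if name in ("pt_magnitude", "pt_both") else 1.0
        g = params.gamma if name in ("pt_probability", "pt_both") else 1.0
        num = P**g
        w = num / (num + (1.0 - P) ** g) ** (1.0 / g)
        return w * M**a
    raise ValueError(f"unknown model {name!r}")


def delta_sv(spec, params: ModelParams, mag_left, mag_right, prob_left, prob_right):
    """Left-minus-right subjective value difference per trial."""
    spec = get_spec(spec)
    return subjective_values(spec, params, mag_left, prob_left) - subjective_values(
        spec, params, mag_right, prob_right
    )


# ---------------------------------------------------------------------------
# Choice rule and likelihood
# ---------------------------------------------------------------------------

def choice_prob(delta_sv, tau, rep_term=None, bias=None):
    """Softmax probability of a *left* choice.

    ``p = 1 / (1 + exp(-(delta_sv * tau + bias * rep_term)))`` where
    ``rep_term`` is +1 if the previous choice was left, -1 if right, 0 on the
    first trial.  Without the repetition extension the bias term is omitted.
    Numerically safe for arbitrarily large arguments.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    arg = np.asarray(delta_sv, dtype=float) * tau
    if rep_term is not None and bias is not None:
        arg = arg + np.asarray(bias, dtype=float) * np.asarray(rep_term, dtype=float)
    return expit(arg)


def repetition_terms(choices_left, first_trial_mask=None):
    """Previous-choice coding: +1 after a left choice, -1 after right, 0 on
    the first trial of a session.

    ``choices_left`` is a 0/1 (or boolean) array ordered by trial;
    ``first_trial_mask`` marks session starts (defaults to the first element
    only).
    """
    c = np.asarray(choices_left).astype(float)
    rep = np.empty_like(c)
    rep[0] = 0.0
    rep[1:] = 2.0 * c[:-1] - 1.0
    if first_trial_mask is not None:
        rep[np.asarray(first_trial_mask, dtype=bool)] = 0.0
    return rep


def _session_arrays(session):
    """Duck-typed access: accepts a SessionData or any object with a
    ``schedule`` carrying attribute arrays plus ``choices_left``."""
    sched = getattr(session, "schedule", session)
    return (
        np.asarray(sched.mag_left, dtype=float),
        np.asarray(sched.mag_right, dtype=float),
        np.asarray(sched.prob_left, dtype=float),
        np.asarray(sched.prob_right, dtype=float),
        np.asarray(session.choices_left, dtype=bool),
    )


def negloglik(session, spec, params: ModelParams, eps: float = DEFAULT_EPS):
    """Negative log-likelihood of one session's choices under a model.

    Per-trial left-choice probabilities are clipped to ``[eps, 1-eps]`` so the
    result is always finite.  With the repetition-bias extension the
    previous *observed* choice feeds the bias term.
    """
    spec = get_spec(spec)
    ml, mr, pl, pr = _session_arrays(session)[:4]
    chose_left = _session_arrays(session)[4]
    dsv = delta_sv(spec, params, ml, mr, pl, pr)
    if spec.name == "hybrid_repbias":
        rep = repetition_terms(chose_left)
        p_left = choice_prob(dsv, params.tau, rep, params.bias)
    else:
        p_left = choice_prob(dsv, params.tau)
    p_left = np.clip(p_left, eps, 1.0 - eps)
    p_choice = np.where(chose_left, p_left, 1.0 - p_left)
    return float(-np.sum(np.log(p_choice)))
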
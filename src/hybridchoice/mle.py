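"""Per-session maximum-likelihood fitting and BIC model comparison.

Each subject x drug session is fitted independently by minimizing the
session negative log-likelihood with a bound-constrained derivative-free
optimizer (Powell's method with box bounds), restarted from multiple random
initial points drawn uniformly within the parameter bounds.  Model selection
across the family uses the Bayesian Information Criterion,
``BIC = k * ln(n_trials) + 2 * negloglik``, averaged across sessions.

The estimator :class:`SoftmaxChoiceMLE` follows scikit-learn conventions
(``fit``/``predict_proba``, ``get_params``, trailing-underscore fitted
attributes); :func:`fit_session` and :func:`compare_models` are thin
functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .models import (
    MODEL_SPECS,
    PARAM_BOUNDS,
    ModelParams,
    ModelSpec,
    choice_prob,
    delta_sv,
    get_spec,
    negloglik,
    repetition_terms,
)
from .task import CohortData, SessionData

__all__ = [
    "FitResult",
    "ModelComparisonTable",
    "SoftmaxChoiceMLE",
    "bic",
    "fit_session",
    "compare_models",
]


def bic(negll: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: ``k * ln(n) + 2 * negll``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) + 2.0 * negll


@dataclass
class FitResult:
    """Outcome of one session fit."""

    spec: ModelSpec
    params: ModelParams
    negll: float
    bic: float
    n_restarts_used: int
    converged: bool
    best_restart_seed: int


class SoftmaxChoiceMLE(BaseEstimator):
    """Maximum-likelihood softmax choice model for one session.

    Parameters
    ----------
    model : str
        One of the family names (``multiplicative``, ``additive``,
        ``hybrid``, ``hybrid_repbias``, ``pt_magnitude``, ``pt_probability``,
        ``pt_both``).
    n_restarts : int
        Random restarts of the optimizer; initial values are drawn uniformly
        within the parameter box from ``seed`` as a single sequential stream,
        so restarts are nested: the first ``k`` restarts of a larger run are
        identical to a run with ``n_restarts=k``.
    maxeval, xtol_rel : optimizer budget and relative-change stopping rule
        passed to the bound-constrained derivative-free optimizer.
    seed : int
        Restart-stream seed; fitting is deterministic given it.

    Attributes
    ----------
    params_ : ModelParams — best-likelihood parameter estimates.
    negll_ : float — minimized negative log-likelihood.
    bic_ : float — ``k ln(n) + 2 negll``.
    converged_ : bool — whether the best restart reported convergence.
    result_ : FitResult — full record.
    """

    def __init__(self, model="hybrid", n_restarts=100, maxeval=10000,
                 xtol_rel=1.0e-08, seed=None):
        self.model = model
        self.n_restarts = n_restarts
        self.maxeval = maxeval
        self.xtol_rel = xtol_rel
        self.seed = seed

    # -- data marshalling ---------------------------------------------------

    @staticmethod
    def _extract(X, y):
        if isinstance(X, SessionData):
            s = X.schedule
            return (np.asarray(s.mag_left, float), np.asarray(s.mag_right, float),
                    np.asarray(s.prob_left, float), np.asarray(s.prob_right, float),
                    np.asarray(X.choices_left, bool))
        X = pd.DataFrame(X)
        cols = ("mag_left", "mag_right", "prob_left", "prob_right")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"missing trial columns: {missing}")
        if y is None:
            if "choice" not in X.columns:
                raise ValueError("y (choices) required when X has no 'choice' column")
            y = X["choice"]
        y = np.asarray(y)
        if y.dtype.kind in "OU":
            chose_left = np.char.upper(y.astype(str)) == "L"
        else:
            chose_left = y.astype(bool)
        return tuple(X[c].to_numpy(float) for c in cols) + (chose_left,)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the model to one session.

        ``X`` may be a :class:`~hybridchoice.task.SessionData` or a tabular
        object with columns ``mag_left, mag_right, prob_left, prob_right``
        (plus ``choice`` if ``y`` is not given); ``y`` holds choices as
        'L'/'R' strings or 1/0 with 1 = left.
        """
        spec = get_spec(self.model)
        ml, mr, pl, pr, chose_left = self._extract(X, y)
        n = len(ml)
        if n < 2:
            raise ValueError("need at least 2 trials to fit")
        sign = np.where(chose_left, 1.0, -1.0)
        rep = repetition_terms(chose_left) if "bias" in spec.free_params else None

        # Precompute choice-signed value-difference components so each
        # objective evaluation is a handful of vector ops.
        Ml, Mr = ml / 10.0, mr / 10.0
        sd_pm = sign * (pl * Ml - pr * Mr)
        sd_p = sign * (pl - pr)
        sd_m = sign * (Ml - Mr)
        srep = sign * rep if rep is not None else None

        names = spec.free_params
        lo = np.array([PARAM_BOUNDS[p][0] for p in names])
        hi = np.array([PARAM_BOUNDS[p][1] for p in names])
        logaddexp = np.logaddexp

        if spec.name == "multiplicative":
            def objective(theta):
                return float(logaddexp(0.0, sd_pm * -theta[0]).sum())
        elif spec.name == "additive":
            def objective(theta):
                op, tau = theta
                return float(logaddexp(
                    0.0, (op * sd_p + (1.0 - op) * sd_m) * -tau).sum())
        elif spec.name == "hybrid":
            def objective(theta):
                om, op, tau = theta
                z = om * sd_pm + (1.0 - om) * (op * sd_p + (1.0 - op) * sd_m)
                return float(logaddexp(0.0, z * -tau).sum())
        elif spec.name == "hybrid_repbias":
            def objective(theta):
                om, op, tau, bias = theta
                z = om * sd_pm + (1.0 - om) * (op * sd_p + (1.0 - op) * sd_m)
                return float(logaddexp(0.0, -(z * tau + bias * srep)).sum())
        else:
            i_tau = names.index("tau")

            def objective(theta):
                d = dict(zip(names, theta))
                p = ModelParams(alpha=d.get("alpha", 1.0), gamma=d.get("gamma", 1.0))
                dsv = delta_sv(spec, p, ml, mr, pl, pr)
                return float(logaddexp(0.0, sign * dsv * -theta[i_tau]).sum())

        rng = np.random.default_rng(self.seed)
        best = None
        for r in range(self.n_restarts):
            x0 = rng.uniform(lo, hi)
            try:
                res = minimize(
                    objective, x0, method="Powell",
                    bounds=list(zip(lo, hi)),
                    options={"maxfev": self.maxeval, "xtol": self.xtol_rel,
                             "ftol": self.xtol_rel},
                )
            except Exception:  # noqa: BLE001 — a failed restart is not fatal
                continue
            if best is None or res.fun < best[0]:
                best = (float(res.fun), res.x.copy(), bool(res.success), r)
        if best is None:
            raise RuntimeError("all optimizer restarts failed to evaluate")

        negll, theta, success, r_best = best
        params = ModelParams(**dict(zip(names, map(float, theta))))
        self.spec_ = spec
        self.params_ = params
        self.negll_ = negll
        self.bic_ = bic(negll, spec.k, n)
        self.n_trials_ = n
        self.converged_ = success
        self.result_ = FitResult(
            spec=spec, params=params, negll=negll, bic=self.bic_,
            n_restarts_used=self.n_restarts, converged=success,
            best_restart_seed=r_best,
        )
        return self

    def predict_proba(self, X):
        """Per-trial [P(right), P(left)] under the fitted parameters."""
        ml, mr, pl, pr = self._extract_X_only(X)
        dsv = delta_sv(self.spec_, self.params_, ml, mr, pl, pr)
        p_left = choice_prob(dsv, self.params_.tau)
        return np.column_stack([1.0 - p_left, p_left])

    @staticmethod
    def _extract_X_only(X):
        if isinstance(X, SessionData):
            s = X.schedule
            return s.mag_left, s.mag_right, s.prob_left, s.prob_right
        X = pd.DataFrame(X)
        return tuple(X[c].to_numpy(float)
                     for c in ("mag_left", "mag_right", "prob_left", "prob_right"))


def fit_session(session, spec="hybrid", n_restarts=100, maxeval=10000,
                xtol_rel=1.0e-08, seed=None) -> FitResult:
    """Fit one model to one session; returns the :class:`FitResult`."""
    name = spec.name if isinstance(spec, ModelSpec) else spec
    est = SoftmaxChoiceMLE(model=name, n_restarts=n_restarts, maxeval=maxeval,
                           xtol_rel=xtol_rel, seed=seed)
    est.fit(session)
    return est.result_


@dataclass
class ModelComparisonTable:
    """Mean (SE) of per-session BIC for each candidate model."""

    table: pd.DataFrame  # index: model; columns: mean_bic, se_bic, n_sessions, k
    best_model: str
    n_failures: int = 0

    def __str__(self) -> str:
        lines = ["model  mean_bic (se)"]
        for name, row in self.table.iterrows():
            se = "NA" if np.isnan(row.se_bic) else f"{row.se_bic:.2f}"
            lines.append(f"{name}: {row.mean_bic:.2f} ({se})")
        lines.append(f"best: {self.best_model}")
        return "\n".join(lines)


def compare_models(cohort: CohortData, specs=("multiplicative", "additive", "hybrid"),
                   n_restarts=100, seed=None) -> ModelComparisonTable:
    """Fit every candidate model to every session and rank by mean BIC.

    Sessions whose fit fails are excluded from that model's mean with a
    counted failure; ties in mean BIC break toward fewer free parameters.
    """
    rng = np.random.default_rng(seed)
    rows, n_failures = [], 0
    specs = [get_spec(s) for s in specs]
    fit_seeds = {
        (spec.name, i): int(rng.integers(2**31))
        for spec in specs for i in range(len(cohort.sessions))
    }
    for spec in specs:
        bics = []
        for i, session in enumerate(cohort.sessions):
            try:
                fr = fit_session(session, spec, n_restarts=n_restarts,
                                 seed=fit_seeds[(spec.name, i)])
                bics.append(fr.bic)
            except RuntimeError:
                n_failures += 1
        bics = np.asarray(bics)
        se = float(bics.std(ddof=1) / math.sqrt(len(bics))) if len(bics) > 1 else float("nan")
        rows.append({"model": spec.name, "mean_bic": float(bics.mean()),
                     "se_bic": se, "n_sessions": len(bics), "k": spec.k})
    table = pd.DataFrame(rows).set_index("model")
    # minimal mean BIC; ties toward fewer parameters
    order = table.sort_values(["mean_bic", "k"])
    return ModelComparisonTable(table=table, best_model=str(order.index[0]),
                                n_failures=n_failures)
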
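"""Binomial mixed-effects regression stage.

Trial-level choice (right vs. left option) is regressed on z-scored
right-minus-left attribute differences (reward magnitude, reward
probability, mean-centered expected value), a previous-choice repetition
regressor, drug dummies (amisulpride and L-DOPA, each vs. placebo) and all
drug x predictor interactions, with by-subject random effects.

The model is a logistic GLMM estimated by maximum likelihood with a Laplace
approximation to the marginal likelihood: for each subject the random-effect
vector is profiled out at its conditional mode (inner Newton iterations,
globally concave), and the fixed effects plus the Cholesky-parameterized
random-effect covariance are optimized in an outer quasi-Newton loop.
Inference on fixed effects uses asymptotic Wald tests conditional on the
estimated variance components, and the marginal (fixed-effects) R-squared
follows the Nakagawa-Schielzeth definition for logit models (residual
variance pi^2 / 3).

Random-effect structure selection mirrors the principal-component check:
components of the estimated random-effect covariance that explain 0.00% of
the random variance (share below a two-decimal rounding tolerance) flag the
smallest-variance term for removal, and the model is refitted until stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .task import CohortData

__all__ = [
    "DesignMatrix",
    "GlmmFit",
    "BinomialGLMM",
    "build_design",
    "fit_glmm",
    "prune_random_effects",
]

FIXED_PREDICTORS = ("mag_diff", "prob_diff", "ev_diff", "repetition")
DRUG_DUMMIES = ("amisulpride", "ldopa")
DEFAULT_RANDOM_TERMS = ("intercept", "amisulpride", "ldopa",
                        "mag_diff", "prob_diff", "ev_diff")
#: a PCA share below this counts as "0.00%" (two-decimal percentage rounding)
ZERO_VARIANCE_SHARE = 5e-5


@dataclass
class DesignMatrix:
    """Trial-level design: response, fixed-effect columns, subject grouping."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray           # 1 = right option chosen
    groups: np.ndarray      # integer subject codes
    group_labels: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def col(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def build_design(cohort: CohortData, z_scope: str = "pooled",
                 extra_fixed: pd.DataFrame | None = None) -> DesignMatrix:
    """Build the regression design from a cohort.

    Differences are right minus left; the response is 1 iff the right option
    was chosen; the repetition regressor is +1 after a right choice, -1
    after a left choice, 0 on each session's first trial.  The
    "mean-centered EV" of each option is ``(M - mean M) * (P - mean P)``
    with means over all options presented in that session, decorrelating it
    from the raw attributes.  Attribute columns are z-scored over all
    included trials (``z_scope='session'`` rescales within each session).
    Drug dummy columns identically zero (e.g. placebo-only cohorts) are
    dropped, together with their interactions, with a warning.
    """
    if z_scope not in ("pooled", "session"):
        raise ValueError("z_scope must be 'pooled' or 'session'")
    rows = {k: [] for k in ("y", "mag_diff", "prob_diff", "ev_diff",
                            "repetition", "amisulpride", "ldopa", "subject")}
    for s in cohort.sessions:
        sc = s.schedule
        chose_right = ~np.asarray(s.choices_left, bool)
        Ml, Mr = sc.mag_left / 10.0, sc.mag_right / 10.0
        Pl, Pr = sc.prob_left, sc.prob_right
        mean_m = np.concatenate([Ml, Mr]).mean()
        mean_p = np.concatenate([Pl, Pr]).mean()
        ev_l = (Ml - mean_m) * (Pl - mean_p)
        ev_r = (Mr - mean_m) * (Pr - mean_p)
        rep = np.zeros(s.n_trials)
        rep[1:] = np.where(chose_right[:-1], 1.0, -1.0)
        md, pdiff, evd = Mr - Ml, Pr - Pl, ev_r - ev_l
        if z_scope == "session":
            md, pdiff, evd = _zscore(md), _zscore(pdiff), _zscore(evd)
        rows["y"].append(chose_right.astype(float))
        rows["mag_diff"].append(md)
        rows["prob_diff"].append(pdiff)
        rows["ev_diff"].append(evd)
        rows["repetition"].append(rep)
        rows["amisulpride"].append(np.full(s.n_trials, float(s.drug == "amisulpride")))
        rows["ldopa"].append(np.full(s.n_trials, float(s.drug == "ldopa")))
        rows["subject"].append(np.repeat(s.subject_id, s.n_trials))
    data = {k: np.concatenate(v) for k, v in rows.items()}
    if z_scope == "pooled":
        for c in ("mag_diff", "prob_diff", "ev_diff"):
            data[c] = _zscore(data[c])

    dummies = [d for d in DRUG_DUMMIES if data[d].any()]
    dropped = set(DRUG_DUMMIES) - set(dummies)
    if dropped:
        warnings.warn(
            f"drug dummy column(s) {sorted(dropped)} are identically zero; "
            "dropping them and their interactions", stacklevel=2,
        )
    columns = ["intercept", *FIXED_PREDICTORS, *dummies]
    mats = [np.ones_like(data["y"])] + [data[c] for c in FIXED_PREDICTORS] \
        + [data[d] for d in dummies]
    for d in dummies:
        for p in FIXED_PREDICTORS:
            columns.append(f"{d}:{p}")
            mats.append(data[d] * data[p])
    if extra_fixed is not None:
        for c in extra_fixed.columns:
            columns.append(str(c))
            mats.append(np.asarray(extra_fixed[c], dtype=float))
    labels = list(dict.fromkeys(data["subject"]))
    codes = np.array([labels.index(s) for s in data["subject"]])
    return DesignMatrix(X=np.column_stack(mats), columns=columns,
                        y=data["y"], groups=codes, group_labels=labels)


@dataclass
class GlmmFit:
    """Fitted mixed model: Wald table, variance components, marginal R^2."""

    coef_table: pd.DataFrame   # index term; columns beta, se, z, p
    Sigma: np.ndarray          # random-effect covariance (q x q)
    random_terms: tuple[str, ...]
    marginal_r2: float
    negll: float
    n_obs: int
    converged: bool
    message: str = ""
    design: DesignMatrix | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> pd.Series:
        return self.coef_table["beta"]


class _LaplaceLogistic:
    """Laplace-approximate marginal negative log-likelihood machinery."""

    def __init__(self, design: DesignMatrix, random_terms, cov_structure):
        self.d = design
        self.random_terms = tuple(random_terms)
        self.q = len(self.random_terms)
        self.cov_structure = cov_structure
        self.p = design.X.shape[1]
        Zcols = []
        for t in self.random_terms:
            if t == "intercept":
                Zcols.append(np.ones(design.n_obs))
            else:
                Zcols.append(design.col(t))
        Z = np.column_stack(Zcols)
        self.group_rows = [np.flatnonzero(design.groups == g)
                           for g in range(len(design.group_labels))]
        self.Xg = [design.X[r] for r in self.group_rows]
        self.Zg = [Z[r] for r in self.group_rows]
        self.yg = [design.y[r] for r in self.group_rows]
        self.n_theta = self.q if cov_structure == "diagonal" \
            else self.q + self.q * (self.q - 1) // 2
        self._bhat = [np.zeros(self.q) for _ in self.group_rows]

    def chol(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        L[np.diag_indices(self.q)] = np.exp(theta[: self.q])
        if self.cov_structure == "full" and self.q > 1:
            L[np.tril_indices(self.q, -1)] = theta[self.q:]
        return L

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        L = self.chol(theta)
        return L @ L.T

    def split(self, x: np.ndarray):
        return x[: self.p], x[self.p:]

    def negll(self, x: np.ndarray) -> float:
        beta, theta = self.split(x)
        L = self.chol(theta)
        # Sigma^{-1} via Cholesky; logdet(Sigma) = 2 sum log diag(L)
        logdet_sigma = 2.0 * float(np.sum(theta[: self.q]))
        Linv = np.linalg.inv(L)
        Sinv = Linv.T @ Linv
        total = 0.0
        for g, (Xi, Zi, yi) in enumerate(zip(self.Xg, self.Zg, self.yg)):
            off = Xi @ beta
            b = self._bhat[g].copy()
            # Newton ascent on the (concave) joint log-density in b
            for _ in range(50):
                eta = off + Zi @ b
                mu = expit(eta)
                grad = Zi.T @ (yi - mu) - Sinv @ b
                if float(np.max(np.abs(grad))) < 1e-9:
                    break
                W = mu * (1.0 - mu)
                H = (Zi * W[:, None]).T @ Zi + Sinv
                step = np.linalg.solve(H, grad)
                # damped update: backtrack if the objective decreases
                f0 = float(yi @ eta - np.logaddexp(0.0, eta).sum()
                           - 0.5 * b @ Sinv @ b)
                t = 1.0
                for _ in range(20):
                    bn = b + t * step
                    etan = off + Zi @ bn
                    fn = float(yi @ etan - np.logaddexp(0.0, etan).sum()
                               - 0.5 * bn @ Sinv @ bn)
                    if fn >= f0:
                        break
                    t *= 0.5
                b = bn
            self._bhat[g] = b
            eta = off + Zi @ b
            mu = expit(eta)
            W = mu * (1.0 - mu)
            H = (Zi * W[:, None]).T @ Zi + Sinv
            sign, logdet_H = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            ll = float(yi @ eta - np.logaddexp(0.0, eta).sum()
                       - 0.5 * b @ Sinv @ b
                       - 0.5 * logdet_sigma - 0.5 * logdet_H)
            total += ll
        return -total


def fit_glmm(design: DesignMatrix,
             random_spec=DEFAULT_RANDOM_TERMS,
             cov_structure: str = "diagonal",
             maxiter: int = 300) -> GlmmFit:
    """Fit the logistic mixed model by Laplace maximum likelihood.

    ``random_spec`` lists by-subject random terms ('intercept' plus fixed
    column names); terms whose column is absent from the design (e.g.
    dropped drug dummies) are ignored.  Raises for single-subject data,
    where random effects are unidentifiable.
    """
    if len(design.group_labels) < 2:
        raise ValueError("random effects are unidentifiable with a single subject")
    random_terms = tuple(t for t in random_spec
                         if t == "intercept" or t in design.columns)
    if not random_terms:
        raise ValueError("random_spec selected no usable terms")
    lap = _LaplaceLogistic(design, random_terms, cov_structure)

    x0 = np.zeros(lap.p + lap.n_theta)
    x0[lap.p: lap.p + lap.q] = math.log(0.3)
    bounds = [(None, None)] * lap.p + [(-6.0, 3.0)] * lap.q \
        + [(-5.0, 5.0)] * (lap.n_theta - lap.q)
    res = minimize(lap.negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6})
    if not res.success:
        warnings.warn(f"GLMM optimizer did not report convergence: {res.message} "
                      f"(|grad|max={np.max(np.abs(res.jac)):.3g})", stacklevel=2)

    beta, theta = lap.split(res.x)
    Sigma = lap.sigma(theta)

    # Wald SEs: finite-difference Hessian over beta, conditional on theta-hat
    p = lap.p
    h = 1e-4 * np.maximum(1.0, np.abs(beta))
    f0 = res.fun

    def f_beta(b):
        return lap.negll(np.concatenate([b, theta]))

    H = np.zeros((p, p))
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f_beta(beta + e)
        fm[i] = f_beta(beta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            e = np.zeros(p); e[i] = h[i]; e[j] = h[j]
            fpp = f_beta(beta + e)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pval = 2.0 * norm.sf(np.abs(zval))
    table = pd.DataFrame({"beta": beta, "se": se, "z": zval, "p": pval},
                         index=design.columns)

    # Nakagawa-Schielzeth marginal R^2 for logit models
    eta_fix = design.X @ beta
    var_fix = float(np.var(eta_fix))
    Z = np.column_stack([np.ones(design.n_obs) if t == "intercept"
                         else design.col(t) for t in random_terms])
    var_rand = float(np.mean(np.einsum("ij,jk,ik->i", Z, Sigma, Z)))
    r2m = var_fix / (var_fix + var_rand + math.pi**2 / 3.0)

    return GlmmFit(coef_table=table, Sigma=Sigma, random_terms=random_terms,
                   marginal_r2=r2m, negll=float(res.fun), n_obs=design.n_obs,
                   converged=bool(res.success), message=str(res.message),
                   design=design)


def prune_random_effects(fit: GlmmFit, design: DesignMatrix | None = None,
                         cov_structure: str = "diagonal",
                         tol_share: float = ZERO_VARIANCE_SHARE):
    """Drop random components explaining 0.00% of the random variance.

    Principal components of the estimated random-effect covariance are
    inspected; while any component's share of total random variance falls
    below ``tol_share`` (i.e. rounds to 0.00%), the term with the smallest
    estimated variance is removed and the model refitted.  Returns the final
    ``(random_terms, fit)``.
    """
    design = design or fit.design
    if design is None:
        raise ValueError("design required for refitting during pruning")
    terms = tuple(fit.random_terms)
    current = fit
    while len(terms) > 1:
        eigvals = np.clip(np.linalg.eigvalsh(current.Sigma), 0.0, None)
        total = float(eigvals.sum())
        if total <= 0:
            terms = terms[:1]
            current = fit_glmm(design, random_spec=terms,
                               cov_structure=cov_structure)
            break
        if float(eigvals.min()) / total >= tol_share:
            break
        drop = int(np.argmin(np.diag(current.Sigma)))
        terms = tuple(t for i, t in enumerate(terms) if i != drop)
        current = fit_glmm(design, random_spec=terms, cov_structure=cov_structure)
    return terms, current


class BinomialGLMM(BaseEstimator):
    """scikit-learn style estimator for the choice GLMM.

    ``fit`` accepts a :class:`~hybridchoice.task.CohortData` (the design is
    built internally) or a prebuilt :class:`DesignMatrix`.  Fitted
    attributes: ``coef_table_``, ``Sigma_``, ``random_terms_``,
    ``marginal_r2_``, ``result_``.
    """

    def __init__(self, random_terms=DEFAULT_RANDOM_TERMS,
                 cov_structure="diagonal", prune=True, z_scope="pooled",
                 maxiter=300):
        self.random_terms = random_terms
        self.cov_structure = cov_structure
        self.prune = prune
        self.z_scope = z_scope
        self.maxiter = maxiter

    def fit(self, X, y=None):
        design = X if isinstance(X, DesignMatrix) else build_design(
            X, z_scope=self.z_scope)
        fit = fit_glmm(design, random_spec=self.random_terms,
                       cov_structure=self.cov_structure, maxiter=self.maxiter)
        if self.prune:
            terms, fit = prune_random_effects(
                fit, design, cov_structure=self.cov_structure)
        self.design_ = design
        self.result_ = fit
        self.coef_table_ = fit.coef_table
        self.Sigma_ = fit.Sigma
        self.random_terms_ = fit.random_terms
        self.marginal_r2_ = fit.marginal_r2
        return self
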
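"""Hierarchical Bayesian model with per-drug parameter shifts.

The winning subjective-value model (the hybrid mixture by default; the
two-distortion Prospect-Theory variant is also supported) is embedded in a
three-level hierarchy.  Each subject s has latent parameters

    x_{s,j} = X_j + sigma_j * z_{s,j},      z_{s,j} ~ N(0, 1)

on an unconstrained scale; an inverse-logit transform maps the latents of
``omega_mult`` and ``omega_p`` into (0, 1) and an exponential transform maps
the inverse-temperature latent onto (0, inf).  Non-placebo sessions add the
drug's group-level latent shift *before* the transform:

    latent(session) = x_{s,j} + delta_{drug,j}

Hyperpriors: X_mult, X_p ~ N(0, 2); X_beta ~ N(2, 3); sigma_j ~
half-Cauchy(scale 2); the six shifts delta ~ N(0, 3).  A drug shift is
called significant when its 95% interval excludes zero.

Sampling uses an affine-invariant ensemble MCMC sampler (emcee) with a
fully vectorized log-posterior; the requested ``chains x draws`` schedule is
mapped onto the walker ensemble (walkers are partitioned into ``chains``
groups, whose kept draws are evenly thinned to exactly ``draws`` each), and
convergence is checked with rank-normalized R-hat (< 1.05) and effective
sample size via arviz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .task import CohortData

__all__ = [
    "HierarchicalModel",
    "PosteriorDraws",
    "PosteriorSummary",
    "PPCResult",
    "HierarchicalChoiceModel",
    "build_model",
    "sample_posterior",
    "summarize",
    "posterior_predictive",
    "hdi",
]

_SHIFT_DRUGS = ("amisulpride", "ldopa")

# latent parameter names and natural-scale names per supported model
_PARAM_NAMES = {
    "hybrid": ("omega_mult", "omega_p", "tau"),
    "pt_both": ("alpha", "gamma", "tau"),
}
# hyperprior (mean, sd) of the group means X_j
_MU_PRIORS = {
    "hybrid": ((0.0, 2.0), (0.0, 2.0), (2.0, 3.0)),
    "pt_both": ((0.0, 2.0), (0.0, 2.0), (0.0, 3.0)),
}
_SIGMA_SCALE = 2.0  # half-Cauchy scale of the group SDs
_SHIFT_SD = 3.0  # N(0, 3) shift hyperprior


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the (flattened) draws."""
    x = np.sort(np.asarray(draws).ravel())
    n = len(x)
    m = max(1, int(math.ceil(prob * n)))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


class HierarchicalModel:
    """Data + log-posterior of the hierarchy, vectorized over walkers.

    Parameter vector layout (D = 6 + 6*include_shifts + 3*S):
    ``[X(3), log_sigma(3), shifts(6: ami x 3, ldopa x 3), z(S, 3)]``.
    """

    def __init__(self, cohort: CohortData, include_shifts: bool = True,
                 model: str = "hybrid", require_complete: bool = True):
        if model not in _PARAM_NAMES:
            raise ValueError(f"hierarchical model supports {sorted(_PARAM_NAMES)}")
        if require_complete:
            cohort.validate()
        self.model = model
        self.include_shifts = include_shifts
        self.cohort = cohort
        self.subjects = cohort.subjects
        self.n_subjects = len(self.subjects)
        subj_index = {s: i for i, s in enumerate(self.subjects)}

        sessions = cohort.sessions
        self.session_subject = np.array([subj_index[s.subject_id] for s in sessions])
        self.session_drug = np.array(
            [_SHIFT_DRUGS.index(s.drug) + 1 if s.drug in _SHIFT_DRUGS else 0
             for s in sessions]
        )
        T = max(s.n_trials for s in sessions)
        S = len(sessions)
        # choice-signed value-difference components; padded cells contribute
        # a constant log(2) to every evaluation (harmless for MCMC)
        self._sd_pm = np.zeros((S, T))
        self._sd_p = np.zeros((S, T))
        self._sd_m = np.zeros((S, T))
        self._smag_l = np.zeros((S, T))
        self._smag_r = np.zeros((S, T))
        self._sprob_l = np.zeros((S, T))
        self._sprob_r = np.zeros((S, T))
        self._sign = np.zeros((S, T))
        for i, s in enumerate(sessions):
            sc, t = s.schedule, s.n_trials
            sign = np.where(np.asarray(s.choices_left, bool), 1.0, -1.0)
            Ml, Mr = sc.mag_left / 10.0, sc.mag_right / 10.0
            self._sd_pm[i, :t] = sign * (sc.prob_left * Ml - sc.prob_right * Mr)
            self._sd_p[i, :t] = sign * (sc.prob_left - sc.prob_right)
            self._sd_m[i, :t] = sign * (Ml - Mr)
            self._smag_l[i, :t] = sc.mag_left
            self._smag_r[i, :t] = sc.mag_right
            self._sprob_l[i, :t] = sc.prob_left
            self._sprob_r[i, :t] = sc.prob_right
            self._sign[i, :t] = sign
        self.n_sessions = S
        self.ndim = 6 + (6 if include_shifts else 0) + 3 * self.n_subjects
        self.param_names = _PARAM_NAMES[model]
        self._mu_priors = _MU_PRIORS[model]

    # -- parameter unpacking ------------------------------------------------

    def _unpack(self, theta):
        """theta: (W, D) -> dict of views."""
        W = theta.shape[0]
        X = theta[:, 0:3]
        log_sigma = theta[:, 3:6]
        off = 6
        if self.include_shifts:
            shifts = theta[:, 6:12].reshape(W, 2, 3)
            off = 12
        else:
            shifts = np.zeros((W, 2, 3))
        z = theta[:, off:].reshape(W, self.n_subjects, 3)
        return X, log_sigma, shifts, z

    def session_latents(self, theta):
        """Per-session latent parameters, shape (W, n_sessions, 3)."""
        X, log_sigma, shifts, z = self._unpack(theta)
        sigma = np.exp(log_sigma)
        x_subj = X[:, None, :] + sigma[:, None, :] * z  # (W, subj, 3)
        lat = x_subj[:, self.session_subject, :]
        drug = self.session_drug  # 0 placebo, 1 ami, 2 ldopa
        shift_full = np.concatenate([np.zeros_like(shifts[:, :1]), shifts], axis=1)
        lat = lat + shift_full[:, drug, :]
        return lat

    def _signed_dsv(self, lat):
        """Choice-signed subjective-value difference, (W, S, T)."""
        if self.model == "hybrid":
            om = expit(lat[:, :, 0])[:, :, None]
            op = expit(lat[:, :, 1])[:, :, None]
            add = op * self._sd_p[None] + (1.0 - op) * self._sd_m[None]
            return om * self._sd_pm[None] + (1.0 - om) * add
        # pt_both: alpha/gamma positive via exp transform, raw magnitudes;
        # exponents clipped to a numerically safe range (the prior keeps the
        # posterior far from these limits)
        a = np.exp(np.clip(lat[:, :, 0], -7.0, 3.0))[:, :, None]
        g = np.exp(np.clip(lat[:, :, 1], -7.0, 3.0))[:, :, None]
        pl, pr = self._sprob_l[None], self._sprob_r[None]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            wl = pl**g / (pl**g + (1.0 - pl) ** g) ** (1.0 / g)
            wr = pr**g / (pr**g + (1.0 - pr) ** g) ** (1.0 / g)
        sv = wl * self._smag_l[None] ** a - wr * self._smag_r[None] ** a
        return np.nan_to_num(self._sign[None] * sv)

    def log_prob(self, theta):
        """Vectorized log posterior; theta has shape (W, D) or (D,)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        X, log_sigma, shifts, z = self._unpack(theta)
        sigma = np.exp(log_sigma)

        lp = np.zeros(theta.shape[0])
        for j, (m, sd) in enumerate(self._mu_priors):
            lp += -0.5 * ((X[:, j] - m) / sd) ** 2
        # half-Cauchy(2) on sigma, sampled as log(sigma): + Jacobian log sigma
        lp += np.sum(-np.log1p((sigma / _SIGMA_SCALE) ** 2) + log_sigma, axis=1)
        if self.include_shifts:
            lp += np.sum(-0.5 * (shifts / _SHIFT_SD) ** 2, axis=(1, 2))
        lp += np.sum(-0.5 * z**2, axis=(1, 2))

        lat = self.session_latents(theta)
        zarg = np.exp(np.clip(lat[:, :, 2], -30.0, 30.0))[:, :, None] \
            * self._signed_dsv(lat)
        lp += -np.sum(np.logaddexp(0.0, -zarg), axis=(1, 2))
        return lp if lp.shape[0] > 1 else float(lp[0])

    # -- initialization & prior ---------------------------------------------

    def initial_vector(self) -> np.ndarray:
        """Group means at hyperprior centers, shifts at 0, subject offsets 0."""
        x0 = np.zeros(self.ndim)
        x0[0:3] = [m for m, _ in self._mu_priors]
        x0[3:6] = math.log(0.5)  # modest initial group spread
        return x0

    def data_informed_init(self, seed=None) -> np.ndarray:
        """Initialization from quick per-session ML fits.

        Each session gets a small-budget maximum-likelihood fit; subject
        latents start at the subject's mean fitted latents, group means and
        SDs at their across-subject mean and SD, shifts at 0 (as stated for
        the full model).  This places the walkers inside the posterior's
        bulk so the ensemble burn-in does not have to traverse the long,
        highly correlated group-mean directions from the prior center.
        """
        from .mle import fit_session

        rng = np.random.default_rng(seed)
        lat = np.zeros((self.n_subjects, 3))
        counts = np.zeros(self.n_subjects)
        for sess_i, session in enumerate(self.cohort.sessions):
            try:
                fr = fit_session(session, self.model, n_restarts=2,
                                 maxeval=500, seed=int(rng.integers(2**31)))
            except RuntimeError:
                continue
            p = fr.params
            if self.model == "hybrid":
                vals = [p.omega_mult, p.omega_p, p.tau]
                latv = [math.log(max(v, 1e-3) / max(1 - v, 1e-3))
                        for v in vals[:2]] + [math.log(max(vals[2], 1e-2))]
            else:  # pt_both
                latv = [math.log(max(p.alpha, 1e-2)),
                        math.log(max(p.gamma, 1e-2)),
                        math.log(max(p.tau, 1e-2))]
            s = self.session_subject[sess_i]
            lat[s] += latv
            counts[s] += 1
        lat /= np.maximum(counts, 1)[:, None]
        X = lat.mean(axis=0)
        sigma = np.clip(lat.std(axis=0, ddof=1) if self.n_subjects > 1
                        else np.full(3, 0.5), 0.15, 3.0)
        x0 = np.zeros(self.ndim)
        x0[0:3] = X
        x0[3:6] = np.log(sigma)
        off = 12 if self.include_shifts else 6
        x0[off:] = ((lat - X) / sigma).ravel()
        return x0

    def sample_prior(self, n: int, seed=None) -> dict[str, np.ndarray]:
        """Prior draws of the group-level parameters on the natural scale."""
        rng = np.random.default_rng(seed)
        out = {}
        for j, name in enumerate(self.param_names):
            m, sd = self._mu_priors[j]
            lat = rng.normal(m, sd, size=n)
            out[name] = np.exp(lat) if name in ("tau", "alpha", "gamma") else expit(lat)
        return out


@dataclass
class PosteriorDraws:
    """Kept posterior draws with named dimensions (chain, draw, ...)."""

    idata: az.InferenceData
    model: HierarchicalModel
    chains: int
    draws: int

    @property
    def posterior(self) -> xr.Dataset:
        return self.idata.posterior


@dataclass
class PosteriorSummary:
    """Medians, 95% intervals and convergence diagnostics per parameter."""

    table: pd.DataFrame  # index: parameter; median, hdi_low, hdi_high, rhat, ess
    passed: bool
    interval: str = "hdi"

    def __str__(self) -> str:
        return self.table.to_string() + f"\nall R-hat < 1.05: {self.passed}"


@dataclass
class PPCResult:
    """Posterior predictive check: real vs simulated behavioral summaries."""

    n_sim: int
    real: pd.DataFrame        # per-session summary rates
    sim_mean: pd.DataFrame    # mean over simulated datasets
    correlations: dict[str, float]  # Spearman r_s per summary


def build_model(cohort: CohortData, include_shifts: bool = True,
                model: str = "hybrid",
                require_complete: bool = True) -> HierarchicalModel:
    """Construct the hierarchical model description for a cohort.

    ``require_complete=False`` skips the one-session-per-drug check, e.g. for
    identifiability probes on deliberately incomplete cohorts.
    """
    return HierarchicalModel(cohort, include_shifts=include_shifts, model=model,
                             require_complete=require_complete)


def sample_posterior(model: HierarchicalModel, chains: int = 4, warmup: int = 500,
                     draws: int = 2500, adapt_delta: float = 0.97,
                     seed=None, nwalkers: int | None = None,
                     init: str = "mle", progress: bool = False) -> PosteriorDraws:
    """Draw from the posterior with the ensemble sampler.

    ``chains``/``warmup``/``draws`` follow the conventional MCMC schedule
    (kept draws total ``chains * draws``); internally the ensemble runs
    ``nwalkers`` coupled walkers, partitioned into ``chains`` groups whose
    post-warmup draws are evenly thinned to exactly ``draws`` per chain.
    ``adapt_delta`` is accepted for interface compatibility; the ensemble
    sampler has no step-size adaptation target.  ``init`` selects the
    starting point: ``"mle"`` (default) seeds the walkers from quick
    per-session maximum-likelihood fits, ``"prior"`` from the hyperprior
    centers.
    """
    del adapt_delta
    D = model.ndim
    if nwalkers is None:
        nwalkers = max(2 * D + 2, 64)
    nwalkers += (-nwalkers) % (2 * chains)  # even and divisible by chains
    per_chain_walkers = nwalkers // chains
    nsteps_keep = max(int(math.ceil(draws / per_chain_walkers)), 40)

    rng = np.random.default_rng(seed)
    if init == "mle":
        x0 = model.data_informed_init(seed=rng.integers(2**31))
    elif init == "prior":
        x0 = model.initial_vector()
    else:
        raise ValueError("init must be 'mle' or 'prior'")
    p0 = x0[None, :] + 0.1 * rng.standard_normal((nwalkers, D))

    sampler = emcee.EnsembleSampler(nwalkers, D, model.log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(rng.integers(2**31)).get_state()
    state = sampler.run_mcmc(p0, warmup, progress=progress)
    sampler.reset()
    sampler.run_mcmc(state, nsteps_keep, progress=progress)

    chain = sampler.get_chain()  # (steps, walkers, D)
    # partition walkers into chain groups, draws step-major within group
    grouped = chain.reshape(nsteps_keep, chains, per_chain_walkers, D)
    grouped = grouped.transpose(1, 0, 2, 3).reshape(chains, -1, D)
    total = grouped.shape[1]
    keep_idx = np.linspace(0, total - 1, num=min(draws, total)).round().astype(int)
    kept = grouped[:, keep_idx, :]  # (chains, draws, D)

    S = model.n_subjects
    off = 12 if model.include_shifts else 6
    data = {
        "X": (("chain", "draw", "param"), kept[:, :, 0:3]),
        "sigma": (("chain", "draw", "param"), np.exp(kept[:, :, 3:6])),
        "z": (("chain", "draw", "subject", "param"),
              kept[:, :, off:].reshape(chains, kept.shape[1], S, 3)),
    }
    if model.include_shifts:
        data["shift"] = (("chain", "draw", "drug", "param"),
                         kept[:, :, 6:12].reshape(chains, kept.shape[1], 2, 3))
    posterior = xr.Dataset(
        {k: xr.DataArray(v[1], dims=v[0]) for k, v in data.items()},
        coords={
            "param": list(model.param_names),
            "subject": model.subjects,
            "drug": list(_SHIFT_DRUGS),
        },
    )
    idata = az.InferenceData(posterior=posterior)
    return PosteriorDraws(idata=idata, model=model, chains=chains,
                          draws=kept.shape[1])


def _natural_group(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Group-level parameters transformed draw-by-draw to the natural scale."""
    X = draws.posterior["X"]
    out = {}
    for j, name in enumerate(draws.model.param_names):
        lat = X.isel(param=j).to_numpy()
        out[name] = np.exp(lat) if name in ("tau", "alpha", "gamma") else expit(lat)
    return out


def summarize(draws: PosteriorDraws, hdi_prob: float = 0.95,
              interval: str = "hdi", rhat_limit: float = 1.05) -> PosteriorSummary:
    """Medians and 95% intervals (HDI by default, equal-tailed via
    ``interval='eti'``) for group parameters on the natural scale and drug
    shifts on the latent scale, with R-hat and ESS per parameter."""

    def ivl(x):
        if interval == "eti":
            lo, hi_ = np.quantile(x, [(1 - hdi_prob) / 2, 1 - (1 - hdi_prob) / 2])
            return float(lo), float(hi_)
        return hdi(x, hdi_prob)

    def diag(x2d):
        x2d = np.asarray(x2d)
        return (float(np.asarray(az.rhat(x2d)).item()),
                float(np.asarray(az.ess(x2d)).item()))

    rows = []
    for name, x in _natural_group(draws).items():
        lo, hi_ = ivl(x)
        r, e = diag(x)
        rows.append({"parameter": name, "median": float(np.median(x)),
                     "low": lo, "high": hi_, "rhat": r, "ess": e})
    if draws.model.include_shifts and "shift" in draws.posterior:
        for di, drug in enumerate(_SHIFT_DRUGS):
            for j, pname in enumerate(draws.model.param_names):
                x = draws.posterior["shift"].isel(drug=di, param=j).to_numpy()
                lo, hi_ = ivl(x)
                r, e = diag(x)
                rows.append({
                    "parameter": f"shift_{drug}_{pname}", "median": float(np.median(x)),
                    "low": lo, "high": hi_, "rhat": r, "ess": e,
                })
    table = pd.DataFrame(rows).set_index("parameter")
    bad = table["median"].isna().any() or not np.all(table["low"] <= table["median"] + 1e-12)
    passed = bool((table["rhat"] < rhat_limit).all()) and not bad
    return PosteriorSummary(table=table, passed=passed, interval=interval)


def behavioral_summaries(cohort: CohortData, choices=None) -> pd.DataFrame:
    """Per-session rates of choosing the higher-EV / higher-magnitude /
    higher-probability option (EV ties excluded from the EV rate)."""
    rows = []
    for i, s in enumerate(cohort.sessions):
        sc = s.schedule
        cl = np.asarray(choices[i] if choices is not None else s.choices_left, bool)
        ev_l, ev_r = sc.ev_left, sc.ev_right
        nontie = ev_l != ev_r
        chose_hi_ev = np.where(ev_l > ev_r, cl, ~cl)[nontie]
        chose_hi_mag = np.where(sc.mag_left > sc.mag_right, cl, ~cl)
        chose_hi_prob = np.where(sc.prob_left > sc.prob_right, cl, ~cl)
        rows.append({
            "subject": s.subject_id, "drug": s.drug,
            "p_higher_ev": float(chose_hi_ev.mean()) if nontie.any() else np.nan,
            "p_higher_mag": float(chose_hi_mag.mean()),
            "p_higher_prob": float(chose_hi_prob.mean()),
        })
    return pd.DataFrame(rows)


def posterior_predictive(draws: PosteriorDraws, cohort: CohortData | None = None,
                         n_sim: int = 500, seed=None) -> PPCResult:
    """Simulate ``n_sim`` datasets from the subject-level posterior and
    correlate (Spearman) their behavioral summaries with the real data's,
    across subject x session cells."""
    model = draws.model
    cohort = cohort or model.cohort
    rng = np.random.default_rng(seed)
    post = draws.posterior
    nchain, ndraw = post.sizes["chain"], post.sizes["draw"]
    flat_idx = rng.integers(0, nchain * ndraw, size=n_sim)

    # reconstruct per-session latents for the sampled draws
    X = post["X"].to_numpy().reshape(-1, 3)[flat_idx]
    sig = post["sigma"].to_numpy().reshape(-1, 3)[flat_idx]
    z = post["z"].to_numpy().reshape(nchain * ndraw, model.n_subjects, 3)[flat_idx]
    x_subj = X[:, None, :] + sig[:, None, :] * z
    lat = x_subj[:, model.session_subject, :]
    if model.include_shifts and "shift" in post:
        sh = post["shift"].to_numpy().reshape(nchain * ndraw, 2, 3)[flat_idx]
        sh_full = np.concatenate([np.zeros_like(sh[:, :1]), sh], axis=1)
        lat = lat + sh_full[:, model.session_drug, :]

    signed = model._signed_dsv(lat)  # (n_sim, S, T), choice-signed
    dsv = signed * model._sign[None]  # undo observed-choice signing
    tau = np.exp(lat[:, :, 2])[:, :, None]
    p_left = expit(tau * dsv)
    sims = rng.random(p_left.shape) < p_left  # (n_sim, S, T)

    real = behavioral_summaries(cohort)
    cols = ["p_higher_ev", "p_higher_mag", "p_higher_prob"]
    acc = np.zeros((len(cohort.sessions), len(cols)))
    for k in range(n_sim):
        choices = [sims[k, i, : s.n_trials] for i, s in enumerate(cohort.sessions)]
        acc += behavioral_summaries(cohort, choices)[cols].to_numpy()
    sim_mean = real.copy()
    sim_mean[cols] = acc / n_sim

    corr = {}
    for c in cols:
        a, b = real[c].to_numpy(), sim_mean[c].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            corr[c] = float("nan")
        else:
            corr[c] = float(spearmanr(a[ok], b[ok]).statistic)
    return PPCResult(n_sim=n_sim, real=real, sim_mean=sim_mean, correlations=corr)


class HierarchicalChoiceModel(BaseEstimator):
    """scikit-learn style wrapper around the hierarchy.

    ``fit`` accepts a :class:`~hybridchoice.task.CohortData` (or a trial
    table readable by :func:`hybridchoice.io.cohort_from_frame`), samples the
    posterior, and exposes ``draws_``, ``summary_`` and
    ``posterior_predictive``.
    """

    def __init__(self, model="hybrid", include_shifts=True, chains=4,
                 warmup=500, draws=2500, adapt_delta=0.97, nwalkers=None,
                 seed=None):
        self.model = model
        self.include_shifts = include_shifts
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.adapt_delta = adapt_delta
        self.nwalkers = nwalkers
        self.seed = seed

    def fit(self, X, y=None):
        if not isinstance(X, CohortData):
            from .io import cohort_from_frame

            X = cohort_from_frame(pd.DataFrame(X))
        self.model_ = build_model(X, include_shifts=self.include_shifts,
                                  model=self.model)
        self.draws_ = sample_posterior(
            self.model_, chains=self.chains, warmup=self.warmup,
            draws=self.draws, adapt_delta=self.adapt_delta,
            seed=self.seed, nwalkers=self.nwalkers,
        )
        self.summary_ = summarize(self.draws_)
        return self

    def posterior_predictive(self, n_sim=500, seed=None) -> PPCResult:
        return posterior_predictive(self.draws_, n_sim=n_sim, seed=seed)
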
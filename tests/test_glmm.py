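"""Design construction and the Laplace binomial mixed model."""

import json
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from hybridchoice import make_cohort
from hybridchoice.glmm import (
    BinomialGLMM,
    GlmmFit,
    build_design,
    fit_glmm,
    prune_random_effects,
)
from hybridchoice.task import CohortData, Schedule, SessionData, generate_schedule


@pytest.fixture(scope="module")
def design(small_cohort):
    return build_design(small_cohort)


def test_design_columns_are_z_scored(design):
    for c in ("mag_diff", "prob_diff", "ev_diff"):
        assert abs(design.col(c).mean()) < 1e-10
        assert abs(design.col(c).std() - 1.0) < 1e-10
    for d in ("amisulpride", "ldopa"):
        assert set(np.unique(design.col(d))) == {0.0, 1.0}
    # placebo rows have both dummies zero
    both = design.col("amisulpride") + design.col("ldopa")
    assert both.max() == 1.0 and (both == 0).sum() > 0


def test_design_hand_built_four_trial_session():
    # two options, four trials, hand-computed cells
    sched = Schedule(
        mag_left=np.array([2.0, 8.0, 5.0, 3.0]),
        mag_right=np.array([6.0, 4.0, 9.0, 7.0]),
        prob_left=np.array([0.8, 0.3, 0.6, 0.2]),
        prob_right=np.array([0.4, 0.7, 0.15, 0.9]),
    )
    sess = SessionData(subject_id="A", drug="placebo", session_order=1,
                       schedule=sched,
                       choices_left=np.array([True, False, True, False]))
    sess2 = SessionData(subject_id="B", drug="placebo", session_order=1,
                        schedule=sched,
                        choices_left=np.array([False, True, False, True]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # placebo-only cohort drops dummies
        d = build_design(CohortData(sessions=[sess, sess2]))
    assert d.columns == ["intercept", "mag_diff", "prob_diff", "ev_diff",
                         "repetition"]
    # response is 1 iff right chosen
    assert np.array_equal(d.y[:4], [0, 1, 0, 1])
    # repetition: 0 on the first trial, then +-1 tracking the previous choice
    assert np.array_equal(d.col("repetition")[:4], [0, -1, 1, -1])
    assert np.array_equal(d.col("repetition")[4:], [0, 1, -1, 1])
    # raw right-minus-left differences, then z-scored: check via the oracle
    raw_md = (sched.mag_right - sched.mag_left) / 10.0
    md = np.tile(raw_md, 2)
    assert np.allclose(d.col("mag_diff"), (md - md.mean()) / md.std())
    # mean-centered EV: (M - mean M)(P - mean P), means over all 8 options
    M = np.concatenate([sched.mag_left, sched.mag_right]) / 10.0
    P = np.concatenate([sched.prob_left, sched.prob_right])
    ev_l = (sched.mag_left / 10 - M.mean()) * (sched.prob_left - P.mean())
    ev_r = (sched.mag_right / 10 - M.mean()) * (sched.prob_right - P.mean())
    evd = np.tile(ev_r - ev_l, 2)
    assert np.allclose(d.col("ev_diff"), (evd - evd.mean()) / evd.std())


def test_placebo_only_drops_dummies_with_warning():
    sched = generate_schedule(30, seed=1)
    sessions = [SessionData(subject_id=f"S{i}", drug="placebo", session_order=1,
                            schedule=sched,
                            choices_left=np.arange(30) % 2 == 0)
                for i in range(3)]
    with pytest.warns(UserWarning, match="identically zero"):
        d = build_design(CohortData(sessions=sessions))
    assert "amisulpride" not in d.columns
    assert not any(":" in c for c in d.columns)


def test_single_subject_raises(design):
    sched = generate_schedule(40, seed=2)
    sess = SessionData(subject_id="only", drug="placebo", session_order=1,
                       schedule=sched, choices_left=np.arange(40) % 2 == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = build_design(CohortData(sessions=[sess]))
    with pytest.raises(ValueError, match="single subject"):
        fit_glmm(d)


def test_fit_recovers_attribute_effects(small_cohort):
    fit = fit_glmm(build_design(small_cohort),
                   random_spec=("intercept", "mag_diff", "prob_diff"))
    t = fit.coef_table
    # softmax agents weight both attributes positively and reliably
    assert t.loc["mag_diff", "beta"] > 0 and t.loc["mag_diff", "p"] < 1e-4
    assert t.loc["prob_diff", "beta"] > 0 and t.loc["prob_diff", "p"] < 1e-4
    # risk-averse generating parameters (omega_p > .5): probability dominates
    assert t.loc["prob_diff", "beta"] > t.loc["mag_diff", "beta"]
    assert 0 < fit.marginal_r2 < 1


def test_zero_between_subject_variance_matches_plain_logistic():
    import statsmodels.api as sm

    from hybridchoice.task import GroupParams

    g = GroupParams(sigma_mult=1e-12, sigma_p=1e-12, sigma_beta=1e-12)
    cohort = make_cohort(n_subjects=5, n_trials=120, seed=8, group=g)
    d = build_design(cohort)
    fit = fit_glmm(d, random_spec=("intercept",))
    sm_fit = sm.GLM(d.y, d.X, family=sm.families.Binomial()).fit()
    assert np.allclose(fit.coef_table["beta"].to_numpy(), sm_fit.params,
                       atol=0.05)
    assert np.allclose(fit.coef_table["se"].to_numpy(), sm_fit.bse,
                       rtol=0.1, atol=0.01)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
def test_against_lme4_reference(tmp_path):
    """Independent oracle: lme4::glmer on the identical design."""
    cohort = make_cohort(n_subjects=6, n_trials=80, seed=11)
    d = build_design(cohort)
    fit = fit_glmm(d, random_spec=("intercept", "mag_diff"),
                   cov_structure="diagonal")
    df = pd.DataFrame({"y": d.y,
                       "subject": np.asarray(d.group_labels)[d.groups]})
    rcols = []
    for c in d.columns[1:]:
        rc = c.replace(":", "_x_")
        rcols.append(rc)
        df[rc] = d.col(c)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
    d <- read.csv("{csv}")
    m <- glmer(y ~ {' + '.join(rcols)} + (1 + mag_diff || subject),
               data = d, family = binomial)
    co <- summary(m)$coefficients
    cat(toJSON(list(beta = unname(co[, 1]), se = unname(co[, 2]),
                    vc = unname(as.data.frame(VarCorr(m))$vcov))))
    """
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout[out.stdout.index("{"):])
    beta = fit.coef_table["beta"].to_numpy()
    assert np.allclose(beta, ref["beta"], atol=0.05, rtol=0.05)
    assert np.allclose(fit.coef_table["se"].to_numpy(), ref["se"],
                       rtol=0.15, atol=0.02)
    assert np.allclose(np.sort(np.diag(fit.Sigma)), np.sort(ref["vc"]),
                       atol=0.05)


def test_prune_keeps_positive_diagonal_structure(small_cohort):
    d = build_design(small_cohort)
    fit = fit_glmm(d, random_spec=("intercept", "mag_diff", "prob_diff"))
    if np.diag(fit.Sigma).min() / np.diag(fit.Sigma).sum() > 1e-4:
        terms, pruned = prune_random_effects(fit, d)
        assert terms == fit.random_terms


def test_prune_removes_null_dimension():
    # synthetic rank-deficient covariance: pruning must remove exactly the
    # null-space dimension identified by a direct eigendecomposition
    sigma = np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.0]])
    evals = np.linalg.eigvalsh(sigma)
    assert (evals < 1e-12).sum() == 1  # the oracle
    cohort = make_cohort(n_subjects=5, n_trials=60, seed=4)
    d = build_design(cohort)
    base = fit_glmm(d, random_spec=("intercept", "mag_diff", "prob_diff"))
    fake = GlmmFit(coef_table=base.coef_table, Sigma=sigma,
                   random_terms=("intercept", "mag_diff", "prob_diff"),
                   marginal_r2=base.marginal_r2, negll=base.negll,
                   n_obs=base.n_obs, converged=True, design=d)
    terms, refit = prune_random_effects(fake, d)
    assert "prob_diff" not in terms  # the zero-variance slope went away
    assert len(terms) >= 1 and refit.Sigma.shape == (len(terms),) * 2


def test_estimator_wrapper(small_cohort):
    est = BinomialGLMM(random_terms=("intercept", "prob_diff"), prune=False)
    est.fit(small_cohort)
    assert est.coef_table_.shape[0] == len(est.design_.columns)
    assert set(est.random_terms_) == {"intercept", "prob_diff"}
    assert 0 <= est.marginal_r2_ <= 1
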
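"""Data contracts, configuration and the end-to-end pipeline.

The canonical trial table is a tidy CSV with one row per trial:

    subject, drug, session_order, trial, mag_left, mag_right,
    prob_left, prob_right, choice (L/R), prev_choice,
    rewarded_left, rewarded_right

(one header row, UTF-8, '.' decimal separator; probabilities as fractions —
percentage-scaled inputs are detected and rescaled on read).  A
column-mapping dictionary translates arbitrary input headers (e.g. a
third-party deposit) to this schema, and a drug-label mapping normalizes
condition names.

``run_pipeline`` ties the stages together — simulate (or load) -> per-session
ML fitting and BIC comparison -> hierarchical Bayesian fit -> posterior
predictive check -> mixed-effects regression — writing tidy CSV artifacts
and a JSON manifest (config hash, per-stage outputs, diagnostics).  All
randomness flows from the config's named seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import (
    DRUGS,
    CohortData,
    DrugShifts,
    GroupParams,
    Schedule,
    SessionData,
    make_cohort,
)

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "cohort_from_frame",
    "frame_from_cohort",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger("hybridchoice")

TRIAL_COLUMNS = (
    "subject", "drug", "session_order", "trial", "mag_left", "mag_right",
    "prob_left", "prob_right", "choice", "prev_choice",
    "rewarded_left", "rewarded_right",
)


class TrialTableError(ValueError):
    """Malformed trial table; the message names the offending rows/columns."""


def frame_from_cohort(cohort: CohortData) -> pd.DataFrame:
    """Serialize a cohort to the canonical tidy trial table."""
    frames = []
    for s in cohort.sessions:
        sc = s.schedule
        choice = np.where(s.choices_left, "L", "R")
        prev = np.concatenate([[""], choice[:-1]])
        frames.append(pd.DataFrame({
            "subject": s.subject_id,
            "drug": s.drug,
            "session_order": s.session_order,
            "trial": np.arange(1, s.n_trials + 1),
            "mag_left": sc.mag_left.astype(int),
            "mag_right": sc.mag_right.astype(int),
            "prob_left": sc.prob_left,
            "prob_right": sc.prob_right,
            "choice": choice,
            "prev_choice": prev,
            "rewarded_left": (sc.rewarded_left.astype(int)
                              if sc.rewarded_left is not None else 0),
            "rewarded_right": (sc.rewarded_right.astype(int)
                               if sc.rewarded_right is not None else 0),
        }))
    return pd.concat(frames, ignore_index=True)


def write_trials(cohort: CohortData, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame_from_cohort(cohort).to_csv(path, index=False)
    return path


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    problems = []
    mags = df[["mag_left", "mag_right"]]
    bad = df.index[~mags.isin(range(1, 11)).all(axis=1)]
    for i in bad[:5]:
        problems.append(f"row {i + 2}: magnitude outside 1-10 "
                        f"({df.loc[i, 'mag_left']}, {df.loc[i, 'mag_right']})")
    probs = df[["prob_left", "prob_right"]].to_numpy(float)
    bad = df.index[((probs <= 0) | (probs >= 1)).any(axis=1)]
    for i in bad[:5]:
        problems.append(f"row {i + 2}: probability outside (0, 1) in "
                        "column prob_left/prob_right")
    bad = df.index[~df["drug"].isin(DRUGS)]
    for i in bad[:5]:
        problems.append(f"row {i + 2}: unknown drug label {df.loc[i, 'drug']!r}")
    bad = df.index[~df["choice"].astype(str).str.upper().isin(["L", "R"])]
    for i in bad[:5]:
        problems.append(f"row {i + 2}: choice must be 'L' or 'R'")
    if problems:
        raise TrialTableError("; ".join(problems))


def cohort_from_frame(df: pd.DataFrame, validate: bool = True) -> CohortData:
    """Assemble a :class:`CohortData` from a canonical trial table."""
    if validate:
        _validate_frame(df)
    sessions = []
    for (subj, drug), g in df.groupby(["subject", "drug"], sort=True):
        g = g.sort_values("trial")
        sched = Schedule(
            mag_left=g["mag_left"].to_numpy(float),
            mag_right=g["mag_right"].to_numpy(float),
            prob_left=g["prob_left"].to_numpy(float),
            prob_right=g["prob_right"].to_numpy(float),
            rewarded_left=(g["rewarded_left"].to_numpy(float).astype(bool)
                           if "rewarded_left" in g else None),
            rewarded_right=(g["rewarded_right"].to_numpy(float).astype(bool)
                            if "rewarded_right" in g else None),
        )
        order = int(g["session_order"].iloc[0]) if "session_order" in g else 1
        sessions.append(SessionData(
            subject_id=str(subj), drug=str(drug), session_order=order,
            schedule=sched,
            choices_left=(g["choice"].astype(str).str.upper() == "L").to_numpy(),
        ))
    return CohortData(sessions=sessions)


def read_trials(path, column_map: dict | None = None,
                drug_map: dict | None = None) -> CohortData:
    """Read and validate a trial-table CSV.

    ``column_map`` maps canonical names to the file's headers (e.g.
    ``{"subject": "id", "mag_left": "magL"}``); ``drug_map`` normalizes
    condition labels (e.g. ``{"A": "amisulpride"}``).  Probabilities given
    on a 0-100 percentage scale are rescaled to fractions.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    if drug_map and "drug" in df.columns:
        df["drug"] = df["drug"].map(lambda d: drug_map.get(d, d))
    for c in ("prob_left", "prob_right"):
        if c in df.columns and df[c].to_numpy(float).max() > 1.0:
            df[c] = df[c].to_numpy(float) / 100.0
    if "trial" not in df.columns:
        df["trial"] = df.groupby(["subject", "drug"]).cumcount() + 1
    _validate_frame(df)
    return cohort_from_frame(df, validate=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every pipeline default, overridable and fully serializable."""

    out_dir: str = "results"
    seed: int = 0
    data_path: str | None = None          # load instead of simulate
    column_map: dict | None = None
    drug_map: dict | None = None
    # simulation
    n_subjects: int = 31
    n_trials: int = 500
    group: dict = field(default_factory=lambda: dataclasses.asdict(GroupParams()))
    shifts: dict = field(default_factory=lambda: dataclasses.asdict(DrugShifts()))
    corr_cap: float = 0.1
    # stages
    stages: tuple = ("simulate", "compare", "hier", "ppc", "glmm")
    # mle
    models: tuple = ("multiplicative", "additive", "hybrid")
    n_restarts: int = 100
    maxeval: int = 10000
    xtol_rel: float = 1.0e-08
    # hierarchical
    hier_model: str = "hybrid"
    chains: int = 4
    warmup: int = 500
    draws: int = 2500
    adapt_delta: float = 0.97
    n_sim_ppc: int = 500
    # glmm
    glmm_random: tuple = ("intercept", "amisulpride", "ldopa",
                          "mag_diff", "prob_diff", "ev_diff")
    glmm_cov_structure: str = "diagonal"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        if "shifts" in d:
            d["shifts"] = {k: tuple(v) for k, v in d["shifts"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages_run: list[str]
    outputs: dict[str, str]
    diagnostics: dict[str, object]
    wall_clock_s: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages end to end.

    Any stage failure halts the run with a stage-tagged error; outputs
    written so far are listed in the manifest next to a ``failed`` marker.
    """
    from . import glmm as glmm_mod
    from . import hier as hier_mod
    from . import mle as mle_mod

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31))
             for name in ("simulate", "compare", "hier", "ppc")}
    outputs: dict[str, str] = {"config": str(out / "config.json")}
    diagnostics: dict[str, object] = {"seeds": seeds}
    clocks: dict[str, float] = {}
    stages_run: list[str] = []

    def stage(name):
        def deco(fn):
            if name not in config.stages and name != "load":
                return lambda *a, **k: None
            def wrapped(*a, **k):
                t0 = time.perf_counter()
                logger.info("stage %s: starting (seed=%s)", name, seeds.get(name))
                try:
                    r = fn(*a, **k)
                except Exception as exc:
                    diagnostics[name] = f"failed: {exc}"
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                clocks[name] = round(time.perf_counter() - t0, 3)
                stages_run.append(name)
                logger.info("stage %s: done in %.1fs", name, clocks[name])
                return r
            return wrapped
        return deco

    @stage("simulate")
    def do_simulate():
        cohort = make_cohort(
            n_subjects=config.n_subjects,
            group=GroupParams(**config.group),
            shifts=DrugShifts(
                amisulpride=tuple(config.shifts["amisulpride"]),
                ldopa=tuple(config.shifts["ldopa"]),
            ),
            n_trials=config.n_trials, seed=seeds["simulate"],
            corr_cap=config.corr_cap,
        )
        outputs["trials"] = str(write_trials(cohort, out / "trials.csv"))
        return cohort

    if config.data_path:
        cohort = read_trials(config.data_path, config.column_map, config.drug_map)
        stages_run.append("load")
    else:
        cohort = do_simulate()
        if cohort is None:  # simulate toggled off and no data path
            raise RuntimeError("no data: enable the simulate stage or set data_path")

    @stage("compare")
    def do_compare():
        table = mle_mod.compare_models(
            cohort, specs=config.models, n_restarts=config.n_restarts,
            seed=seeds["compare"],
        )
        path = out / "model_comparison.csv"
        table.table.to_csv(path)
        outputs["model_comparison"] = str(path)
        diagnostics["best_model"] = table.best_model
        diagnostics["fit_failures"] = table.n_failures
        return table

    do_compare()

    posterior_draws = None

    @stage("hier")
    def do_hier():
        nonlocal posterior_draws
        model = hier_mod.build_model(cohort, include_shifts=True,
                                     model=config.hier_model)
        posterior_draws = hier_mod.sample_posterior(
            model, chains=config.chains, warmup=config.warmup,
            draws=config.draws, adapt_delta=config.adapt_delta,
            seed=seeds["hier"],
        )
        summary = hier_mod.summarize(posterior_draws)
        path = out / "posterior_summary.csv"
        summary.table.to_csv(path)
        outputs["posterior_summary"] = str(path)
        diagnostics["rhat_pass"] = summary.passed
        diagnostics["max_rhat"] = float(summary.table["rhat"].max())

    do_hier()

    @stage("ppc")
    def do_ppc():
        if posterior_draws is None:
            raise RuntimeError("ppc requires the hier stage")
        ppc = hier_mod.posterior_predictive(
            posterior_draws, cohort, n_sim=config.n_sim_ppc, seed=seeds["ppc"])
        merged = ppc.real.merge(ppc.sim_mean, on=["subject", "drug"],
                                suffixes=("_real", "_sim"))
        path = out / "ppc.csv"
        merged.to_csv(path, index=False)
        outputs["ppc"] = str(path)
        diagnostics["ppc_spearman"] = ppc.correlations

    do_ppc()

    @stage("glmm")
    def do_glmm():
        est = glmm_mod.BinomialGLMM(
            random_terms=config.glmm_random,
            cov_structure=config.glmm_cov_structure,
        ).fit(cohort)
        path = out / "glmm_coefficients.csv"
        est.coef_table_.rename_axis("term").to_csv(path)
        outputs["glmm"] = str(path)
        diagnostics["glmm_marginal_r2"] = est.marginal_r2_
        diagnostics["glmm_random_terms"] = list(est.random_terms_)

    do_glmm()

    manifest = RunManifest(
        config_hash=config.config_hash(), stages_run=stages_run,
        outputs=outputs, diagnostics=diagnostics, wall_clock_s=clocks,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
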
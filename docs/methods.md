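# Methods

## The task and its simulator

The task is a two-option, two-attribute gamble: on every trial the decision
maker sees a left and a right option, each defined by a reward magnitude
(integer, displayed on a 1–10 scale) and a reward probability (displayed as
a percentage). Both attributes are explicit — nothing is learned — and the
outcomes of the two options are independent Bernoulli draws.

`hybridchoice.task.generate_schedule` produces the trial list under three
constraints:

* **no attribute ties** — the two options never share a magnitude or a
  probability (guaranteed by construction: attribute pairs are sampled
  without replacement from their grids);
* **dominated-trial cap** — trials where one option is strictly higher on
  both attributes ("no-brainers") are limited to 17.8% of trials (89 of
  500 by default);
* **left/right decorrelation** — the Pearson correlations between the two
  options' magnitudes, probabilities and expected values are all kept below
  a cap (default |r| ≤ 0.1).

Because capping dominance forces most trials to be *anti*-dominated (the
magnitude winner is the probability loser), it couples the two options'
expected values; independent resampling cannot reach |r| ≤ 0.1. The
generator therefore runs a greedy local search over constraint-preserving
moves — exchanging the probability pairs of two trials, mirroring a whole
trial left/right, or redrawing one trial's attribute pair, always
re-orienting the pair so the trial's dominance status is preserved — and
accepts only moves that reduce the correlation penalty. Typical runtimes
are tens of milliseconds for a 500-trial schedule; an explicit
`ScheduleConstraintError` names the violated constraint if the search
budget (default 20 000 moves) is exhausted. The probability grid
(0.10–0.95 in steps of 0.05) is a design choice: probabilities are
displayed as percentages and the magnitude dimension has ten levels, so a
comparable resolution is used. The correlation between chosen and unchosen
value cannot be constrained before choices exist and is only reported post
hoc. Outcome feedback, bonus accounting and presentation timing are not
modeled; none of them enters any model's likelihood.

## Value models and the choice rule

All models assign each option a subjective value `sv` and choose through a
softmax (logistic) rule on the left-minus-right difference,

    P(left) = 1 / (1 + exp(−(Δsv · τ + b · rep))),

with inverse temperature τ ≥ 0 and an optional repetition bias `b` whose
regressor `rep` is +1 if the previous choice was left, −1 if right, and 0
on a session's first trial (so `b < 0` means alternation). The bias enters
inside the softmax argument, mirroring the regression stage's repetition
regressor; adding it outside the τ multiplication would be an equivalent
reparameterization at fixed τ.

With magnitudes scaled to 0.10–1.00 (commensurate with probabilities):

* multiplicative: `sv = P·M` (the expected value),
* additive: `sv = ω_p·P + (1−ω_p)·M`, where ω_p > 0.5 means probabilities
  dominate (risk aversion) and ω_p < 0.5 magnitude dominance (risk
  seeking),
* hybrid: `sv = ω_mult·P·M + (1−ω_mult)·(ω_p·P + (1−ω_p)·M)` — a convex
  mixture arbitrated by ω_mult ∈ [0, 1].

The Prospect-Theory family instead uses raw 1–10 magnitudes with a power
distortion `M^α` and/or the one-parameter probability-weighting function
`w(P) = P^γ / (P^γ + (1−P)^γ)^(1/γ)`; variants distort only the magnitude,
only the probability, or both. Only gains occur in the task, so no
loss-frame value function is implemented.

The session negative log-likelihood clips per-trial choice probabilities to
`[1e−12, 1 − 1e−12]` (configurable) so it is finite for any admissible
parameter set.

## Per-session maximum likelihood and BIC

Each subject × drug session is fitted independently. The optimizer is a
bound-constrained, derivative-free method (Powell line-search with box
bounds) run with a function-evaluation budget of 10 000 and a relative
stopping tolerance of 1.0e−08, restarted from 100 random initial points
drawn uniformly inside the parameter box (defaults; both configurable).
Restart draws come from one sequential seeded stream, so the first *k*
restarts of a larger run replicate a smaller run exactly — the returned
optimum is monotone in the number of restarts. Bounds: ω_mult, ω_p ∈
[0, 1]; τ ∈ [0, 100]; bias ∈ [−5, 5]; α, γ ∈ [0.01, 5] — generous but
optimizer-safe boxes. Model selection uses the plain per-session
`BIC = k·ln(n_trials) + 2·negloglik`, averaged across sessions (mean and
standard error reported; ties break toward fewer parameters; per-session
fit failures are excluded from means with a logged count).

## Hierarchical Bayesian model with drug shifts

The winning hybrid model (and, with the same machinery, the two-distortion
Prospect-Theory variant) is embedded in a hierarchy on an unconstrained
latent scale: subject latents `x_s = X + σ·z_s` with `z_s ~ N(0, 1)`
(non-centered), inverse-logit transforms for ω_mult and ω_p, an exponential
transform for τ. Hyperpriors: `X_mult, X_p ~ N(0, 2)`, `X_β ~ N(2, 3)`
(so the prior-central τ is e² ≈ 7.4), half-Cauchy(2) on the group SDs, and
`N(0, 3)` on the six unconstrained drug shifts (three per drug), which are
added to the subject latents *before* the transforms in non-placebo
sessions. Shifts are group-level scalars — no subject-level shift
variability — and a shift is called significant when its 95% interval
excludes zero. Posterior summaries report group parameters on the natural
scale by transforming draws first and summarizing afterwards; shifts are
summarized on the latent scale. Intervals are 95% highest-density by
default (equal-tailed available via a flag).

Sampling uses an affine-invariant ensemble sampler with a fully vectorized
log posterior. The conventional `chains × draws` schedule (default 4 ×
2500 kept after 500 warm-up sweeps) is mapped onto the walker ensemble:
walkers are partitioned into `chains` groups whose post-warmup draws are
evenly thinned to exactly `draws` per chain, preserving the total kept-draw
count and giving rank-normalized split R-hat (threshold 1.05) and ESS a
chain structure to work on. Because walkers of one ensemble interact, this
R-hat is mildly anticonservative compared with independent chains; runs
failing the threshold are flagged, never silently summarized. The
`adapt_delta` argument is accepted for interface compatibility but has no
effect on an ensemble sampler. Initialization is data-informed by
default: quick small-budget per-session maximum-likelihood fits seed each
subject's latents, and the group means and SDs start at their
across-subject mean and SD, with drug shifts at 0 and per-walker jitter
of 0.1. This matters for the ensemble sampler: started from the
hyperprior centers it converges only very slowly along the long,
correlated group-mean directions (walker-group R-hat does not flag the
collective drift), whereas the data-informed start places the ensemble in
the posterior bulk; prior-center initialization remains available via
`init="prior"`. Latent
exponents are clipped (τ at e^±30, α and γ at [e^−7, e^3]) purely for
numerical safety; the priors keep posteriors far from these limits.

Posterior predictive checks draw `n_sim` (default 500) parameter vectors
from the subject-level posterior, replay every session's schedule through
the softmax model, and compare per-session behavioral summaries — the
probability of choosing the option with the higher expected value
(EV-tied trials excluded), the higher magnitude, and the higher
probability — between real and simulated data via Spearman rank
correlations across subject × session cells. Degenerate cases (constant
summaries, e.g. pure-noise cohorts) return NaN correlations rather than
raising.

## Cohort simulator

`make_cohort` draws subject latents from the group Normals, applies the
per-drug latent shifts exactly as the hierarchical model assumes, assigns
drug order by a balanced 3×3 Latin square, and generates one fresh
schedule per session. Defaults emulate the study conditions: 31 subjects ×
3 within-subject drug sessions (placebo, amisulpride, L-DOPA) × 500
trials, group medians ω_mult = 0.49, ω_p = 0.82, τ = 14.56, zero shifts.
The group SDs (0.8 on the logit scale for the two weights, 0.4 on the log
scale for τ) are not reported quantities; they were chosen once as a
moderate, realistic between-subject spread (e.g. τ roughly 7–32 across
subjects) and are not tuned. What the simulator does *not* emulate:
reaction times, within-session non-stationarity (fatigue, learning of the
probability format), session-order effects, and any repetition bias unless
explicitly requested — so passing recovery tests demonstrate correctness
of the estimation machinery under the model's own assumptions, not that
real choice data satisfy those assumptions.

## Mixed-effects regression stage

The trial-level design regresses an indicator of choosing the *right*
option on z-scored right-minus-left difference scores for magnitude,
probability, and a "mean-centered EV" — per session, each option's
`(M − mean M)(P − mean P)` with means over all presented options, a
decorrelating construction that makes the EV regressor independent of the
raw attributes — plus the ±1 repetition regressor, drug dummies
(amisulpride and L-DOPA vs. placebo) and all drug × predictor
interactions. Z-scoring is over all included trials by default
(per-session via a flag). Placebo-only inputs drop the degenerate dummy
columns with a warning. Extra fixed-effect columns (session order, mood
scores) can be appended without bespoke handling.

The model is a logistic GLMM with by-subject random effects, estimated by
Laplace-approximation maximum likelihood: the inner mode of each subject's
random-effect vector is found by damped Newton iterations (the joint
log-density is concave), and the outer problem over fixed effects plus a
Cholesky-parameterized random-effect covariance is solved by L-BFGS-B.
The default covariance is diagonal (independent variance components);
full covariance is available via `cov_structure="full"`. Wald standard
errors come from a finite-difference Hessian over the fixed effects,
conditional on the estimated variance components, with two-sided
asymptotic p-values and no degrees-of-freedom correction; the
implementation reproduces lme4's `glmer` coefficients and standard errors
to within a few percent on matched designs (checked in the test suite).
The marginal R² follows the Nakagawa–Schielzeth definition for logit
models: `var(Xβ) / (var(Xβ) + mean(zᵀΣz) + π²/3)`.

Random-effect structure selection mirrors the principal-component
procedure: eigenvalues of the estimated covariance whose share of the
total random variance would print as 0.00% (below 0.005%, i.e. 5e−5) flag
the smallest-variance term for removal, and the model is refitted until
stable. A single-subject input raises — random effects are unidentifiable.

## Problem sizes and numerical choices

Test and acceptance runs scale the study down so everything fits one CPU:
ML recovery uses 50 sessions × 500 trials with 8 restarts and a 2000-eval
budget (the Powell optimizer reaches the same optima as the full 10 000
budget on these likelihoods; the full budget remains the default);
BIC selection uses 20 replicate cohorts of 12 subjects × 200 trials with
3 restarts; hierarchical recovery uses 12 subjects × 200 trials with
2 chains × 500 kept draws after 1500 warm-up sweeps; GLMM type-I
calibration uses 200 noise cohorts of 6 subjects × 40 trials with a
random intercept; GLMM sign recovery runs at the full 31 × 3 × 500 size.
At the reduced hierarchical scale the τ shifts (±0.5 on the log scale)
are reliably detected, while the posterior HDIs for the ω shifts have
half-widths around 0.3–0.4 latent units — detection of ±0.5 ω shifts is
therefore borderline by construction at 12 subjects, which the acceptance
test acknowledges by requiring sign consistency for all shifts but
interval exclusion only for the majority per run.

Other numerical choices: likelihood clipping at 1e−12; schedule local
search accepts strictly improving moves against a penalty with a 10%
safety margin inside the correlation cap; the GLMM outer optimizer bounds
log-SDs to [−6, 3]; diagnostics treat an R-hat ≥ 1.05 anywhere in the
summarized parameters as a failed run.

## Known limitations

* The ensemble sampler explores high-dimensional hierarchies more slowly
  than gradient-based samplers; full-scale runs (31 subjects) need longer
  warm-up than the reduced defaults used in tests.
* Shift placement before the transforms means the printed τ shifts are on
  the log scale (multiplicative on τ); natural-scale readings would need a
  different model.
* The "mean-centered EV" construction and the pooled z-scoring scope are
  one admissible reading of the regression design; both are configurable.
* The GLMM Wald covariance conditions on the estimated variance
  components, as is standard for this model class; variance-component
  uncertainty is not propagated.
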
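# Methods

This note documents the models implemented in `twostep`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## Task environment (`twostep.task`)

Each trial: first-stage choice a ∈ {0, 1} → second-stage pair s with
P(s = canonical(a)) = `p_common` (default 0.7; the canonical mapping is the
identity labelling 0↔0, 1↔1, fixed for the whole session, with choice 1's
mapping the mirror of choice 0's) → second-stage choice c ∈ {0, 1} →
reward r ~ Bernoulli(p[s, c]).

The four reward probabilities follow independent Gaussian random walks:
per trial, p ← reflect(p + ε), ε ~ N(0, `walk_sd`²) with `walk_sd` = 0.025,
reflected into [`lower_bound`, `upper_bound`] = [0.25, 0.75]. Reflection is
the standard reflecting-walk map (p′ > U ⇒ 2U − p′, p′ < L ⇒ 2L − p′,
iterated), implemented in closed form as a triangle-wave fold; with
SD 0.025 a multiple reflection is a ~10⁻⁸⁰ event, but the closed form is
exact regardless. Two consequences worth knowing:

* the walk's stationary distribution is uniform on the reflecting
  interval, so long-run means sit at 0.5 and an indifferent agent earns
  ~50% reward;
* restricting increments to steps whose endpoints both lie in
  [0.30, 0.70] (the diagnostic used for the SD check) conditions away a
  small tail of large excursions, biasing the measured SD down by ~3%
  (0.0243 observed vs 0.025 nominal). This is a property of the
  estimator, not of the walk.

Initial probabilities are drawn uniformly within the bounds unless given
explicitly; they are recorded in the emitted latent-walk table. The walk
advances once per trial, including masked (missed) trials — drift is
time-driven, not event-driven. Sessions are 300 or 350 trials to match the
two subsamples the generators emulate.

## Hybrid agents (`twostep.agents`)

The model-free system is SARSA(λ) over the two stages:

    δ₂ = r − Q₂(s, c)            Q₂(s, c) += α δ₂
    δ₁ = Q₂ᵖʳᵉ(s, c) − Q₁(a)     Q₁(a)   += α δ₁ + α λ δ₂

The model-based system plans through the true transition probabilities
(transition learning is omitted deliberately: the mapping never changes
within a session, and participants are instructed about its structure):

    Q_MB(a) = p_common · max_c Q₂(canonical(a), c)
            + (1 − p_common) · max_c Q₂(other(a), c)

Stage-1 choice is softmax with inverse temperature β₁ over
w·Q_MB + (1−w)·Q_MF plus a perseveration bonus on the previous choice;
stage-2 choice is softmax(β₂·Q₂) within the presented pair. w = 0 yields a
pure model-free agent (reward main effect only), w = 1 a pure model-based
agent (interaction only, with the characteristic crossover in the
stay-probability table). These update equations follow the standard hybrid
formulation for this task (Daw et al., 2011, *Neuron*).

**Population defaults.** 97 subjects in two subsamples (48 at 350 trials,
49 at 300). Per-subject parameters are truncated-normal draws with means
(SDs): w 0.45 (0.25), α 0.45 (0.15), λ 0.55 (0.20), β₁ 4.0 (1.5),
β₂ 3.5 (1.5), perseveration 0.15 (0.30) — centred on the ranges typically
estimated for this task, producing a cohort with the usual mixture of both
effects and wide individual variation. The "extraversion" trait is drawn as
round(N(16, 5²)) truncated to [0, 23], matching the questionnaire scale of
the emulated sample (subsample means ≈ 16.5 / 15.2, SDs ≈ 4.7 / 5.1).
Missed trials are generated by masking completed trials at random at rate
0.014; the conservative pairing rule below then drops any stay/switch pair
touching one. Optional covariate links act on logit(w) and log(β₁) so that
sampled parameters always stay in range; the link is a synthetic device for
power and recovery studies, not a mechanistic claim.

**Direct generative model.** `simulate_from_regression` draws stay
outcomes straight from the multilevel logistic model: per-subject random
effects b ~ MVN(0, Σ) on (intercept, trans, rew, trans:rew); per trial
rew = ±1 with marginal probability 0.5 (the emulated study's observed
reward rate was 50.8%) and trans = +1 with probability 0.7; stay ~
Bernoulli(logit⁻¹(x′β + z′b)). Defaults: β = (1.0, 0, 0.198, 0.132) — the
intercept giving a realistic ~73% marginal stay rate, reward and
interaction at the group-level values the analysis is expected to recover —
and Σ = 0.09·I (random-effect SDs 0.3, uncorrelated).

## Stay/switch coding (`twostep.coding`)

One design row per consecutive completed trial pair (n, n+1) within a
subject: predictors rew/trans (±1) from trial n, outcome stay = 1 iff the
first-stage choice repeats on trial n+1. Pairs containing a missed trial
are dropped (symmetric and conservative; no imputation). The odd/even
split used for cross-fitting takes parity of the *outcome* trial n+1
(1-based) by default; the alternative convention (parity of the predictor
trial n) is exposed as `on="predictor"` because either reading of an
"odd-numbered trial" is defensible for a trial pair, and the pipeline
behaves identically under both.

## Per-subject logistic and engagement (`twostep.hier_logit`, `twostep.engagement`)

Per-subject fits maximize the Bernoulli log-likelihood of the 2 × 2
factorial model with an L2 ridge (default 10⁻⁴) on the non-intercept
terms. The ridge exists only to keep separated fits finite; reported
deviances are the unpenalized −2 log-likelihood at the optimum, and a fit
whose coefficients run beyond |15| is flagged as separation-limited.

The engagement score is deviance(intercept-only) − deviance(full), both on
the subject's odd-trial rows — the likelihood-ratio statistic for "the
subject's staying responds to trial events in any way" vs "constant stay
tendency". Under the null it is ~χ²₃ (verified by simulation at n = 1000
non-learning subjects, KS p ≫ 0.01); under responsiveness it grows
linearly in trials. Subjects with fewer than 8 scored rows are excluded
with a logged warning. The top-fraction subgroup takes the ⌈f·N⌉ highest
scores (⌈0.2·97⌉ = 20), ties broken by subject id; the score is z-scored
across the included sample before entering any model. Every model that
consumes the score is fit on even-trial rows only; `check_crossfit`
raises on any overlap between defining and testing rows.

## Multilevel logistic regression (`twostep.hier_logit`)

The GLMM is stay_ij ~ Bernoulli(logit⁻¹(x′_ij β + z′_ij b_i)), with
z = (1, trans, rew, trans·rew) and b_i ~ MVN(0, Σ) unstructured.
Moderators expand x factorially (8 fixed effects with one moderator, 16
with two).

Estimation maximizes the Laplace approximation to the marginal
likelihood. Σ is parameterized by its Cholesky factor Λ with
log-parameterized diagonal (b = Λu, u spherical); for each candidate
(β, θ) the u are profiled out by batched per-subject Newton iterations
(strictly concave subproblems, solved to 10⁻¹² relative tolerance), and
L-BFGS-B moves (β, θ) jointly against the full Laplace criterion

    −2ℓ = −2[ Σ_ij log p(y|η̂) − ½ Σ_i |û_i|² − ½ Σ_i log det(Λ′Z_i′W_iZ_iΛ + I) ].

β must be part of the outer optimization because the log-determinant
depends on it through the weights W; profiling β through the penalized
likelihood instead (a common shortcut) leaves a systematic offset of up to
half a standard error. This is the same formulation as lme4's `glmer` at
nAGQ = 1, and on shared data the two agree to ~10⁻⁴ on coefficients and
random-effect SDs. Numerical details: θ diagonals bounded in [−8, 3] on
the log scale (the lower bound is numerically zero variance and makes the
zero-variance limit exactly a pooled logistic fit, available via
`fix_theta`), finite-difference outer gradients with step 10⁻⁶, outer
ftol 10⁻¹¹.

Fixed-effect covariance is the inverse Schur complement of the joint
(β, u) Hessian at the optimum, conditional on θ̂ — lme4's convention. Wald
Z = β/SE with two-sided normal p-values; linear contrasts c′β are tested
as χ²₁ = (c′β)²/(c′Vc). Two calibration facts measured during
development: the conditional SEs are within 0.5% of SEs from the full
observed information including the θ block (covariance-parameter
uncertainty is negligible at ~100 subjects), and across 50 independent
study-scale replicates the 95% Wald intervals covered generating values
94–100% of the time with no detectable bias.

The Laplace approximation itself is accurate to much better than 10⁻² log
units in the regime the analyses occupy (random-effect SDs ≈ 0.15 against
an adaptive Gauss–Hermite oracle on desk-scale instances); its error grows
with the random-effect scale (~0.02 per 80 observations at SD 0.3), which
is inherent to Laplace and shared by glmer, not an implementation
artifact.

## Pipeline (`twostep.pipeline`)

`run_analysis` executes: generate/load → encode → odd/even split →
engagement on the defining half → model (a) extraversion moderation on
*all* rows (the main analysis uses the full data; only engagement-related
models are restricted) → model (b) same moderation on the top-20%
subgroup, testing half only → model (c) extraversion × engagement
moderation, testing half only → Wald contrast comparing the
engagement × extraversion moderation of the reward effect (model-free)
against that of the reward × transition effect (model-based). An optional
fourth model moderates by a ±1-coded subsample indicator. All outputs are
deterministic functions of the config and seed; tables serialize with a
fixed float format so repeated runs are byte-identical.

## What the synthetic tests do and do not show

The generators emulate the study's structural conditions (cohort size,
trial counts, transition and walk parameters, missed-trial rate,
questionnaire scale) and the analysis model's own assumptions. Passing
recovery and calibration tests therefore establishes that the pipeline is
self-consistent and correctly implemented — not that real participants
satisfy the model. In particular: real choice sequences have
autocorrelated predictors (the ±1 reward sequence here is i.i.d.), real
engagement differences involve attention and reaction-time structure this
package does not model, and any extraversion–strategy link in a synthetic
cohort is inserted by construction. Problem sizes in the test suite
(cohorts of 20–97 subjects, 20–50 replicates) are the package's chosen
trade-off between statistical resolution and runtime.

## Known limitations

* No likelihood-based fitting of the hybrid RL model itself; inference is
  regression-based by design.
* Laplace only (no adaptive quadrature in the fitting path; quadrature is
  reserved for the test oracle because the 4-dim random effect makes it
  expensive).
* Wald inference conditional on θ̂; no profile-likelihood or bootstrap
  intervals.
* The engagement score's χ²₃ null calibration assumes enough rows per
  subject (~150 here); it degrades for very short sessions.
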
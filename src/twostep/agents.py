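"""Synthetic behaviour generators for the two-stage task.

Two generative routes are provided:

* :class:`HybridAgent` — a SARSA(λ) model-free learner mixed with a
  Bellman model-based planner through a weight ``w``, choosing by softmax
  with a perseveration bonus. ``w = 0`` is a pure model-free agent
  (reward main effect in stay behaviour), ``w = 1`` a pure model-based
  agent (reward-by-transition interaction). :func:`simulate_population`
  plays a cohort of such agents, optionally linking a latent
  "extraversion" trait to strategy parameters.

* :func:`simulate_from_regression` — draws stay/switch data directly from
  the multilevel logistic model used for analysis (fixed effects plus
  per-subject random effects on intercept, transition, reward and their
  interaction), for self-consistency and recovery studies.

The agent update rules follow the standard hybrid formulation for this
task (Daw et al., 2011): the stage-2 prediction error updates stage-2
values and, scaled by the eligibility trace λ, the stage-1 value of the
chosen option; model-based stage-1 values are computed from the true
transition probabilities, which are fixed throughout a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TaskConfig, canonical_pair, simulate_session

__all__ = [
    "AgentParams",
    "HybridAgent",
    "PopulationSpec",
    "RegressionGenSpec",
    "mf_update",
    "mb_values",
    "hybrid_choice_prob",
    "simulate_population",
    "simulate_from_regression",
]

COVARIATE_COLUMNS = ["subject_id", "extraversion_raw", "extraversion_z", "subsample"]


@dataclass(frozen=True)
class AgentParams:
    """Hybrid-agent parameters.

    Parameters
    ----------
    w
        Model-based mixing weight in [0, 1].
    alpha
        Learning rate in (0, 1].
    lam
        Eligibility-trace parameter λ in [0, 1]: how directly terminal
        reward credits the first-stage choice in the model-free system.
    beta1, beta2
        Softmax inverse temperatures (>= 0) for stages 1 and 2.
    persev
        Perseveration bonus added to the utility of the previously chosen
        first-stage option.
    """

    w: float = 0.5
    alpha: float = 0.5
    lam: float = 0.6
    beta1: float = 4.0
    beta2: float = 3.5
    persev: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("softmax temperatures must be non-negative")


def mf_update(
    q1: np.ndarray,
    q2: np.ndarray,
    choice1: int,
    pair: int,
    choice2: int,
    reward: float,
    params: AgentParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One SARSA(λ) update of the model-free value tables.

    ``q1`` has shape (2,) over first-stage options, ``q2`` shape (2, 2)
    over (pair, option). The stage-2 prediction error
    ``δ2 = r - q2[pair, choice2]`` updates the stage-2 value; the stage-1
    error ``δ1 = q2_pre[pair, choice2] - q1[choice1]`` plus λ-weighted δ2
    updates the stage-1 value. Returns updated copies.
    """
    q1 = np.array(q1, dtype=float)
    q2 = np.array(q2, dtype=float)
    d2 = reward - q2[pair, choice2]
    d1 = q2[pair, choice2] - q1[choice1]
    q2[pair, choice2] += params.alpha * d2
    q1[choice1] += params.alpha * d1 + params.alpha * params.lam * d2
    return q1, q2


def mb_values(q2: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Model-based stage-1 values from the true transition structure.

    Q_MB(a) = p_common * max_b q2[canonical(a), b]
            + (1 - p_common) * max_b q2[other(a), b].
    """
    q2 = np.asarray(q2, dtype=float)
    best = q2.max(axis=1)
    p = config.p_common
    return np.array(
        [
            p * best[canonical_pair(0)] + (1.0 - p) * best[1 - canonical_pair(0)],
            p * best[canonical_pair(1)] + (1.0 - p) * best[1 - canonical_pair(1)],
        ]
    )


def hybrid_choice_prob(
    q_mb: np.ndarray,
    q_mf: np.ndarray,
    prev_choice: int | None,
    params: AgentParams,
) -> float:
    """Probability of choosing first-stage option 0.

    Softmax with inverse temperature ``beta1`` over the mixed values
    ``w*Q_MB + (1-w)*Q_MF``, with ``persev`` added to the utility of the
    previously chosen option (none on the first trial).
    """
    q = params.w * np.asarray(q_mb, float) + (1.0 - params.w) * np.asarray(q_mf, float)
    u = params.beta1 * q
    if prev_choice is not None:
        u = u.copy()
        u[prev_choice] += params.persev
    return float(1.0 / (1.0 + math.exp(u[1] - u[0])))


def _softmax2(u0: float, u1: float) -> np.ndarray:
    m = max(u0, u1)
    e0, e1 = math.exp(u0 - m), math.exp(u1 - m)
    return np.array([e0, e1]) / (e0 + e1)


class HybridAgent:
    """Stateful hybrid model-based/model-free agent playing the task."""

    def __init__(self, params: AgentParams, config: TaskConfig):
        self.params = params
        self.config = config
        self.q1 = np.zeros(2)
        self.q2 = np.zeros((2, 2))
        self.prev_choice: int | None = None

    def stage1_probs(self) -> np.ndarray:
        p0 = hybrid_choice_prob(
            mb_values(self.q2, self.config), self.q1, self.prev_choice, self.params
        )
        return np.array([p0, 1.0 - p0])

    def stage2_probs(self, pair: int) -> np.ndarray:
        b = self.params.beta2
        return _softmax2(b * self.q2[pair, 0], b * self.q2[pair, 1])

    def observe(self, choice1: int, pair: int, choice2: int, reward: int) -> None:
        self.q1, self.q2 = mf_update(
            self.q1, self.q2, choice1, pair, choice2, reward, self.params
        )
        self.prev_choice = choice1


# ---------------------------------------------------------------------------
# population generator


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort description for the hybrid-agent generator.

    Parameter distributions are (mean, SD) pairs, truncated to each
    parameter's legal range. Defaults emulate the study cohort: 97
    participants in two subsamples (48 at 350 trials, 49 at 300), a
    questionnaire-scale trait with mean 16 and SD 5 truncated to [0, 23],
    1.4% missed trials, and hybrid parameters in the range typically
    estimated for this task.

    ``link_w`` and ``link_beta1`` are linear slopes of the standardized
    trait on logit(w) and log(beta1): a synthetic device tying the
    covariate to strategy for power and recovery studies, not a claim
    about mechanism.
    """

    n_subjects: int = 97
    subsample_sizes: tuple[int, int] = (48, 49)
    subsample_trials: tuple[int, int] = (350, 300)
    w: tuple[float, float] = (0.45, 0.25)
    alpha: tuple[float, float] = (0.45, 0.15)
    lam: tuple[float, float] = (0.55, 0.20)
    beta1: tuple[float, float] = (4.0, 1.5)
    beta2: tuple[float, float] = (3.5, 1.5)
    persev: tuple[float, float] = (0.15, 0.30)
    link_w: float = 0.0
    link_beta1: float = 0.0
    trait_mean: float = 16.0
    trait_sd: float = 5.0
    trait_range: tuple[float, float] = (0.0, 23.0)
    miss_rate: float = 0.014

    def __post_init__(self) -> None:
        if sum(self.subsample_sizes) != self.n_subjects:
            raise ValueError("subsample sizes must total n_subjects")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        for name in ("w", "alpha", "lam", "beta1", "beta2", "persev"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be non-negative")


_PARAM_BOUNDS = {
    "w": (0.0, 1.0),
    "alpha": (1e-6, 1.0),
    "lam": (0.0, 1.0),
    "beta1": (0.0, math.inf),
    "beta2": (0.0, math.inf),
    "persev": (-math.inf, math.inf),
}


def _truncnorm(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed (bounds too tight)")


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _mask_missed(trials: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    if rate <= 0:
        return trials
    mask = rng.random(len(trials)) < rate
    trials = trials.copy()
    trials.loc[mask, "missed"] = True
    for col in ("choice1", "pair", "common", "choice2", "reward"):
        trials[col] = trials[col].where(~trials["missed"], pd.NA)
    return trials


def simulate_population(
    spec: PopulationSpec,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of hybrid agents playing the task.

    Returns ``(trials, covariates, truth)``: the concatenated trial table,
    the subject covariate table (raw and standardized trait, subsample
    label) and the generating per-subject parameters for recovery tests.
    Trial counts follow the subject's subsample; ``config.n_trials`` is
    overridden accordingly. Missed trials are produced by masking
    completed trials at random at ``spec.miss_rate``.
    """
    n = spec.n_subjects
    lo, hi = spec.trait_range
    raw = np.array(
        [round(_truncnorm(spec.trait_mean, spec.trait_sd, lo, hi, rng)) for _ in range(n)]
    )
    if raw.std(ddof=1) == 0:
        raise ValueError("degenerate trait sample (constant); increase trait_sd")
    z = (raw - raw.mean()) / raw.std(ddof=1)

    subject_ids = [f"s{i + 1:03d}" for i in range(n)]
    subsample = np.repeat([1, 2], spec.subsample_sizes)

    trials_parts: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i, sid in enumerate(subject_ids):
        draws = {
            name: _truncnorm(*getattr(spec, name), *_PARAM_BOUNDS[name], rng)
            for name in ("w", "alpha", "lam", "beta1", "beta2", "persev")
        }
        draws["w"] = _expit(_logit(draws["w"]) + spec.link_w * z[i])
        if draws["beta1"] > 0:
            draws["beta1"] = math.exp(
                math.log(draws["beta1"]) + spec.link_beta1 * z[i]
            )
        params = AgentParams(**draws)
        n_trials = spec.subsample_trials[subsample[i] - 1]
        sess_config = TaskConfig(
            n_trials=n_trials,
            p_common=config.p_common,
            walk_sd=config.walk_sd,
            lower_bound=config.lower_bound,
            upper_bound=config.upper_bound,
            initial_probs=config.initial_probs,
        )
        agent = HybridAgent(params, sess_config)
        trials, _ = simulate_session(agent, sess_config, rng, subject_id=sid)
        trials = _mask_missed(trials, spec.miss_rate, rng)
        trials_parts.append(trials)
        truth_rows.append({"subject_id": sid, "trait_z": z[i], **draws})

    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "extraversion_raw": raw,
            "extraversion_z": z,
            "subsample": subsample,
        }
    )
    truth = pd.DataFrame(truth_rows)
    return pd.concat(trials_parts, ignore_index=True), covariates, truth


# ---------------------------------------------------------------------------
# direct generative form of the analysis model


@dataclass(frozen=True)
class RegressionGenSpec:
    """Generative form of the multilevel stay/switch logistic model.

    ``fixed_coefs`` maps design-column names (see
    :func:`twostep.hier_logit.build_design`) to coefficients; missing
    terms are zero. ``re_cov`` is the 4x4 random-effect covariance over
    (Intercept, trans, rew, trans:rew); the default is independent
    effects with SD 0.3. Predictor sequences are drawn i.i.d.: reward
    ±1 with marginal probability ``p_reward_marginal`` (the study's
    observed reward rate was close to 0.5), transition +1 with
    probability ``p_common``.
    """

    fixed_coefs: dict = field(
        default_factory=lambda: {
            "Intercept": 1.0,
            "trans": 0.0,
            "rew": 0.198,
            "trans:rew": 0.132,
        }
    )
    re_cov: tuple = tuple(map(tuple, (0.09 * np.eye(4)).tolist()))
    n_subjects: int = 97
    n_trials: int = 300
    p_reward_marginal: float = 0.5
    p_common: float = 0.7

    def re_cov_matrix(self) -> np.ndarray:
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError("re_cov must be a symmetric 4x4 matrix")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("re_cov must be positive semidefinite")
        return cov

    def __post_init__(self) -> None:
        self.re_cov_matrix()
        if not 0.0 < self.p_reward_marginal < 1.0:
            raise ValueError("p_reward_marginal must lie in (0, 1)")
        if not 0.5 < self.p_common <= 1.0:
            raise ValueError("p_common must lie in (0.5, 1]")


def simulate_from_regression(
    spec: RegressionGenSpec,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    moderators: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Draw an encoded stay/switch dataset directly from the analysis model.

    Returns a design-row table (subject_id, outcome_trial, stay, rew,
    trans, rewXtrans). When ``moderators`` are given, ``covariates`` must
    hold the corresponding standardized columns; the linear predictor then
    includes the full factorial expansion of the within-subject terms with
    the moderators, with coefficients looked up in ``spec.fixed_coefs``.
    """
    from .hier_logit import build_design

    cov = spec.re_cov_matrix()
    n_rows = spec.n_trials - 1
    if moderators and covariates is None:
        raise ValueError("moderators require a covariate table")
    subject_ids = (
        list(covariates["subject_id"])
        if covariates is not None
        else [f"s{i + 1:03d}" for i in range(spec.n_subjects)]
    )
    n_subj = len(subject_ids)
    b = rng.multivariate_normal(np.zeros(4), cov, size=n_subj)  # svd: PSD-safe
    rew = np.where(rng.random((n_subj, n_rows)) < spec.p_reward_marginal, 1, -1)
    trans = np.where(rng.random((n_subj, n_rows)) < spec.p_common, 1, -1)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_rows),
            "outcome_trial": np.tile(np.arange(2, spec.n_trials + 1), n_subj),
            "rew": rew.ravel(),
            "trans": trans.ravel(),
        }
    )
    df["rewXtrans"] = df["rew"] * df["trans"]
    if moderators:
        cov_idx = covariates.set_index("subject_id")
        for m in moderators:
            df[m] = cov_idx[m].reindex(df["subject_id"]).to_numpy(dtype=float)
    X, names = build_design(df, moderators)
    beta = np.array([spec.fixed_coefs.get(name, 0.0) for name in names])
    group = np.repeat(np.arange(n_subj), n_rows)
    eta = X @ beta + np.einsum("ij,ij->i", X[:, :4], b[group])
    stay = (rng.random(n_subj * n_rows) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df.insert(2, "stay", stay)
    return df
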
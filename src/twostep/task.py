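"""Generative model of the two-stage sequential decision task.

On each trial the participant chooses one of two first-stage options; the
choice leads stochastically (common transition with probability ``p_common``,
rare otherwise) to one of two second-stage option pairs, where a second
choice yields a binary monetary reward. The four second-stage reward
probabilities drift as independent Gaussian random walks with reflecting
boundaries, forcing continual learning.

The module provides the drifting-reward environment, the transition and
reward samplers, and a session harness that plays an arbitrary choice policy
(an object implementing :class:`Agent`) through a full session, emitting a
trial table and the latent walk trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Agent",
    "reflect",
    "step_reward_walk",
    "simulate_walk",
    "sample_transition",
    "sample_reward",
    "simulate_session",
    "TRIAL_COLUMNS",
    "WALK_COLUMNS",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "choice1",
    "pair",
    "common",
    "choice2",
    "reward",
    "missed",
]

#: Latent reward-probability trajectory columns, indexed (pair, option).
WALK_COLUMNS = ["trial", "p00", "p01", "p10", "p11"]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-stage task environment.

    Parameters
    ----------
    n_trials
        Trials per session (the study used 300 or 350).
    p_common
        Probability that a first-stage choice leads to its canonical
        second-stage pair. Must lie in (0.5, 1].
    walk_sd
        SD of the per-step Gaussian perturbation of each reward
        probability, on the probability scale.
    lower_bound, upper_bound
        Reflecting boundaries of the reward-probability walks.
    initial_probs
        Optional 4 starting probabilities, ordered (pair 0 option 0,
        pair 0 option 1, pair 1 option 0, pair 1 option 1). ``None``
        draws them uniformly within the bounds.
    seed
        Session seed, recorded for provenance; ``None`` leaves seeding
        to the caller.
    """

    n_trials: int = 300
    p_common: float = 0.7
    walk_sd: float = 0.025
    lower_bound: float = 0.25
    upper_bound: float = 0.75
    initial_probs: tuple[float, float, float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        if not 0.5 < self.p_common <= 1.0:
            raise ValueError("p_common must lie in (0.5, 1]")
        if not self.walk_sd > 0:
            raise ValueError("walk_sd must be positive")
        if not 0.0 <= self.lower_bound < self.upper_bound <= 1.0:
            raise ValueError("require 0 <= lower_bound < upper_bound <= 1")
        if self.initial_probs is not None:
            p = np.asarray(self.initial_probs, dtype=float)
            if p.shape != (4,):
                raise ValueError("initial_probs must have exactly 4 entries")
            if (p < self.lower_bound).any() or (p > self.upper_bound).any():
                raise ValueError("initial_probs must lie within the bounds")

    def draw_initial_probs(self, rng: np.random.Generator) -> np.ndarray:
        if self.initial_probs is not None:
            return np.asarray(self.initial_probs, dtype=float)
        return rng.uniform(self.lower_bound, self.upper_bound, size=4)


def reflect(x: np.ndarray | float, lower: float, upper: float) -> np.ndarray | float:
    """Fold values into [lower, upper] by repeated boundary reflection.

    Implements the reflecting-walk map (p' > U -> 2U - p', p' < L -> 2L - p',
    iterated until inside) in closed form as a triangle wave of period
    2*(upper - lower).
    """
    width = upper - lower
    y = np.mod(np.asarray(x, dtype=float) - lower, 2.0 * width)
    out = lower + np.where(y > width, 2.0 * width - y, y)
    if np.ndim(x) == 0:
        return float(out)
    return out


def step_reward_walk(
    probs: np.ndarray, config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Advance the 4 reward probabilities by one Gaussian step with reflection."""
    probs = np.asarray(probs, dtype=float)
    proposed = probs + rng.normal(0.0, config.walk_sd, size=probs.shape)
    new = reflect(proposed, config.lower_bound, config.upper_bound)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("reward walk produced non-finite probability")
    return new


def simulate_walk(
    n_steps: int,
    config: TaskConfig,
    rng: np.random.Generator,
    n_walks: int = 4,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate reflecting reward-probability walks.

    Returns an array of shape ``(n_steps + 1, n_walks)`` including the
    initial state. Noise for all steps is drawn up front; the per-step
    reflection is identical to :func:`step_reward_walk`.
    """
    if initial is None:
        start = rng.uniform(config.lower_bound, config.upper_bound, size=n_walks)
    else:
        start = np.asarray(initial, dtype=float)
        if start.shape != (n_walks,):
            raise ValueError("initial must have shape (n_walks,)")
    noise = rng.normal(0.0, config.walk_sd, size=(n_steps, n_walks))
    lo, hi = config.lower_bound, config.upper_bound
    width = hi - lo
    period = 2.0 * width
    out = np.empty((n_steps + 1, n_walks), dtype=float)
    out[0] = start
    # tight scalar loop: reflection is per-step, so the walk is sequential
    pos = start.tolist()
    noise_list = noise.tolist()
    for t in range(n_steps):
        row = noise_list[t]
        for k in range(n_walks):
            p = pos[k] + row[k]
            if p > hi or p < lo:
                y = (p - lo) % period
                p = lo + (period - y if y > width else y)
            pos[k] = p
        out[t + 1] = pos
    return out


def canonical_pair(choice1: int) -> int:
    """Second-stage pair most often reached from a first-stage choice.

    The labelling convention is choice 0 <-> pair 0, choice 1 <-> pair 1;
    the mapping for choice 1 is the mirror of choice 0 and is fixed for the
    whole session.
    """
    return int(choice1)


def sample_transition(
    choice1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, bool]:
    """Sample the second-stage pair reached after a first-stage choice.

    Returns ``(pair, common)`` where ``common`` is True iff the canonical
    pair of ``choice1`` was reached.
    """
    if choice1 not in (0, 1):
        raise ValueError(f"choice1 must be 0 or 1, got {choice1!r}")
    common = bool(rng.random() < config.p_common)
    pair = canonical_pair(choice1) if common else 1 - canonical_pair(choice1)
    return pair, common


def sample_reward(prob: float, rng: np.random.Generator) -> int:
    """Bernoulli reward draw for the chosen second-stage option."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"reward probability must lie in [0, 1], got {prob!r}")
    return int(rng.random() < prob)


@runtime_checkable
class Agent(Protocol):
    """Choice policy interface consumed by :func:`simulate_session`.

    The harness draws the realised choices from the probabilities the agent
    supplies, then feeds the trial's outcome back through ``observe``.
    """

    def stage1_probs(self) -> np.ndarray:
        """Length-2 probability vector over first-stage options."""

    def stage2_probs(self, pair: int) -> np.ndarray:
        """Length-2 probability vector over the presented pair's options."""

    def observe(self, choice1: int, pair: int, choice2: int, reward: int) -> None:
        """Update internal state after a completed trial."""


def _validate_choice_probs(p: np.ndarray, stage: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise ValueError(f"agent produced invalid {stage} probabilities: {p!r}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"agent {stage} probabilities must be a distribution: {p!r}")
    return p


def simulate_session(
    agent: Agent,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "s001",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Play one agent through a full session of the task.

    Returns ``(trials, walk)``: the trial table (one row per trial, schema
    :data:`TRIAL_COLUMNS`) and the latent reward-probability trajectory used
    on each trial (schema :data:`WALK_COLUMNS`). The walk advances once per
    trial; reward on trial t uses the walk state of trial t.
    """
    probs = config.draw_initial_probs(rng)
    records: list[tuple] = []
    walk_rows: list[tuple] = []
    for t in range(1, config.n_trials + 1):
        walk_rows.append((t, *probs))
        p1 = _validate_choice_probs(agent.stage1_probs(), "stage-1")
        choice1 = int(rng.random() >= p1[0])
        pair, common = sample_transition(choice1, config, rng)
        p2 = _validate_choice_probs(agent.stage2_probs(pair), "stage-2")
        choice2 = int(rng.random() >= p2[0])
        reward = sample_reward(probs[2 * pair + choice2], rng)
        agent.observe(choice1, pair, choice2, reward)
        records.append((subject_id, t, choice1, pair, common, choice2, reward, False))
        probs = step_reward_walk(probs, config, rng)
    trials = pd.DataFrame(records, columns=TRIAL_COLUMNS)
    trials = trials.astype(
        {
            "trial": "int64",
            "choice1": "Int64",
            "pair": "Int64",
            "common": "boolean",
            "choice2": "Int64",
            "reward": "Int64",
            "missed": "bool",
        }
    )
    walk = pd.DataFrame(walk_rows, columns=WALK_COLUMNS)
    return trials, walk
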
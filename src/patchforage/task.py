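"""Timed patch-leaving task simulator.

A session consists of four 720-second blocks arranged in a 2x2 factorial
design crossing within-patch reward decay (fast = 0.81, slow = 0.91 mean
multiplier per dig) with between-patch travel time (short = 2.5 s,
long = 9 s).  On each patch the first dig is forced and pays a Gaussian
reward (mean 100, SD 10); each further dig pays the previous reward times
a decay constant drawn fresh per dig from a Gaussian (block-specific mean,
SD 0.07) censored above at 1.  A leave decision triggers the travel delay
and a fresh patch.

Clock semantics: every event duration — the decision reaction time, the
1.5-s reward feedback after a dig, and the travel delay — consumes block
time.  A block starts with one travel delay and ends at the first decision
onset at which no time remains; the patch in progress at that point is left
without a leave action and is recognisably truncated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "BlockCondition",
    "Observation",
    "Agent",
    "FixedActionsAgent",
    "default_conditions",
    "sample_initial_reward",
    "sample_decay",
    "step",
    "run_block",
    "run_session",
    "TRIAL_COLUMNS",
    "EXPLOIT",
    "LEAVE",
]

EXPLOIT = "exploit"
LEAVE = "leave"

#: Fixed column order of the trial table (one decision event per row).
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "block_index",
    "decay_cond",
    "travel_cond",
    "patch_index",
    "action_index",
    "action",
    "forced",
    "reward",
    "rt_s",
    "time_remaining_s",
]

#: Guard against non-terminating agents with zero-duration events.
MAX_TRIALS_PER_BLOCK = 10_000


@dataclass(frozen=True)
class BlockCondition:
    """One cell of the decay x travel design with its generative constants."""

    decay_mean: float
    travel_time_s: float
    decay_cond: str = ""
    travel_cond: str = ""
    decay_sd: float = 0.07
    block_duration_s: float = 720.0
    reward0_mean: float = 100.0
    reward0_sd: float = 10.0
    feedback_duration_s: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.decay_mean <= 1.0):
            raise ValueError(f"decay_mean must be in (0, 1], got {self.decay_mean}")
        if self.decay_sd < 0:
            raise ValueError("decay_sd must be >= 0")
        if self.travel_time_s <= 0:
            raise ValueError("travel_time_s must be > 0")
        if self.block_duration_s < 0:
            raise ValueError("block_duration_s must be >= 0")
        if self.reward0_mean <= 0:
            raise ValueError("reward0_mean must be > 0")
        if self.reward0_sd < 0:
            raise ValueError("reward0_sd must be >= 0")
        if not self.decay_cond:
            object.__setattr__(self, "decay_cond", "fast" if self.decay_mean <= 0.86 else "slow")
        if not self.travel_cond:
            object.__setattr__(self, "travel_cond", "short" if self.travel_time_s <= 5.0 else "long")


def default_conditions() -> list[BlockCondition]:
    """The four study conditions: {0.81, 0.91} decay x {2.5, 9} s travel."""
    return [
        BlockCondition(decay_mean=d, travel_time_s=t)
        for d in (0.81, 0.91)
        for t in (2.5, 9.0)
    ]


def sample_initial_reward(cond: BlockCondition, rng: np.random.Generator) -> float:
    """First-dig reward: Gaussian(reward0_mean, reward0_sd), clamped at 0 below."""
    return max(0.0, rng.normal(cond.reward0_mean, cond.reward0_sd))


def sample_decay(cond: BlockCondition, rng: np.random.Generator) -> float:
    """Per-dig decay constant k: Gaussian censored above at 1, clamped at 0.

    Draws above 1 are set to exactly 1, so within-patch rewards never
    increase.  The lower clamp is defensive; at the study parameters a
    draw below 0 is a >11-sigma event.
    """
    k = rng.normal(cond.decay_mean, cond.decay_sd)
    return min(1.0, max(0.0, k))


@dataclass
class PatchState:
    """Mutable state of the patch currently being exploited."""

    last_reward: float | None = None
    n_actions: int = 0


@dataclass(frozen=True)
class Observation:
    """What the agent sees at a decision onset."""

    last_reward: float | None
    time_remaining_s: float
    forced: bool
    patch_index: int
    action_index: int
    condition: BlockCondition


class Agent(Protocol):
    """Decision policy interface used by :func:`run_block`."""

    def begin_block(self, cond: BlockCondition) -> None: ...

    def act(self, obs: Observation, rng: np.random.Generator) -> tuple[str, float]:
        """Return (action, reaction time in seconds)."""
        ...

    def observe(self, action: str, reward: float | None) -> None:
        """Feedback after the action resolves (reward is None on leave)."""
        ...


class FixedActionsAgent:
    """Dig a fixed number of times on every patch, then leave.

    Used for the optimal-residence policy sweep; reaction times are
    deterministic at ``rt_s``.
    """

    def __init__(self, n_actions: int, rt_s: float = 1.0):
        if n_actions < 1:
            raise ValueError("n_actions must be >= 1")
        self.n_actions = n_actions
        self.rt_s = rt_s

    def begin_block(self, cond: BlockCondition) -> None:
        pass

    def act(self, obs: Observation, rng: np.random.Generator) -> tuple[str, float]:
        action = EXPLOIT if obs.action_index <= self.n_actions else LEAVE
        return action, self.rt_s

    def observe(self, action: str, reward: float | None) -> None:
        pass


def step(
    patch: PatchState,
    action: str,
    cond: BlockCondition,
    rng: np.random.Generator,
) -> tuple[float | None, PatchState]:
    """Resolve one action on a patch; returns (reward, next patch state).

    The first action on a fresh patch must be an exploit (the task forces
    the first dig); its reward is the patch's initial Gaussian draw.  Each
    later exploit pays the previous reward times a fresh decay draw.  A
    leave pays nothing and abandons the patch.
    """
    if action not in (EXPLOIT, LEAVE):
        raise ValueError(f"unknown action {action!r}")
    if patch.n_actions == 0 and action == LEAVE:
        raise ValueError("the first action on a patch is a forced exploit; cannot leave")
    if action == LEAVE:
        return None, replace_patch(patch, patch.last_reward)
    if patch.last_reward is None:
        reward = sample_initial_reward(cond, rng)
    else:
        reward = patch.last_reward * sample_decay(cond, rng)
    return reward, replace_patch(patch, reward)


def replace_patch(patch: PatchState, last_reward: float | None) -> PatchState:
    return PatchState(last_reward=last_reward, n_actions=patch.n_actions + 1)


def run_block(
    agent: Agent,
    cond: BlockCondition,
    rng: np.random.Generator,
    max_trials: int = MAX_TRIALS_PER_BLOCK,
) -> list[dict]:
    """Run one block to timeout; returns trial records as dicts.

    The block clock starts at ``block_duration_s``, pays the initial travel
    delay, then alternates decision onsets and event durations.  Time
    remaining is recorded at each decision onset; the block ends at the
    first onset with no time remaining.
    """
    records: list[dict] = []
    remaining = cond.block_duration_s - cond.travel_time_s
    agent.begin_block(cond)
    patch_index = 0
    while True:
        patch_index += 1
        patch = PatchState()
        in_patch = True
        while in_patch:
            if remaining <= 0:
                return records  # block timeout; current patch truncated
            if len(records) >= max_trials:
                raise RuntimeError(
                    f"exceeded {max_trials} trials in one block; "
                    "check event durations in the configuration"
                )
            action_index = patch.n_actions + 1
            forced = action_index == 1
            obs = Observation(
                last_reward=patch.last_reward,
                time_remaining_s=remaining,
                forced=forced,
                patch_index=patch_index,
                action_index=action_index,
                condition=cond,
            )
            action, rt = agent.act(obs, rng)
            if forced and action != EXPLOIT:
                raise ValueError("agent attempted to leave on the forced first dig")
            reward, patch = step(patch, action, cond, rng)
            records.append(
                {
                    "patch_index": patch_index,
                    "action_index": action_index,
                    "action": action,
                    "forced": forced,
                    "reward": reward,
                    "rt_s": rt,
                    "time_remaining_s": remaining,
                }
            )
            agent.observe(action, reward)
            remaining -= rt
            if action == EXPLOIT:
                remaining -= cond.feedback_duration_s
            else:
                remaining -= cond.travel_time_s
                in_patch = False


def run_session(
    agent: Agent,
    conditions: Iterable[BlockCondition],
    rng: np.random.Generator,
    participant_id: str = "sim",
    group: str = "NA",
) -> pd.DataFrame:
    """Run a four-block session with block order randomised by ``rng``.

    ``conditions`` must contain exactly one condition per cell of the
    2x2 decay x travel design.
    """
    conds = list(conditions)
    cells = [(c.decay_cond, c.travel_cond) for c in conds]
    if len(conds) != 4 or len(set(cells)) != 4:
        raise ValueError(
            "run_session requires exactly one condition per decay x travel cell; "
            f"got cells {cells}"
        )
    order = rng.permutation(len(conds))
    frames = []
    for block_index, ci in enumerate(order, start=1):
        cond = conds[ci]
        recs = run_block(agent, cond, rng)
        df = pd.DataFrame(recs, columns=TRIAL_COLUMNS[5:])
        df.insert(0, "participant_id", participant_id)
        df.insert(1, "group", group)
        df.insert(2, "block_index", block_index)
        df.insert(3, "decay_cond", cond.decay_cond)
        df.insert(4, "travel_cond", cond.travel_cond)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]
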
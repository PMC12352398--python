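"""MVT reward-rate choice model: likelihood, fitting, forward simulation.

The model treats each exploit/leave decision as a comparison between the
last reward obtained from the current patch, ``r_{t-1}``, and a leaving
threshold ``T_t`` equal to a running delta-rule estimate of the
environment's reward rate:

    P(exploit)_t = 1 / (1 + exp(-[c + beta * (r_{t-1} - T_t)]))
    r_hat_t      = r_hat_{t-1} + alpha   * (r_t - r_hat_{t-1})   after a dig
    r_hat_t      = r_hat_{t-1} + alpha_l * (0   - r_hat_{t-1})   after a leave
    T_t          = r_hat_t

Four free parameters: learning rates ``alpha`` (rewarded updates) and
``alpha_l`` (leave updates), both in [0, 1]; choice sensitivity ``beta`` in
[0, 2]; exploitation bias ``c`` in [-50, 50].  The reward-rate estimate is
initialised at 50 at the start of each block.  The forced first dig on
every patch is assigned probability 1 - 1e-5 without the logistic rule, and
all exploit probabilities are clamped to [1e-5, 1 - 1e-5].  The decision at
trial t uses the threshold formed from all updates through trial t-1; the
update for trial t's outcome is applied after the choice (the forced dig
updates the estimate too — it is an exploit with feedback).

Fitting is participant-level maximum likelihood: bounded L-BFGS-B from
multiple uniformly drawn start points within the parameter box, keeping the
best.  :class:`MVTForagingModel` / :class:`MVTForagingResults` follow the
model/results idiom of statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import task
from .task import EXPLOIT, LEAVE, Agent, BlockCondition, Observation

__all__ = [
    "ModelParams",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "P_CLAMP",
    "R_HAT_INIT",
    "p_exploit",
    "update_reward_rate",
    "negative_log_likelihood",
    "MVTForagingModel",
    "MVTForagingResults",
    "MVTAgent",
    "fit_participant",
    "fit_cohort",
    "simulate_agent",
]

PARAM_NAMES = ("alpha", "alpha_l", "beta", "c")
PARAM_BOUNDS = ((0.0, 1.0), (0.0, 1.0), (0.0, 2.0), (-50.0, 50.0))
P_CLAMP = 1e-5
R_HAT_INIT = 50.0


@dataclass(frozen=True)
class ModelParams:
    """The four free parameters; bounds are part of the type."""

    alpha: float
    alpha_l: float
    beta: float
    c: float

    def __post_init__(self):
        for name, value, (lo, hi) in zip(PARAM_NAMES, self.as_array(), PARAM_BOUNDS):
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite")
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.alpha_l, self.beta, self.c])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModelParams":
        return cls(*[float(v) for v in x])


@dataclass
class ModelState:
    """Latent reward-rate estimate; the leaving threshold T mirrors it."""

    r_hat: float = R_HAT_INIT

    @property
    def T(self) -> float:
        return self.r_hat


def p_exploit(params: ModelParams, r_prev: float, T: float) -> float:
    """Logistic exploit probability, clamped to [1e-5, 1 - 1e-5]."""
    x = params.c + params.beta * (r_prev - T)
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x))
    else:  # numerically safe for large negative arguments
        e = math.exp(x)
        p = e / (1.0 + e)
    return min(1.0 - P_CLAMP, max(P_CLAMP, p))


def update_reward_rate(
    params: ModelParams, state: ModelState, action: str, reward: float | None = None
) -> ModelState:
    """One delta-rule step: toward the reward after a dig, toward 0 after a leave."""
    if action == EXPLOIT:
        if reward is None or not np.isfinite(reward):
            raise ValueError("exploit update requires a finite reward")
        r_hat = state.r_hat + params.alpha * (reward - state.r_hat)
    elif action == LEAVE:
        r_hat = state.r_hat + params.alpha_l * (0.0 - state.r_hat)
    else:
        raise ValueError(f"unknown action {action!r}")
    return ModelState(r_hat=r_hat)


# ---------------------------------------------------------------------------
# Fast likelihood kernel.  The recursion over the reward-rate estimate is
# inherently sequential, so the kernel is a scalar loop compiled with numba;
# a pure-python twin serves as fallback and as the step-by-step oracle used
# in the tests.
# ---------------------------------------------------------------------------


def _nll_kernel_py(alpha, alpha_l, beta, c, r_prev, is_exploit, is_forced, reward):
    lo = P_CLAMP
    hi = 1.0 - P_CLAMP
    r_hat = R_HAT_INIT
    nll = 0.0
    n = r_prev.shape[0]
    for i in range(n):
        if is_forced[i]:
            p = hi
        else:
            x = c + beta * (r_prev[i] - r_hat)
            if x >= 0:
                p = 1.0 / (1.0 + math.exp(-x))
            else:
                e = math.exp(x)
                p = e / (1.0 + e)
            if p < lo:
                p = lo
            elif p > hi:
                p = hi
        if is_exploit[i]:
            nll -= math.log(p)
            r_hat = r_hat + alpha * (reward[i] - r_hat)
        else:
            nll -= math.log(1.0 - p)
            r_hat = r_hat + alpha_l * (0.0 - r_hat)
    return nll


try:  # compiled kernel; falls back to the python loop if numba is absent
    from numba import njit

    _nll_kernel = njit(cache=False)(_nll_kernel_py)
except Exception:  # pragma: no cover
    _nll_kernel = _nll_kernel_py


def _prepare_blocks(trials: pd.DataFrame) -> list[tuple[np.ndarray, ...]]:
    """Per-block arrays (r_prev, is_exploit, is_forced, reward) in trial order."""
    required = {"block_index", "patch_index", "action_index", "action", "forced", "reward"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    blocks = []
    for _, blk in trials.groupby("block_index", sort=True):
        blk = blk.sort_values(["patch_index", "action_index"], kind="stable")
        action = blk["action"].to_numpy()
        bad = ~np.isin(action, (EXPLOIT, LEAVE))
        if bad.any():
            raise ValueError(f"unknown actions: {set(action[bad])}")
        is_exploit = action == EXPLOIT
        is_forced = blk["forced"].to_numpy(dtype=bool)
        if np.any(is_forced & ~is_exploit):
            raise ValueError("forced trials must be exploits")
        if np.any(is_forced != (blk["action_index"].to_numpy() == 1)):
            raise ValueError("forced must hold exactly on the first action of each patch")
        reward = blk["reward"].to_numpy(dtype=float)
        if np.any(is_exploit & ~np.isfinite(reward)):
            raise ValueError("exploit trials must carry a finite reward")
        reward = np.where(is_exploit, reward, 0.0)
        # last observed reward in the same patch before each decision
        r_prev = np.zeros(len(blk))
        last = 0.0
        patch = None
        for i, (p, ex, r) in enumerate(zip(blk["patch_index"].to_numpy(), is_exploit, reward)):
            if p != patch:
                patch = p
                last = 0.0
            r_prev[i] = last
            if ex:
                last = r
        blocks.append(
            (
                r_prev,
                is_exploit.astype(np.bool_),
                is_forced.astype(np.bool_),
                reward,
            )
        )
    return blocks


def negative_log_likelihood(params: ModelParams, trials: pd.DataFrame) -> float:
    """Summed -log choice probability over a participant's trials.

    The reward-rate estimate is re-initialised at 50 at each block start,
    so the value is invariant to the order of blocks in the table.
    """
    model = MVTForagingModel(trials)
    return model.nll(params.as_array())


class MVTForagingModel:
    """Maximum-likelihood model of one participant's exploit/leave choices.

    Parameters
    ----------
    trials : pandas.DataFrame
        One participant's decision events in the standard trial-table
        schema.  Must contain a single participant.
    """

    def __init__(self, trials: pd.DataFrame):
        if "participant_id" in trials.columns:
            ids = trials["participant_id"].unique()
            if len(ids) > 1:
                raise ValueError(f"expected one participant, got {len(ids)}")
            self.participant_id = ids[0] if len(ids) else None
        else:
            self.participant_id = None
        if "rt_s" in trials.columns:
            rt = trials["rt_s"].to_numpy(dtype=float)
            if not np.all(np.isfinite(rt)):
                raise ValueError("non-finite reaction times; participant rejected")
        self._blocks = _prepare_blocks(trials)
        self.nobs = int(sum(len(b[0]) for b in self._blocks))
        self.n_free = int(sum((~b[2]).sum() for b in self._blocks))

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, participant: str | None = None):
        """Build a model for ``participant`` from a multi-participant table."""
        if participant is not None:
            trials = trials[trials["participant_id"] == participant]
            if trials.empty:
                raise ValueError(f"participant {participant!r} not in table")
        return cls(trials)

    def nll(self, x: Sequence[float]) -> float:
        """Negative log likelihood at parameter vector (alpha, alpha_l, beta, c)."""
        alpha, alpha_l, beta, c = (float(v) for v in x)
        total = 0.0
        for r_prev, is_exploit, is_forced, reward in self._blocks:
            total += _nll_kernel(alpha, alpha_l, beta, c, r_prev, is_exploit, is_forced, reward)
        return total

    def threshold_trace(self, params: ModelParams) -> np.ndarray:
        """Per-trial leaving threshold T_t used at each decision, in trial order."""
        out = []
        for r_prev, is_exploit, is_forced, reward in self._blocks:
            r_hat = R_HAT_INIT
            for i in range(len(r_prev)):
                out.append(r_hat)
                if is_exploit[i]:
                    r_hat += params.alpha * (reward[i] - r_hat)
                else:
                    r_hat += params.alpha_l * (0.0 - r_hat)
        return np.asarray(out)

    def fit(self, n_starts: int = 20, seed: int = 0) -> "MVTForagingResults":
        """Multi-start bounded maximum likelihood.

        ``n_starts`` start points are drawn uniformly within the parameter
        box from a generator seeded with ``seed``; each is refined with
        L-BFGS-B and the lowest NLL wins.  Deterministic given the seed.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in PARAM_BOUNDS])
        hi = np.array([b[1] for b in PARAM_BOUNDS])
        starts = lo + rng.random((n_starts, 4)) * (hi - lo)
        best = None
        converged = []
        best_index = 0
        for i, x0 in enumerate(starts):
            res = optimize.minimize(
                self.nll, x0, method="L-BFGS-B", bounds=PARAM_BOUNDS
            )
            converged.append(bool(res.success))
            if best is None or res.fun < best.fun:
                best = res
                best_index = i
        params = ModelParams.from_array(np.clip(best.x, lo, hi))
        identifiable = self.n_free > 0
        return MVTForagingResults(
            model=self,
            params=params,
            nll=float(best.fun),
            n_starts=n_starts,
            best_start_index=best_index,
            converged=converged,
            seed=seed,
            identifiable=identifiable,
            bse=self._bse(params, float(best.fun)),
        )

    def _bse(self, params: ModelParams, nll: float) -> np.ndarray:
        """Approximate standard errors from a central-difference Hessian."""
        x = params.as_array()
        h = np.maximum(1e-4, 1e-4 * np.abs(x))
        n = len(x)
        H = np.full((n, n), np.nan)
        try:
            f0 = nll
            for i in range(n):
                for j in range(i, n):
                    if i == j:
                        xp, xm = x.copy(), x.copy()
                        xp[i] += h[i]
                        xm[i] -= h[i]
                        H[i, i] = (self.nll(xp) - 2 * f0 + self.nll(xm)) / h[i] ** 2
                    else:
                        xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
                        xpp[[i, j]] += h[[i, j]]
                        xpm[i] += h[i]
                        xpm[j] -= h[j]
                        xmp[i] -= h[i]
                        xmp[j] += h[j]
                        xmm[[i, j]] -= h[[i, j]]
                        H[i, j] = H[j, i] = (
                            self.nll(xpp) - self.nll(xpm) - self.nll(xmp) + self.nll(xmm)
                        ) / (4 * h[i] * h[j])
            cov = np.linalg.pinv(H)
            var = np.diag(cov)
            return np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
        except Exception:
            return np.full(n, np.nan)


@dataclass
class MVTForagingResults:
    """Fit results for one participant: estimates, NLL, diagnostics."""

    model: MVTForagingModel
    params: ModelParams
    nll: float
    n_starts: int
    best_start_index: int
    converged: list[bool]
    seed: int
    identifiable: bool = True
    bse: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))

    @property
    def aic(self) -> float:
        return 2 * len(PARAM_NAMES) + 2 * self.nll

    @property
    def params_array(self) -> np.ndarray:
        return self.params.as_array()

    def mean_threshold(self) -> float:
        """Mean of the per-trial leaving threshold T_t under the fitted
        parameters (the reward-rate summary reported per participant)."""
        return float(self.model.threshold_trace(self.params).mean())

    def to_row(self) -> dict:
        row = {"participant_id": self.model.participant_id}
        row.update(dict(zip(PARAM_NAMES, self.params_array)))
        row.update(
            nll=self.nll,
            aic=self.aic,
            n_trials=self.model.nobs,
            n_free_choices=self.model.n_free,
            n_starts=self.n_starts,
            best_start_index=self.best_start_index,
            n_converged=int(sum(self.converged)),
            identifiable=self.identifiable,
            seed=self.seed,
            mean_threshold=self.mean_threshold(),
        )
        return row

    def summary(self) -> str:
        lines = [
            "MVT foraging choice model (participant-level ML fit)",
            "=" * 56,
            f"participant: {self.model.participant_id}   trials: {self.model.nobs}"
            f" (free choices: {self.model.n_free})",
            f"NLL: {self.nll:.4f}   AIC: {self.aic:.4f}   starts: {self.n_starts}"
            f" (converged {sum(self.converged)})",
            "-" * 56,
            f"{'param':>8} {'estimate':>12} {'std err':>12}  bounds",
        ]
        for name, val, se, bound in zip(PARAM_NAMES, self.params_array, self.bse, PARAM_BOUNDS):
            lines.append(f"{name:>8} {val:>12.4f} {se:>12.4f}  {bound}")
        if not self.identifiable:
            lines.append("warning: no non-forced decisions; parameters not identifiable")
        return "\n".join(lines)


def fit_participant(trials: pd.DataFrame, n_starts: int = 20, seed: int = 0) -> MVTForagingResults:
    """Convenience wrapper: build the model and fit in one call."""
    return MVTForagingModel(trials).fit(n_starts=n_starts, seed=seed)


def fit_cohort(
    trials: pd.DataFrame, n_starts: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Fit every participant in a trial table; one row of estimates each.

    Each participant gets an independent fit seed derived from ``seed``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    pids = list(pd.unique(trials["participant_id"]))
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(pids))]
    for pid, pseed in zip(pids, child_seeds):
        sub = trials[trials["participant_id"] == pid]
        res = MVTForagingModel(sub).fit(n_starts=n_starts, seed=pseed)
        row = res.to_row()
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


class MVTAgent:
    """Forward-simulation agent acting by the logistic MVT rule.

    Reaction times come from ``rt_sampler(time_remaining_s, rng)``;
    the default is a constant 1 s.
    """

    def __init__(self, params: ModelParams, rt_sampler=None):
        self.params = params
        self.rt_sampler = rt_sampler or (lambda remaining, rng: 1.0)
        self.state = ModelState()

    def begin_block(self, cond: BlockCondition) -> None:
        self.state = ModelState()

    def act(self, obs: Observation, rng: np.random.Generator) -> tuple[str, float]:
        rt = self.rt_sampler(obs.time_remaining_s, rng)
        if obs.forced:
            return EXPLOIT, rt
        p = p_exploit(self.params, obs.last_reward, self.state.T)
        action = EXPLOIT if rng.random() < p else LEAVE
        return action, rt

    def observe(self, action: str, reward: float | None) -> None:
        self.state = update_reward_rate(self.params, self.state, action, reward)


def simulate_agent(
    params: ModelParams,
    conditions: Iterable[BlockCondition] | None = None,
    rng: np.random.Generator | int | None = None,
    rt_sampler=None,
    participant_id: str = "sim",
    group: str = "NA",
) -> pd.DataFrame:
    """Simulate a full four-block session for one MVT agent."""
    if conditions is None:
        conditions = task.default_conditions()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    agent = MVTAgent(params, rt_sampler=rt_sampler)
    return task.run_session(agent, conditions, rng, participant_id=participant_id, group=group)
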
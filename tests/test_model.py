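"""Choice model: logistic rule, delta updates, likelihood, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchforage import ModelParams, MVTForagingModel, simulate_agent
from patchforage.model import (
    P_CLAMP,
    R_HAT_INIT,
    ModelState,
    fit_cohort,
    negative_log_likelihood,
    p_exploit,
    update_reward_rate,
)
from conftest import make_trials

FORCED_NLL = -math.log(1 - P_CLAMP)


def scalar_nll_oracle(params: ModelParams, trials: pd.DataFrame) -> float:
    """Step-by-step reference likelihood built only from the public
    single-trial operations; deliberately unvectorised."""
    total = 0.0
    for _, blk in trials.groupby("block_index", sort=True):
        state = ModelState()
        blk = blk.sort_values(["patch_index", "action_index"], kind="stable")
        last_reward = {}
        for row in blk.itertuples():
            if row.forced:
                p = 1 - P_CLAMP
            else:
                p = p_exploit(params, last_reward[row.patch_index], state.T)
            if row.action == "exploit":
                total -= math.log(p)
                state = update_reward_rate(params, state, "exploit", row.reward)
                last_reward[row.patch_index] = row.reward
            else:
                total -= math.log(1 - p)
                state = update_reward_rate(params, state, "leave")
    return total


def random_trial_table(rng, n_trials=200, n_blocks=2):
    """A schema-valid random trial sequence (not from the simulator)."""
    rows = []
    per_block = n_trials // n_blocks
    for bi in range(1, n_blocks + 1):
        t = 720.0
        pi, ai = 1, 0
        for _ in range(per_block):
            ai += 1
            forced = ai == 1
            if forced or rng.random() < 0.75:
                action, reward = "exploit", float(rng.uniform(0, 120))
            else:
                action, reward = "leave", None
            rows.append(("p1", "HC", bi, "fast", "short", pi, ai, action,
                         forced, reward, 1.0, t))
            t -= 2.0
            if action == "leave":
                pi += 1
                ai = 0
    from patchforage.task import TRIAL_COLUMNS

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class TestPExploit:
    def test_indifference_point(self):
        params = ModelParams(0.1, 0.1, 1.3, 0.0)
        assert p_exploit(params, 40.0, 40.0) == 0.5

    def test_clamping(self):
        assert p_exploit(ModelParams(0, 0, 0.0, 50.0), 0, 0) == 1 - P_CLAMP
        assert p_exploit(ModelParams(0, 0, 0.0, -50.0), 0, 0) == P_CLAMP

    def test_fitted_group_mean_inputs(self):
        # frozen value from an independent scalar evaluation of the
        # logistic expression at the sED group-mean parameter values
        p = p_exploit(ModelParams(0.13, 0.02, 0.20, 4.62), 37.75, 63.82)
        assert p == pytest.approx(0.3557175958002061, abs=1e-12)

    @given(
        beta=st.floats(0, 2),
        c=st.floats(-50, 50),
        r=st.floats(0, 150),
        T=st.floats(0, 150),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probability_always_clamped(self, beta, c, r, T):
        p = p_exploit(ModelParams(0.1, 0.1, beta, c), r, T)
        assert P_CLAMP <= p <= 1 - P_CLAMP


class TestUpdateRewardRate:
    def test_exploit_delta_step(self):
        st0 = ModelState(r_hat=50.0)
        st1 = update_reward_rate(ModelParams(0.5, 0.1, 1, 0), st0, "exploit", 100.0)
        assert st1.r_hat == 75.0
        assert st1.T == st1.r_hat

    def test_leave_delta_step_toward_zero(self):
        st1 = update_reward_rate(ModelParams(0.5, 0.1, 1, 0), ModelState(60.0), "leave")
        assert st1.r_hat == pytest.approx(54.0)

    def test_zero_leave_rate_keeps_estimate(self):
        st1 = update_reward_rate(ModelParams(0.5, 0.0, 1, 0), ModelState(60.0), "leave")
        assert st1.r_hat == 60.0

    def test_exploit_without_reward_rejected(self):
        with pytest.raises(ValueError, match="reward"):
            update_reward_rate(ModelParams(0.5, 0.1, 1, 0), ModelState(), "exploit")


class TestNLL:
    def test_forced_only_block(self):
        trials = make_trials([[100.0, None]])  # forced dig, then truncation
        params = ModelParams(0.1, 0.05, 0.5, 1.0)
        assert negative_log_likelihood(params, trials) == pytest.approx(FORCED_NLL)

    def test_single_free_exploit_at_half(self):
        # alpha = 0 keeps T at 50; second dig of 50 with c = 0 sits at the
        # indifference point, adding exactly ln 2 over the forced constant
        trials = make_trials([[50.0, 50.0, None]])
        params = ModelParams(0.0, 0.0, 0.7, 0.0)
        nll = negative_log_likelihood(params, trials)
        assert nll == pytest.approx(FORCED_NLL + math.log(2), abs=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        trials = random_trial_table(rng, n_trials=120)
        for seed in range(5):
            prng = np.random.default_rng(seed)
            params = ModelParams(prng.uniform(0, 1), prng.uniform(0, 1),
                                 prng.uniform(0, 2), prng.uniform(-10, 10))
            fast = MVTForagingModel(trials).nll(params.as_array())
            assert fast == pytest.approx(scalar_nll_oracle(params, trials), abs=1e-9)

    def test_block_order_invariance(self):
        rng = np.random.default_rng(9)
        trials = random_trial_table(rng, n_trials=160, n_blocks=4)
        params = ModelParams(0.2, 0.05, 0.3, 2.0)
        base = negative_log_likelihood(params, trials)
        shuffled = trials.copy()
        shuffled["block_index"] = shuffled["block_index"].map({1: 3, 2: 1, 3: 4, 4: 2})
        assert negative_log_likelihood(params, shuffled) == pytest.approx(base, abs=1e-9)

    def test_rejects_forced_leave(self):
        trials = make_trials([[100.0, 81.0]])
        trials.loc[0, "action"] = "leave"
        trials.loc[0, "reward"] = None
        with pytest.raises(ValueError, match="forced"):
            negative_log_likelihood(ModelParams(0.1, 0.1, 0.5, 0), trials)

    @given(
        alpha=st.floats(0, 1),
        alpha_l=st.floats(0, 1),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_r_hat_stays_bounded(self, alpha, alpha_l, seed):
        """The threshold trace never leaves [0, max(50, max reward)]."""
        trials = random_trial_table(np.random.default_rng(seed), n_trials=60)
        params = ModelParams(alpha, alpha_l, 0.5, 0.0)
        trace = MVTForagingModel(trials).threshold_trace(params)
        upper = max(R_HAT_INIT, trials["reward"].max())
        assert np.all(trace >= 0) and np.all(trace <= upper + 1e-9)


class TestFit:
    def test_fit_is_deterministic(self):
        trials = simulate_agent(ModelParams(0.15, 0.02, 0.3, 4.0), rng=2)
        m = MVTForagingModel(trials)
        r1 = m.fit(n_starts=5, seed=11)
        r2 = m.fit(n_starts=5, seed=11)
        assert np.array_equal(r1.params_array, r2.params_array)
        assert r1.nll == r2.nll
        assert r1.best_start_index == r2.best_start_index

    def test_recovers_known_parameters(self):
        true = ModelParams(alpha=0.15, alpha_l=0.02, beta=0.5, c=5.0)
        trials = simulate_agent(true, rng=4)
        res = MVTForagingModel(trials).fit(n_starts=10, seed=0)
        assert res.params.beta == pytest.approx(true.beta, abs=0.2)
        assert res.params.c == pytest.approx(true.c, abs=2.5)
        assert res.nll <= MVTForagingModel(trials).nll(true.as_array()) + 1e-6

    def test_degenerate_forced_only_participant_flagged(self):
        trials = make_trials([[100.0, None]])
        res = MVTForagingModel(trials).fit(n_starts=3, seed=0)
        assert not res.identifiable
        assert "not identifiable" in res.summary()

    def test_fit_cohort_one_row_per_participant(self):
        frames = [
            simulate_agent(ModelParams(0.15, 0.02, 0.3, 4.0), rng=i,
                           participant_id=f"p{i}")
            for i in range(2)
        ]
        fits = fit_cohort(pd.concat(frames, ignore_index=True), n_starts=3, seed=0)
        assert list(fits["participant_id"]) == ["p0", "p1"]
        assert {"alpha", "alpha_l", "beta", "c", "nll", "mean_threshold"} <= set(fits.columns)


class TestSimulateAgent:
    def test_saturated_bias_never_leaves(self):
        trials = simulate_agent(ModelParams(0.1, 0.1, 0.5, 50.0), rng=0)
        assert (trials["action"] == "leave").sum() == 0

    def test_negative_bias_leaves_immediately(self):
        trials = simulate_agent(ModelParams(0.1, 0.1, 0.0, -50.0), rng=0)
        complete = trials.groupby(["block_index", "patch_index"]).filter(
            lambda p: (p["action"] == "leave").any()
        )
        per_patch = complete.groupby(["block_index", "patch_index"]).size()
        assert (per_patch == 2).all()

    def test_zero_beta_leave_rate_is_binomial(self):
        c = 1.0
        trials = simulate_agent(ModelParams(0.1, 0.1, 0.0, c), rng=123)
        free = trials[~trials["forced"]]
        # leave probability is constant at 1 - logistic(c) on free trials
        p_leave = 1 - 1 / (1 + math.exp(-c))
        n = len(free)
        rate = (free["action"] == "leave").mean()
        assert n > 300
        assert abs(rate - p_leave) < 4 * math.sqrt(p_leave * (1 - p_leave) / n)
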
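"""Behavioural outcome measures and their group-level statistics.

From a trial table this module derives, per participant:

* patch residence time — clock time from arrival at a patch (first
  decision onset) to the leave response: the sum of decision reaction
  times plus the feedback interval for every dig;
* leaving threshold — the prospective reward of one further dig at the
  moment of leaving: last observed reward times the condition's mean
  decay (the expected next reward, since the realised decay draw is
  unobservable);
* vigour slope — per block, the remaining-time coefficient of a Gamma
  log-link regression of reaction time on time remaining, averaged over
  blocks.  The oriented "vigour index" is the negated slope, so that a
  larger index means stronger response acceleration;
* total reward accumulated.

Group-level inference uses two-stage summary statistics: per-participant
values compared with a Welch t-test plus a label-permutation test, and
Spearman rank correlations for symptom associations.  This approximates
the marginal group contrast that a crossed random-effects Gamma GLMM would
estimate; the approximation is deliberate and is noted in all outputs.

Patches truncated by block timeout (no leave action) are excluded from
residence and threshold metrics and counted in the returned exclusion
logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DEFAULT_DECAY_MEANS",
    "patch_residence_times",
    "leaving_thresholds",
    "vigour_slope",
    "vigour_slopes",
    "group_compare",
    "slope_symptom_correlation",
    "total_reward",
    "participant_summaries",
    "GroupTestReport",
]

DEFAULT_DECAY_MEANS = {"fast": 0.81, "slow": 0.91}
PATCH_KEYS = ["participant_id", "block_index", "patch_index"]


def _per_patch(trials: pd.DataFrame, feedback_duration_s: float) -> pd.DataFrame:
    """One row per patch with the aggregates both patch metrics need.

    A patch is complete iff it contains a leave action (leaves terminate
    patches, so at most one occurs, and only truncation removes it).
    """
    df = trials.sort_values(PATCH_KEYS + ["action_index"], kind="stable").copy()
    df["_is_exploit"] = df["action"] == "exploit"
    df["_is_leave"] = df["action"] == "leave"
    g = df.groupby(PATCH_KEYS, sort=True)
    out = g.agg(
        decay_cond=("decay_cond", "first"),
        travel_cond=("travel_cond", "first"),
        group=("group", "first"),
        n_actions=("action", "size"),
        n_exploits=("_is_exploit", "sum"),
        n_leaves=("_is_leave", "sum"),
        rt_sum=("rt_s", "sum"),
        last_reward=("reward", "last"),  # last non-missing = final dig's reward
    ).reset_index()
    out["complete"] = out["n_leaves"] > 0
    out["residence_s"] = out["rt_sum"] + feedback_duration_s * out["n_exploits"]
    return out


def patch_residence_times(
    trials: pd.DataFrame, feedback_duration_s: float = 1.5
) -> tuple[pd.DataFrame, dict]:
    """Per-patch residence times; truncated patches are excluded.

    Residence is the clock time from the first decision onset on the patch
    to the leave response: the sum of all decision reaction times plus the
    feedback interval for every dig.  Returns ``(per_patch, log)`` where
    ``per_patch`` has one row per completed patch and ``log`` counts
    exclusions.
    """
    pp = _per_patch(trials, feedback_duration_s)
    complete = pp[pp["complete"]]
    per_patch = complete[
        PATCH_KEYS + ["decay_cond", "travel_cond", "group", "n_actions", "residence_s"]
    ].reset_index(drop=True)
    return per_patch, {
        "n_truncated_patches": int((~pp["complete"]).sum()),
        "n_patches": len(per_patch),
    }


def leaving_thresholds(
    trials: pd.DataFrame,
    decay_means: dict[str, float] | None = None,
    feedback_duration_s: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Prospective reward at each leave: last observed reward x mean decay.

    Patches without an observed reward before the leave (impossible under
    the forced first dig, defensive otherwise) and truncated patches are
    excluded and counted.
    """
    decay_means = decay_means or DEFAULT_DECAY_MEANS
    pp = _per_patch(trials, feedback_duration_s)
    ok = pp["complete"] & pp["last_reward"].notna() & (pp["n_exploits"] > 0)
    sel = pp[ok].reset_index(drop=True)
    sel["threshold"] = sel["last_reward"] * sel["decay_cond"].map(decay_means)
    per_patch = sel[PATCH_KEYS + ["decay_cond", "travel_cond", "group", "threshold"]]
    return per_patch, {"n_excluded_patches": int((~ok).sum()), "n_patches": len(per_patch)}


def _gamma_log_slope(rt: np.ndarray, remaining: np.ndarray) -> tuple[float, bool]:
    """Remaining-time coefficient of a Gamma log-link GLM of RT.

    Returns (slope, degenerate_flag); constant RTs yield slope 0 with the
    flag set.
    """
    if np.ptp(rt) == 0 or np.ptp(remaining) == 0:
        return 0.0, True
    X = sm.add_constant(remaining)
    fam = sm.families.Gamma(link=sm.families.links.Log())
    try:
        res = sm.GLM(rt, X, family=fam).fit()
        return float(res.params[1]), False
    except Exception:
        return float("nan"), True


def vigour_slope(
    trials: pd.DataFrame, min_trials_per_block: int = 20
) -> tuple[float, pd.DataFrame]:
    """Vigour slope for one participant: per-block Gamma log-link slopes
    of RT on remaining time, averaged across usable blocks.

    Blocks with fewer than ``min_trials_per_block`` decisions are skipped
    (logged in the per-block table).  Decay/travel condition effects are
    absorbed by fitting each block separately.
    """
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("vigour_slope expects a single participant")
    rows = []
    for bi, blk in trials.groupby("block_index", sort=True):
        n = len(blk)
        if n < min_trials_per_block:
            rows.append({"block_index": bi, "n_trials": n, "slope": np.nan,
                         "skipped": True, "degenerate": False})
            continue
        slope, degenerate = _gamma_log_slope(
            blk["rt_s"].to_numpy(dtype=float),
            blk["time_remaining_s"].to_numpy(dtype=float),
        )
        rows.append({"block_index": bi, "n_trials": n, "slope": slope,
                     "skipped": False, "degenerate": degenerate})
    per_block = pd.DataFrame(rows)
    usable = per_block.loc[~per_block["skipped"], "slope"]
    mean_slope = float(usable.mean()) if len(usable) else float("nan")
    return mean_slope, per_block


def vigour_slopes(
    trials: pd.DataFrame, min_trials_per_block: int = 20
) -> pd.DataFrame:
    """Vigour slope and oriented vigour index for every participant."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        slope, per_block = vigour_slope(sub, min_trials_per_block)
        rows.append(
            {
                "participant_id": pid,
                "group": sub["group"].iloc[0],
                "vigour_slope": slope,
                "vigour_index": -slope,
                "n_blocks_used": int((~per_block["skipped"]).sum()),
                "n_blocks_skipped": int(per_block["skipped"].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupTestReport:
    """Welch t-test plus permutation test on a per-participant measure."""

    measure: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_welch: float
    p_perm: float
    n_perm: int
    seed: int
    note: str = (
        "two-stage summary statistics; approximates the marginal group "
        "contrast of a crossed random-effects GLMM"
    )

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_welch": self.p_welch,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def group_compare(
    values, labels, n_perm: int = 5000, seed: int = 0, measure: str = "measure"
) -> GroupTestReport:
    """Compare a per-participant measure between two groups.

    Welch two-sample t statistic with Satterthwaite df, plus a two-sided
    permutation p-value obtained by shuffling group labels ``n_perm``
    times (add-one correction).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    t_res = stats.ttest_ind(a, b, equal_var=False)
    obs = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    n_a = len(a)
    count = 0
    pooled = values.copy()
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = pooled[:n_a].mean() - pooled[n_a:].mean()
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    return GroupTestReport(
        measure=measure,
        group_a=str(groups[0]),
        group_b=str(groups[1]),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(t_res.statistic),
        df=float(t_res.df),
        p_welch=float(t_res.pvalue),
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
    )


def slope_symptom_correlation(slopes, scores) -> dict:
    """Spearman rank correlation between vigour measures and symptom scores."""
    slopes = np.asarray(slopes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(slopes) != len(scores):
        raise ValueError("inputs must be paired")
    if len(slopes) < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(slopes) == 0 or np.ptp(scores) == 0:
        return {"rho": float("nan"), "p": float("nan"), "n": len(slopes),
                "flag": "constant input; correlation undefined"}
    res = stats.spearmanr(slopes, scores)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(slopes), "flag": ""}


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (for correlation batteries)."""
    return sm.stats.multipletests(pvalues, method="holm")[1]


def total_reward(trials: pd.DataFrame) -> pd.Series:
    """Reward accumulated per participant (sum over exploit trials)."""
    if trials.empty:
        return pd.Series(dtype=float, name="total_reward")
    ex = trials[trials["action"] == "exploit"]
    out = ex.groupby("participant_id", sort=False)["reward"].sum()
    out = out.reindex(pd.unique(trials["participant_id"]), fill_value=0.0)
    out.name = "total_reward"
    return out


def _decile_rt_means(sub: pd.DataFrame) -> tuple[float, float]:
    """Mean RT in the 1st-10th ('begin') and 91st-100th ('end') quantiles
    of remaining time, computed within each block and pooled."""
    begin_vals, end_vals = [], []
    for _, blk in sub.groupby("block_index", sort=True):
        rem = blk["time_remaining_s"].to_numpy(dtype=float)
        rt = blk["rt_s"].to_numpy(dtype=float)
        if len(rem) < 10:
            continue
        lo = np.quantile(rem, 0.10)
        hi = np.quantile(rem, 0.90)
        begin_vals.extend(rt[rem <= lo])
        end_vals.extend(rt[rem >= hi])
    b = float(np.mean(begin_vals)) if begin_vals else float("nan")
    e = float(np.mean(end_vals)) if end_vals else float("nan")
    return b, e


def participant_summaries(
    trials: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    decay_means: dict[str, float] | None = None,
    feedback_duration_s: float = 1.5,
    min_trials_per_block: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """One row of derived behavioural metrics per participant.

    Residence and threshold means are reported per factor level (fast/slow
    decay, short/long travel) and overall.  If a ``participants`` table
    with a ``symptom_score`` column is supplied it is merged in.
    Returns ``(summary, log)`` with exclusion counts.
    """
    per_patch_res, res_log = patch_residence_times(trials, feedback_duration_s)
    per_patch_thr, thr_log = leaving_thresholds(trials, decay_means)
    slopes = vigour_slopes(trials, min_trials_per_block)
    totals = total_reward(trials)

    rows = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        r = per_patch_res[per_patch_res["participant_id"] == pid]
        t = per_patch_thr[per_patch_thr["participant_id"] == pid]
        row = {
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "residence_mean_s": r["residence_s"].mean(),
            "leave_threshold_mean": t["threshold"].mean(),
            "total_reward": totals.get(pid, 0.0),
        }
        for level in ("fast", "slow"):
            row[f"residence_{level}_s"] = r.loc[r["decay_cond"] == level, "residence_s"].mean()
            row[f"leave_threshold_{level}"] = t.loc[t["decay_cond"] == level, "threshold"].mean()
        for level in ("short", "long"):
            row[f"residence_{level}_s"] = r.loc[r["travel_cond"] == level, "residence_s"].mean()
            row[f"leave_threshold_{level}"] = t.loc[t["travel_cond"] == level, "threshold"].mean()
        row["mean_rt_begin_s"], row["mean_rt_end_s"] = _decile_rt_means(sub)
        rows.append(row)
    summary = pd.DataFrame(rows).merge(
        slopes.drop(columns=["group"]), on="participant_id", how="left"
    )
    if participants is not None:
        extra = [c for c in ("symptom_score", "true_b1") if c in participants.columns]
        summary = summary.merge(
            participants[["participant_id", *extra]], on="participant_id", how="left"
        )
    log = {**{f"residence_{k}": v for k, v in res_log.items()},
           **{f"threshold_{k}": v for k, v in thr_log.items()}}
    return summary, log
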
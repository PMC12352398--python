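"""Trial-table serialisation, configuration and run manifests.

Tables are plain comma-separated text with a fixed header; the reward
field is empty on leave rows.  Configuration and manifests are YAML
(nested key-value).  ``load_deposited_data`` is a best-effort adapter for
externally obtained raw data and is never required by the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, BlockCondition

__all__ = [
    "read_trials",
    "write_trials",
    "read_config",
    "write_config",
    "write_manifest",
    "conditions_from_config",
    "load_deposited_data",
    "TrialValidationError",
]


class TrialValidationError(ValueError):
    """A trial table violates the schema; message carries row numbers."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the fixed column order."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise TrialValidationError(f"missing columns: {sorted(missing)}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def _fail(problems: list[str]):
    raise TrialValidationError("; ".join(problems))


def validate_trials(trials: pd.DataFrame) -> None:
    """Check trial-table invariants; raises with offending row numbers.

    Row numbers are 0-based positions in the table (header excluded).
    """
    problems = []
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        _fail([f"missing columns: {sorted(missing)}"])
    action = trials["action"]
    bad = trials.index[~action.isin(["exploit", "leave"])]
    if len(bad):
        problems.append(f"unknown action at rows {list(bad[:5])}")
    reward = trials["reward"]
    leave_with_reward = trials.index[(action == "leave") & reward.notna()]
    if len(leave_with_reward):
        problems.append(f"reward present on leave rows {list(leave_with_reward[:5])}")
    exploit_missing = trials.index[(action == "exploit") & reward.isna()]
    if len(exploit_missing):
        problems.append(f"reward missing on exploit rows {list(exploit_missing[:5])}")
    neg = trials.index[(action == "exploit") & (reward < 0)]
    if len(neg):
        problems.append(f"negative reward at rows {list(neg[:5])}")
    forced_mismatch = trials.index[trials["forced"].astype(bool) != (trials["action_index"] == 1)]
    if len(forced_mismatch):
        problems.append(f"forced flag inconsistent at rows {list(forced_mismatch[:5])}")
    for (pid, bi), blk in trials.groupby(["participant_id", "block_index"], sort=False):
        rem = blk["time_remaining_s"].to_numpy(dtype=float)
        if len(rem) and (np.any(rem < 0)):
            problems.append(f"negative time remaining for {pid} block {bi}")
        if len(rem) > 1 and np.any(np.diff(rem) >= 0):
            problems.append(f"non-decreasing time remaining for {pid} block {bi}")
    if problems:
        _fail(problems)


def read_trials(path, validate: bool = True) -> pd.DataFrame:
    """Read and (by default) validate a trial table written by write_trials."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    trials = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise TrialValidationError(f"{path}: missing columns {sorted(missing)}")
    trials["forced"] = trials["forced"].astype(bool)
    if validate:
        validate_trials(trials)
    return trials[TRIAL_COLUMNS]


def read_config(path) -> dict:
    """Load a nested key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_manifest(manifest: dict, out_dir, name: str = "manifest.yaml") -> Path:
    """Write a reproducibility manifest into an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    write_config(manifest, path)
    return path


def conditions_from_config(cfg: dict) -> list[BlockCondition]:
    """Build block conditions from a config mapping.

    Expects ``cfg["conditions"]`` as a list of keyword mappings accepted
    by :class:`BlockCondition`; unknown keys are rejected by the
    constructor.  Shared defaults may be given under
    ``cfg["condition_defaults"]``.
    """
    defaults = cfg.get("condition_defaults", {})
    entries = cfg.get("conditions")
    if not entries:
        raise ValueError("config has no 'conditions' section")
    return [BlockCondition(**{**defaults, **e}) for e in entries]


# ---------------------------------------------------------------------------
# Best-effort adapter for externally deposited raw data
# ---------------------------------------------------------------------------

#: Synonyms accepted for each standard column when mapping deposited files.
_COLUMN_SYNONYMS = {
    "participant_id": ["participant_id", "id", "sub", "subject", "prolific_id"],
    "group": ["group", "grp", "cohort"],
    "block_index": ["block_index", "block", "blk"],
    "decay_cond": ["decay_cond", "decay", "decay_fac", "decay_rate"],
    "travel_cond": ["travel_cond", "travel", "travel_time", "tt"],
    "patch_index": ["patch_index", "patch", "island"],
    "action_index": ["action_index", "trial_in_patch", "action_num", "dig_index"],
    "action": ["action", "choice", "response"],
    "forced": ["forced", "is_forced", "first_action"],
    "reward": ["reward", "points", "medallions", "rew"],
    "rt_s": ["rt_s", "rt", "reaction_time", "rt_sec"],
    "time_remaining_s": ["time_remaining_s", "remaining_time", "time_left", "remaining"],
}


def load_deposited_data(path) -> pd.DataFrame:
    """Map an externally obtained raw-data file/directory onto the trial schema.

    Looks for CSV files, matches columns by the synonym table above and
    logs every mapping.  Fails loudly when the layout is unrecognised;
    optional by design and never needed by the tests.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"optional deposited data not present at {path}; "
            "obtain it separately if real-data reproduction is wanted"
        )
    files = [path] if path.is_file() else sorted(path.rglob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no CSV files under {path}")
    frames = []
    for f in files:
        df = pd.read_csv(f)
        lower = {c.lower().strip(): c for c in df.columns}
        mapping = {}
        for std, syns in _COLUMN_SYNONYMS.items():
            for s in syns:
                if s in lower:
                    mapping[std] = lower[s]
                    break
        missing = set(TRIAL_COLUMNS) - set(mapping)
        if missing:
            raise TrialValidationError(
                f"{f}: unrecognised schema; found columns {list(df.columns)}, "
                f"could not map {sorted(missing)}"
            )
        out = pd.DataFrame({std: df[src] for std, src in mapping.items()})
        if out["action"].dtype == object:
            out["action"] = (
                out["action"].str.lower().map({"exploit": "exploit", "dig": "exploit",
                                               "leave": "leave", "sail": "leave"})
            )
        frames.append(out[TRIAL_COLUMNS])
    return pd.concat(frames, ignore_index=True)
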
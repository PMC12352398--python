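import numpy as np
import pandas as pd
import pytest

from patchforage import BlockCondition, default_conditions
from patchforage.task import TRIAL_COLUMNS


@pytest.fixture
def conditions():
    return default_conditions()


@pytest.fixture
def fast_short():
    return BlockCondition(decay_mean=0.81, travel_time_s=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trials(patches, participant_id="p1", group="HC", block_index=1,
                decay_cond="fast", travel_cond="short", rt=1.0,
                block_duration=720.0):
    """Build a valid trial table from a list of per-patch reward lists.

    Each entry is a list of exploit rewards; a leave action is appended
    after them (pass ``None`` as last element to mark a truncated patch).
    """
    rows = []
    t = block_duration
    for pi, rewards in enumerate(patches, start=1):
        truncated = rewards and rewards[-1] is None
        rewards = [r for r in rewards if r is not None]
        for ai, r in enumerate(rewards, start=1):
            rows.append((participant_id, group, block_index, decay_cond, travel_cond,
                         pi, ai, "exploit", ai == 1, r, rt, t))
            t -= rt + 1.5
        if not truncated:
            rows.append((participant_id, group, block_index, decay_cond, travel_cond,
                         pi, len(rewards) + 1, "leave", False, None, rt, t))
            t -= rt + 2.5
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@pytest.fixture
def two_patch_trials():
    """Two completed patches: rewards (100, 81, 65.61) and (90, 72.9)."""
    return make_trials([[100.0, 81.0, 65.61], [90.0, 72.9]])
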
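import numpy as np
import pandas as pd
import pytest

import cureforest as cf


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture
def toy_outcomes():
    """The hand-computed 3-subject example: event at 1, censored at 2, event at 3."""
    return np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1])


def random_survival_data(rng, n, censor_frac=0.4, tie_round=None):
    t = rng.exponential(1.0, n)
    if tie_round is not None:
        t = t.round(tie_round)
    e = (rng.random(n) > censor_frac).astype(int)
    if e.sum() == 0:
        e[int(np.argmin(t))] = 1
    return t, e


def two_group_cohort(n_per_group=50, early_scale=0.3, late_time=5.0, rng=None):
    """A cohort split by one binary variable: group 1 fails fast, group 0 never."""
    rng = rng or np.random.default_rng(0)
    times = np.concatenate([rng.exponential(early_scale, n_per_group).clip(0.01, late_time - 1),
                            np.full(n_per_group, late_time)])
    events = np.concatenate([np.ones(n_per_group, dtype=int),
                             np.zeros(n_per_group, dtype=int)])
    w = np.concatenate([np.ones(n_per_group), np.zeros(n_per_group)])
    data = pd.DataFrame({"w": w})
    return cf.Cohort(time=times, event=events, data=data, kinds={"w": "binary"})
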
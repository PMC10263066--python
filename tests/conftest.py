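import numpy as np
import pandas as pd
import pytest

from til_subtyper.gating import counts_wide, default_gating_tree, gate_events
from til_subtyper.synthetic_data import default_cohort_spec, simulate_cohort


@pytest.fixture(scope="session")
def tree():
    return default_gating_tree()


@pytest.fixture(scope="session")
def mini_cohort(tree):
    spec = default_cohort_spec("mini")
    spec.seed = 42
    cohort, truth = simulate_cohort(spec, tree)
    return cohort, truth


@pytest.fixture(scope="session")
def mini_counts(tree, mini_cohort):
    cohort, _ = mini_cohort
    pcs = [gate_events(ev, tree, rec.sample_id) for rec, ev in cohort.iter_events()]
    return counts_wide(pcs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_events(tree, **channel_values):
    """Event table with every panel channel at a given constant (default 1.0)."""
    n = max((len(v) for v in channel_values.values() if hasattr(v, "__len__")),
            default=1)
    data = {}
    for ch in tree.channels:
        v = channel_values.get(ch, 1.0)
        data[ch] = np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
    return pd.DataFrame(data)
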
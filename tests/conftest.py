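import numpy as np
import pytest

from neuroperc.networks import WeightedBrainGraph
from neuroperc.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort spec for pipeline-level tests."""
    return CohortSpec(
        n_nodes=8,
        n_subjects=4,
        n_timepoints=120,
        hierarchy_depth=2,
        block_correlation_levels=(0.5, 0.2),
        block_value_spread=0.0,
        n_hub_nodes=2,
        n_weak_nodes=2,
        seed=7,
    )


def random_weighted_graph(rng, n, connected=True, labels=None):
    """Random complete weighted graph with distinct positive weights."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedBrainGraph(
        weights=w,
        node_labels=labels or [f"n{i}" for i in range(n)],
    )


@pytest.fixture
def make_graph(rng):
    return lambda n: random_weighted_graph(rng, n)
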
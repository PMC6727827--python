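import warnings

import numpy as np
import pytest

from bandnet import BinaryNetwork, CohortSpec, FeatureTable, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_short_series_warning():
    """Many tests use deliberately short toy series; the advisory warning
    about noisy correlation estimates is irrelevant there."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*timepoints < 2 x .*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def net_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(adjacency=a, cost=float("nan"))


@pytest.fixture
def path3():
    """Path graph a-b-c (nodes 0-1-2)."""
    return net_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def triangle():
    return net_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def star4():
    """Star K_{1,3}: node 0 is the center."""
    return net_from_edges(4, [(0, 1), (0, 2), (0, 3)])


def random_net(rng, n, p=0.35):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    a = a + a.T
    return BinaryNetwork(adjacency=a, cost=float("nan"))


def small_cohort(seed=0, **overrides):
    kwargs = dict(n_group_a=5, n_group_b=5, n_rois=8, n_timepoints=64, seed=seed)
    kwargs.update(overrides)
    spec = CohortSpec(**kwargs)
    return spec, generate_cohort(spec)


def null_table(rng, n=24, m=12):
    X = rng.standard_normal((n, m))
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    return FeatureTable(X, y)
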
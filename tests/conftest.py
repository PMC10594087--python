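import numpy as np
import pytest

from ordnet import EstimatorSettings, simulate
from ordnet.datatypes import symmetric_network


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fast_settings():
    """Estimator settings sized for test runtimes."""
    return EstimatorSettings(n_lambdas=20, lambda_min_ratio=0.05)


@pytest.fixture
def six_item_config():
    """Two balanced blocks of three items with symmetric thresholds."""
    return simulate.GeneratorConfig(
        n_subjects=400,
        item_labels=[f"i{k}" for k in range(1, 7)],
        blocks={"A": ["i1", "i2", "i3"], "B": ["i4", "i5", "i6"]},
        within_weight=0.35,
        between_weight=0.0,
        thresholds=np.array([-1.07, -0.57, -0.18, 0.18, 0.57, 1.07]),
        seed=11,
    )


@pytest.fixture
def default_truth():
    return simulate.make_true_network(simulate.default_config())


def random_network(rng, p, density=0.5, scale=0.5, labels=None):
    """Random sparse signed network used across metric/community tests."""
    weights = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                weights[i, j] = weights[j, i] = rng.uniform(-scale, scale)
    return symmetric_network(weights, labels or [f"n{k}" for k in range(p)])


def random_correlation(rng, p):
    """Random well-conditioned correlation matrix (factor construction)."""
    a = rng.standard_normal((p, p + 4))
    cov = a @ a.T + 0.5 * p * np.eye(p)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr
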
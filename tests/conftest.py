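import numpy as np
import pytest

from akiforest.forest import HyperParams, fit_forest
from akiforest.records import dataset_from_arrays
from akiforest.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort723():
    """Default-sized synthetic cohort, fixed seed, shared across tests."""
    return generate_cohort(CohortSpec(n=723, seed=11))


@pytest.fixture(scope="session")
def cohort_large():
    """Large cohort for distributional checks."""
    return generate_cohort(CohortSpec(n=10000, seed=7))


@pytest.fixture(scope="session")
def small_forest(cohort723):
    return fit_forest(cohort723, HyperParams(depth=4, MSPL=5, LC=12, n=9), seed=3)


def random_tree_dataset(seed, n=150, n_features=4, label_rate=0.4):
    """Random-feature, random-label dataset for tree stress tests."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 10, size=(n, n_features))
    y = (rng.random(n) < label_rate).astype(int)
    if y.min() == y.max():  # force both classes
        y[0], y[1] = 0, 1
    names = [f"f{i}" for i in range(n_features)]
    return dataset_from_arrays(X, y, names)
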
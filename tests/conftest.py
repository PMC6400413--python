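import numpy as np
import pytest

from bernstack import (
    BinaryOutcomeData,
    ModelSet,
    loo_predictive_table,
    partition_models,
)


@pytest.fixture(scope="session")
def three_interval_set() -> ModelSet:
    """Uniform prior partitioned at .25 and .75: priors (.25, .5, .25)."""
    return partition_models(1.0, 1.0, [0.25, 0.75])


@pytest.fixture(scope="session")
def balanced_data() -> BinaryOutcomeData:
    """10 successes out of n = 20 observations."""
    return BinaryOutcomeData(s=10, f=10)


@pytest.fixture(scope="session")
def three_interval_table(three_interval_set, balanced_data):
    return loo_predictive_table(three_interval_set, balanced_data)


def simplex_grid_search(q0, q1, s, f, step=0.001):
    """Dense grid search of the stacking objective over the simplex.

    Independent of the package's optimizer: enumerates all weight vectors
    with coordinates on a lattice of the given step and returns the best
    (weights, objective).
    """
    q0 = np.nan_to_num(np.asarray(q0, dtype=float), nan=0.0)
    q1 = np.nan_to_num(np.asarray(q1, dtype=float), nan=0.0)
    m = len(q0)
    n = s + f
    steps = int(round(1.0 / step))
    if m == 2:
        w1 = np.arange(steps + 1) / steps
        W = np.column_stack([w1, 1.0 - w1])
    elif m == 3:
        i, j = np.meshgrid(np.arange(steps + 1), np.arange(steps + 1), indexing="ij")
        mask = i + j <= steps
        w1 = i[mask] / steps
        w2 = j[mask] / steps
        W = np.column_stack([w1, w2, 1.0 - w1 - w2])
    else:
        raise NotImplementedError("grid search implemented for 2 or 3 models")
    with np.errstate(divide="ignore"):
        obj = np.zeros(len(W))
        if f > 0:
            obj += (f / n) * np.log(W @ q0)
        if s > 0:
            obj += (s / n) * np.log(W @ q1)
    best = np.argmax(obj)
    return W[best], float(obj[best])
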
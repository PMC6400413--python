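"""Seeded Bernoulli data generation and the registry of fixed study scenarios.

Four scenarios cover the package's worked examples:

* ``fig2_bernoulli`` — three interval models from partitioning a uniform
  prior at .25 and .75, with 10 successes in n = 20 observations;
* ``tumor_grid`` — transplanted-tumor "take" probabilities theta = 2^-k for
  k = 1..10 genes, uniform prior over k, 1 take out of 6 attempts;
* ``general_law`` — a point mass at theta = 1 (the law "all swans are
  white") versus a uniform model, with n all-success observations
  (default n = 2: two white swans);
* ``single_failure`` — the same pair of models with n - 1 successes and a
  single failure (default n = 20), which falsifies the law outright.

Data are stored as counts; where an order is needed (prequential demos) the
canonical order is all successes before all failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from bernstack.models import (
    BetaIntervalModel,
    BinaryOutcomeData,
    DiscreteGridModel,
    PointMassModel,
)
from bernstack.bma import ModelSet, partition_models

__all__ = ["Scenario", "generate_bernoulli", "scenario", "list_scenarios"]


def generate_bernoulli(n: int, theta: float, seed: int) -> BinaryOutcomeData:
    """An ordered exchangeable Bernoulli(theta) sequence of length n.

    Uses ``numpy.random.default_rng(seed)``; the same seed always yields the
    identical sequence.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = (rng.random(n) < theta).astype(int)
    return BinaryOutcomeData(outcomes=draws.tolist())


@dataclass(frozen=True)
class Scenario:
    """A named model set plus data, with optional expected results for fixtures."""

    name: str
    model_set: ModelSet
    data: BinaryOutcomeData
    expected: dict = field(default_factory=dict)


def _fig2_bernoulli() -> Scenario:
    model_set = partition_models(1.0, 1.0, [0.25, 0.75])
    return Scenario(
        name="fig2_bernoulli",
        model_set=model_set,
        data=BinaryOutcomeData(s=10, f=10),
        expected={
            "loo_q0": [0.7758, 0.4786, 0.2206],
            "stacking_weights": [0.5, 0.0, 0.5],
            "combined_loo_at_optimum": 0.4982,
            "posterior_prob_middle": 0.99,
            "bma_predictive_success": 0.5,
        },
    )


def _tumor_grid() -> Scenario:
    k = np.arange(1, 11)
    model = DiscreteGridModel(
        grid_values=(0.5 ** k).tolist(),
        prior_weights=[0.1] * 10,
        label="tumor_grid",
    )
    return Scenario(
        name="tumor_grid",
        model_set=ModelSet([model], prior_probs=[1.0]),
        data=BinaryOutcomeData(s=1, f=5),
        expected={"posterior_mode_k": 3},
    )


def _general_law(n: int = 2) -> Scenario:
    models = ModelSet(
        [
            PointMassModel(1.0, label="general_law"),
            BetaIntervalModel(1.0, 1.0, label="uniform"),
        ],
        prior_probs=[0.5, 0.5],
    )
    return Scenario(
        name="general_law",
        model_set=models,
        data=BinaryOutcomeData(s=n, f=0),
        expected={"stacking_weight_point": 1.0},
    )


def _single_failure(n: int = 20) -> Scenario:
    models = ModelSet(
        [
            PointMassModel(1.0, label="general_law"),
            BetaIntervalModel(1.0, 1.0, label="uniform"),
        ],
        prior_probs=[0.5, 0.5],
    )
    return Scenario(
        name="single_failure",
        model_set=models,
        data=BinaryOutcomeData(s=n - 1, f=1),
        expected={"bayes_factor_point_vs_uniform": 0.0},
    )


_REGISTRY: dict[str, Callable[..., Scenario]] = {
    "fig2_bernoulli": _fig2_bernoulli,
    "tumor_grid": _tumor_grid,
    "general_law": _general_law,
    "single_failure": _single_failure,
}


def list_scenarios() -> list[str]:
    return sorted(_REGISTRY)


def scenario(name: str, **kwargs) -> Scenario:
    """Look up a registered scenario by name.

    ``general_law`` and ``single_failure`` accept ``n=`` to change the
    sample size.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None
    return factory(**kwargs)
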
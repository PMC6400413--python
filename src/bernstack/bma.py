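"""Bayes factors, posterior model probabilities, and Bayesian model averaging.

BMA mixes model-specific posteriors and predictives with posterior model
probabilities p(M_k | y) ∝ p(M_k) p(y | M_k). When the model set is obtained
by partitioning a single continuous prior into non-overlapping intervals,
with prior model probabilities equal to the prior mass in each interval,
BMA reproduces ordinary Bayesian estimation under the unpartitioned prior
exactly (the partition-equivalence result); :func:`partition_models` builds
such a set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from bernstack.models import (
    NEG_INF,
    BetaIntervalModel,
    BinaryOutcomeData,
    Model,
    ZeroProbabilityError,
    log_marginal_likelihood,
    posterior_density,
    posterior_predictive_success,
)

__all__ = [
    "ModelSet",
    "ComparisonReport",
    "compare_models",
    "posterior_model_probs",
    "bayes_factor",
    "bma_predictive",
    "bma_posterior_density",
    "partition_models",
]


@dataclass(frozen=True)
class ModelSet:
    """An ordered collection of models, optionally with prior probabilities."""

    models: tuple[Model, ...]
    prior_probs: tuple[float, ...] | None = None

    def __init__(self, models: Sequence[Model], prior_probs: Sequence[float] | None = None):
        models = tuple(models)
        if not models:
            raise ValueError("model set must be non-empty")
        labels = [m.label for m in models]
        if len(set(labels)) != len(labels):
            raise ValueError(f"model labels must be unique, got {labels}")
        if prior_probs is not None:
            pp = tuple(float(p) for p in prior_probs)
            if len(pp) != len(models):
                raise ValueError("prior_probs length must match number of models")
            if any(p < 0 for p in pp):
                raise ValueError("prior model probabilities must be nonnegative")
            if abs(sum(pp) - 1.0) > 1e-12:
                raise ValueError(f"prior model probabilities must sum to 1, got {sum(pp)}")
            prior_probs = pp
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "prior_probs", prior_probs)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    def __len__(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model marginal likelihoods, posterior probabilities, Bayes factors.

    ``log_bayes_factors[i, j]`` is log BF of model i over model j
    (antisymmetric where finite).
    """

    labels: tuple[str, ...]
    log_marginals: tuple[float, ...]
    prior_probs: tuple[float, ...]
    posterior_probs: tuple[float, ...]
    log_bayes_factors: tuple[tuple[float, ...], ...]
    bma_predictive_success: float

    def to_frame(self) -> pd.DataFrame:
        """One row per model: label, log_marginal, prior_prob, posterior_prob."""
        return pd.DataFrame(
            {
                "label": self.labels,
                "log_marginal": self.log_marginals,
                "prior_prob": self.prior_probs,
                "posterior_prob": self.posterior_probs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        # -inf / NaN are encoded as "-inf" / None so the output is strict JSON
        def enc(x):
            if math.isnan(x):
                return None
            if math.isinf(x):
                return "-inf" if x < 0 else "inf"
            return x

        return {
            "labels": list(self.labels),
            "log_marginals": [enc(x) for x in self.log_marginals],
            "prior_probs": list(self.prior_probs),
            "posterior_probs": list(self.posterior_probs),
            "log_bayes_factors": [[enc(x) for x in row] for row in self.log_bayes_factors],
            "bma_predictive_success": self.bma_predictive_success,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def posterior_model_probs(model_set: ModelSet, data: BinaryOutcomeData) -> np.ndarray:
    """Posterior model probabilities via log-sum-exp.

    Models whose marginal likelihood is zero get posterior probability
    exactly 0 (they stay in the output, supporting the falsification
    reading of a zero Bayes factor).
    """
    if model_set.prior_probs is None:
        raise ValueError("model set has no prior model probabilities")
    log_m = np.array([log_marginal_likelihood(m, data) for m in model_set.models])
    log_prior = np.array(
        [math.log(p) if p > 0 else NEG_INF for p in model_set.prior_probs]
    )
    log_w = log_m + log_prior
    finite = ~np.isneginf(log_w)
    if not finite.any():
        raise ZeroProbabilityError("all models assign zero probability to the data")
    norm = special.logsumexp(log_w[finite])
    probs = np.zeros(len(model_set))
    probs[finite] = np.exp(log_w[finite] - norm)
    probs[finite] /= probs[finite].sum()
    return probs


def bayes_factor(model_a: Model, model_b: Model, data: BinaryOutcomeData) -> float:
    """BF_ab = p(y | M_a) / p(y | M_b); may be 0 or +inf, never 0/0."""
    la = log_marginal_likelihood(model_a, data)
    lb = log_marginal_likelihood(model_b, data)
    if la == NEG_INF and lb == NEG_INF:
        raise ZeroProbabilityError(
            "both models assign zero probability to the data; Bayes factor undefined"
        )
    if la == NEG_INF:
        return 0.0
    if lb == NEG_INF:
        return float("inf")
    return math.exp(la - lb)


def bma_predictive(model_set: ModelSet, data: BinaryOutcomeData) -> float:
    """BMA probability that one new observation is a success.

    Sum over models of p(M_k | y) times the model's posterior predictive;
    models with zero posterior probability are skipped (their predictive
    may be undefined).
    """
    probs = posterior_model_probs(model_set, data)
    out = 0.0
    for p, m in zip(probs, model_set.models):
        if p > 0:
            out += p * posterior_predictive_success(m, data)
    return out


def bma_posterior_density(
    model_set: ModelSet, data: BinaryOutcomeData, theta_grid=None
) -> np.ndarray:
    """BMA posterior density of theta on a grid (interval models only).

    Pointwise mixture of the models' truncated posteriors under the
    posterior model probabilities. Defaults to 1001 equally spaced points
    on [0, 1] inclusive.
    """
    if theta_grid is None:
        theta_grid = np.linspace(0.0, 1.0, 1001)
    theta_grid = np.asarray(theta_grid, dtype=float)
    probs = posterior_model_probs(model_set, data)
    dens = np.zeros_like(theta_grid)
    for p, m in zip(probs, model_set.models):
        if p == 0:
            continue
        if not isinstance(m, BetaIntervalModel):
            raise TypeError(
                "bma_posterior_density requires interval models; "
                f"{m.label!r} has no density on [0, 1]"
            )
        dens += p * posterior_density(m, data, theta_grid)
    return dens


def partition_models(
    base_a: float, base_b: float, cutpoints: Sequence[float]
) -> ModelSet:
    """Partition a Beta(base_a, base_b) prior at the given cutpoints.

    Returns interval models spanning [0, 1] with prior model probabilities
    equal to the base prior's mass in each interval — the construction under
    which BMA coincides with estimation under the unpartitioned prior.
    """
    cuts = [float(c) for c in cutpoints]
    if any(not 0.0 < c < 1.0 for c in cuts):
        raise ValueError("cutpoints must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    edges = [0.0] + cuts + [1.0]
    models = []
    priors = []
    for lo, hi in zip(edges, edges[1:]):
        m = BetaIntervalModel(base_a, base_b, lo, hi)
        models.append(m)
        priors.append(m.prior_interval_mass())
    priors = np.array(priors)
    priors /= priors.sum()
    return ModelSet(models, prior_probs=priors)


def compare_models(model_set: ModelSet, data: BinaryOutcomeData) -> ComparisonReport:
    """Assemble marginals, posterior probabilities, pairwise log Bayes
    factors and the BMA predictive into one report."""
    log_m = [log_marginal_likelihood(m, data) for m in model_set.models]
    post = posterior_model_probs(model_set, data)
    k = len(model_set)
    lbf = [
        tuple(
            log_m[i] - log_m[j]
            if not (log_m[i] == NEG_INF and log_m[j] == NEG_INF)
            else float("nan")
            for j in range(k)
        )
        for i in range(k)
    ]
    return ComparisonReport(
        labels=tuple(model_set.labels),
        log_marginals=tuple(log_m),
        prior_probs=tuple(model_set.prior_probs),
        posterior_probs=tuple(float(p) for p in post),
        log_bayes_factors=tuple(lbf),
        bma_predictive_success=bma_predictive(model_set, data),
    )
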
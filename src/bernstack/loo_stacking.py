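"""Exact leave-one-out predictive densities and stacking weights.

For exchangeable binary data the LOO conditional p(y_i | y_-i, M) depends
on y_i only through its value, so each model contributes exactly one pair
(q0, q1) = (p(0 | rest), p(1 | rest)) regardless of which index is held
out. Each entry is computed exactly as a ratio of marginal likelihoods:

    p(y_i = v | y_-i, M) = p(y | M) / p(y with one v removed | M).

Stacking chooses simplex weights w over models to maximize the average log
of the weighted LOO predictive densities,

    (1/n) * sum_i log( sum_k w_k p(y_i | y_-i, M_k) )
        = (f/n) log( sum_k w_k q0_k ) + (s/n) log( sum_k w_k q1_k ),

a concave objective maximized here by multiplicative (EM-style) updates,
which can approach boundary optima (weights exactly 0 or 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

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
from bernstack.bma import ModelSet

__all__ = [
    "LOOTable",
    "StackingSolution",
    "loo_predictive_table",
    "combined_loo_density",
    "stacking_objective",
    "optimize_stacking_weights",
    "stacking_predictive",
    "stacking_posterior_density",
]


@dataclass(frozen=True)
class LOOTable:
    """Per-model exact LOO predictive densities for held-out 0 and held-out 1.

    ``q0[k]`` / ``q1[k]`` are NaN when that value does not occur in the data
    (nothing to hold out) or when the entry is undefined because removing
    one observation still leaves data of zero probability under the model
    (a 0/0 conditional); ``q0_defined`` / ``q1_defined`` distinguish the
    undefined case. ``s``/``f`` record the data composition the table was
    built from.
    """

    labels: tuple[str, ...]
    q0: np.ndarray
    q1: np.ndarray
    q0_defined: np.ndarray
    q1_defined: np.ndarray
    s: int
    f: int

    @property
    def n(self) -> int:
        return self.s + self.f

    def stackable(self) -> np.ndarray:
        """Models whose every applicable LOO conditional is defined."""
        ok = np.ones(len(self.labels), dtype=bool)
        if self.f > 0:
            ok &= self.q0_defined
        if self.s > 0:
            ok &= self.q1_defined
        return ok

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model_label": self.labels,
                "q0": self.q0,
                "q1": self.q1,
                "defined": self.stackable(),
            }
        )


@dataclass(frozen=True)
class StackingSolution:
    """Simplex weights maximizing the stacking objective.

    ``flat_optimum`` is set when moving 1e-3 of weight along some feasible
    edge changes the objective by less than 1e-10 — the weights are then not
    identified (only the combined predictive is).
    """

    weights: np.ndarray
    objective_value: float
    converged: bool
    flat_optimum: bool
    labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "weights": [float(w) for w in self.weights],
            "objective_value": self.objective_value,
            "converged": self.converged,
            "flat_optimum": self.flat_optimum,
        }


def loo_predictive_table(models: ModelSet | list, data: BinaryOutcomeData) -> LOOTable:
    """Exact LOO predictive table via marginal-likelihood ratios.

    Requires n >= 2 (leaving one out must leave data behind).
    """
    if data.n < 2:
        raise ValueError(f"LOO requires at least 2 observations, got n={data.n}")
    model_list = list(models.models) if isinstance(models, ModelSet) else list(models)
    k = len(model_list)
    q0 = np.full(k, np.nan)
    q1 = np.full(k, np.nan)
    q0_def = np.zeros(k, dtype=bool)
    q1_def = np.zeros(k, dtype=bool)
    for i, m in enumerate(model_list):
        lm_full = log_marginal_likelihood(m, data)
        for value, q, q_def in ((0, q0, q0_def), (1, q1, q1_def)):
            count = data.f if value == 0 else data.s
            if count == 0:
                continue  # value absent from the data: entry not applicable
            lm_red = log_marginal_likelihood(m, data.remove(value))
            if lm_red == NEG_INF:
                # reduced data impossible: the conditional is 0/0
                warnings.warn(
                    f"LOO conditional for value {value} undefined under model "
                    f"{m.label!r} (reduced data has zero marginal likelihood)",
                    stacklevel=2,
                )
                continue
            q[i] = math.exp(lm_full - lm_red)
            q_def[i] = True
    return LOOTable(
        labels=tuple(m.label for m in model_list),
        q0=q0,
        q1=q1,
        q0_defined=q0_def,
        q1_defined=q1_def,
        s=data.s,
        f=data.f,
    )


def _entries(table: LOOTable, value: int) -> tuple[np.ndarray, np.ndarray]:
    if value == 0:
        return table.q0, table.q0_defined
    if value == 1:
        return table.q1, table.q1_defined
    raise ValueError("value must be 0 or 1")


def combined_loo_density(weights, table: LOOTable, value: int) -> float:
    """Weighted per-observation LOO predictive density sum_k w_k q_{value,k}."""
    w = np.asarray(weights, dtype=float)
    q, defined = _entries(table, value)
    if np.any((w > 0) & ~defined):
        raise ZeroProbabilityError(
            "positive stacking weight on a model whose LOO conditional is undefined"
        )
    return float(np.sum(np.where(w > 0, w * q, 0.0)))


def stacking_objective(weights, table: LOOTable, data: BinaryOutcomeData | None = None) -> float:
    """Average log weighted LOO density; -inf when a needed mixture is zero."""
    s = table.s if data is None else data.s
    f = table.f if data is None else data.f
    n = s + f
    out = 0.0
    for value, count in ((0, f), (1, s)):
        if count == 0:
            continue
        c = combined_loo_density(weights, table, value)
        out += NEG_INF if c <= 0.0 else (count / n) * math.log(c)
    return out


def _objective_counts(w: np.ndarray, q0: np.ndarray, q1: np.ndarray, s: int, f: int) -> float:
    n = s + f
    out = 0.0
    if f > 0:
        c0 = float(w @ q0)
        out += NEG_INF if c0 <= 0 else (f / n) * math.log(c0)
    if s > 0:
        c1 = float(w @ q1)
        out += NEG_INF if c1 <= 0 else (s / n) * math.log(c1)
    return out


def optimize_stacking_weights(
    table: LOOTable,
    data: BinaryOutcomeData | None = None,
    *,
    max_iter: int = 100_000,
    obj_tol: float = 1e-12,
    weight_tol: float = 1e-8,
) -> StackingSolution:
    """Maximize the stacking objective over the weight simplex.

    Models with an undefined applicable LOO conditional are excluded from
    the simplex (weight fixed at 0): their one-step conditional is 0/0 and
    any positive weight is dominated. The objective is concave, so the
    multiplicative fixed-point iteration converges to the global optimum;
    weights below 1e-6 at the end are snapped to 0 and the result is kept
    only if that costs less than 1e-10 objective.
    """
    s = table.s if data is None else data.s
    f = table.f if data is None else data.f
    n = s + f
    k = len(table.labels)
    feasible = table.stackable()
    if not feasible.any():
        raise ZeroProbabilityError("no model has defined LOO conditionals")

    idx = np.flatnonzero(feasible)
    q0 = np.nan_to_num(table.q0[idx], nan=0.0)
    q1 = np.nan_to_num(table.q1[idx], nan=0.0)
    m = len(idx)
    w = np.full(m, 1.0 / m)
    obj = _objective_counts(w, q0, q1, s, f)
    converged = False
    if m == 1:
        w[:] = 1.0
        converged = True
    else:
        for _ in range(max_iter):
            grad = np.zeros(m)  # gradient-weighted responsibility update
            if f > 0:
                c0 = w @ q0
                if c0 > 0:
                    grad += (f / n) * q0 / c0
            if s > 0:
                c1 = w @ q1
                if c1 > 0:
                    grad += (s / n) * q1 / c1
            w_new = w * grad
            tot = w_new.sum()
            if tot <= 0 or not np.isfinite(tot):
                break
            w_new /= tot
            obj_new = _objective_counts(w_new, q0, q1, s, f)
            dw = float(np.max(np.abs(w_new - w)))
            w = w_new
            if obj_new - obj < obj_tol and dw < weight_tol:
                obj = obj_new
                converged = True
                break
            obj = max(obj, obj_new)

    # snap near-zero weights to exactly 0 when that loses no objective
    snapped = np.where(w < 1e-6, 0.0, w)
    if snapped.sum() > 0 and not np.array_equal(snapped, w):
        snapped = snapped / snapped.sum()
        obj_snapped = _objective_counts(snapped, q0, q1, s, f)
        if obj - obj_snapped <= 1e-10:
            w = snapped
            obj = obj_snapped

    # flatness: does moving 1e-3 of mass along any feasible edge leave the
    # objective unchanged to 1e-10?
    flat = False
    eps = 1e-3
    for a in range(m):
        for b in range(m):
            if a == b or w[a] < eps:
                continue
            w_try = w.copy()
            w_try[a] -= eps
            w_try[b] += eps
            if abs(_objective_counts(w_try, q0, q1, s, f) - obj) < 1e-10:
                flat = True
                break
        if flat:
            break

    full_w = np.zeros(k)
    full_w[idx] = w
    return StackingSolution(
        weights=full_w,
        objective_value=obj,
        converged=converged,
        flat_optimum=flat,
        labels=table.labels,
    )


def stacking_predictive(
    solution: StackingSolution, models: ModelSet | list, data: BinaryOutcomeData
) -> float:
    """Stacking-weighted probability that the next observation is a success."""
    model_list = list(models.models) if isinstance(models, ModelSet) else list(models)
    out = 0.0
    for w, m in zip(solution.weights, model_list):
        if w > 0:
            out += w * posterior_predictive_success(m, data)
    return out


def stacking_posterior_density(
    solution: StackingSolution,
    models: ModelSet | list,
    data: BinaryOutcomeData,
    theta_grid=None,
) -> np.ndarray:
    """Mixture of per-model truncated posteriors under the stacking weights.

    Illustrative only: stacking is defined for predictive distributions, and
    its originators do not propose averaging parameter posteriors this way;
    the mixture is provided to make the contrast with BMA visible.
    """
    if theta_grid is None:
        theta_grid = np.linspace(0.0, 1.0, 1001)
    theta_grid = np.asarray(theta_grid, dtype=float)
    model_list = list(models.models) if isinstance(models, ModelSet) else list(models)
    dens = np.zeros_like(theta_grid)
    for w, m in zip(solution.weights, model_list):
        if w == 0:
            continue
        if not isinstance(m, BetaIntervalModel):
            raise TypeError(
                f"stacking_posterior_density requires interval models; "
                f"{m.label!r} has no density on [0, 1]"
            )
        dens += w * posterior_density(m, data, theta_grid)
    return dens
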
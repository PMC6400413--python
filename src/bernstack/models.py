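"""Model families and exact conjugate computations for Bernoulli data.

Three families of models for an exchangeable binary outcome with rate
``theta``:

* :class:`PointMassModel` — all prior mass on a single rate ``theta0``
  (e.g., a "general law" asserting theta = 1);
* :class:`BetaIntervalModel` — a Beta(a, b) prior truncated and renormalized
  to a sub-interval [lower, upper] of the unit interval;
* :class:`DiscreteGridModel` — a discrete prior over a finite grid of rates.

All marginal likelihoods use the ordered-sequence convention: the data are
an ordered 0/1 sequence, so p(y | M) carries no binomial coefficient. Every
ratio-based quantity (Bayes factor, posterior model probability, predictive,
LOO conditional) is invariant to that choice because the coefficient cancels.

Log marginal likelihoods are extended-real floats: finite or ``-inf`` (data
impossible under the model), never NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import special
from scipy import stats

__all__ = [
    "BinaryOutcomeData",
    "PointMassModel",
    "BetaIntervalModel",
    "DiscreteGridModel",
    "Model",
    "ZeroProbabilityError",
    "log_marginal_likelihood",
    "posterior_density",
    "posterior_predictive_success",
    "grid_posterior",
]

NEG_INF = float("-inf")

#: Minimum prior mass the base beta must place on a truncation interval.
#: Below this, marginal-likelihood ratios become numerically meaningless,
#: so model construction fails loudly instead.
PRIOR_MASS_FLOOR = 1e-12


class ZeroProbabilityError(ValueError):
    """Raised when conditioning on data that has probability zero under a model."""


def _check_log(x: float) -> float:
    """Validate an extended log value: finite or -inf, never NaN or +inf."""
    if math.isnan(x):
        raise FloatingPointError("log value is NaN")
    if x == float("inf"):
        raise FloatingPointError("log value is +inf")
    return float(x)


@dataclass(frozen=True)
class BinaryOutcomeData:
    """Exchangeable binary outcomes, as an ordered sequence and/or counts.

    Parameters
    ----------
    s, f
        Number of successes (1s) and failures (0s).
    outcomes
        Optional ordered 0/1 sequence. When given, ``s`` and ``f`` may be
        omitted and are derived; when both are given they must agree.
        Counts-only construction leaves the order unspecified.
    """

    s: int
    f: int
    outcomes: tuple[int, ...] | None = None

    def __init__(
        self,
        s: int | None = None,
        f: int | None = None,
        outcomes: Sequence[int] | None = None,
    ):
        if outcomes is not None:
            seq = tuple(int(v) for v in outcomes)
            if any(v not in (0, 1) for v in seq):
                raise ValueError("outcomes must contain only 0 and 1")
            s_seq = sum(seq)
            f_seq = len(seq) - s_seq
            if s is not None and int(s) != s_seq:
                raise ValueError(f"s={s} inconsistent with sequence ({s_seq} ones)")
            if f is not None and int(f) != f_seq:
                raise ValueError(f"f={f} inconsistent with sequence ({f_seq} zeros)")
            s, f = s_seq, f_seq
        else:
            seq = None
            if s is None or f is None:
                raise ValueError("provide either outcomes or both s and f")
        s, f = int(s), int(f)
        if s < 0 or f < 0:
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "outcomes", seq)

    @property
    def n(self) -> int:
        return self.s + self.f

    def sequence(self) -> tuple[int, ...]:
        """The ordered sequence; canonical order (all 1s first) if unspecified."""
        if self.outcomes is not None:
            return self.outcomes
        return (1,) * self.s + (0,) * self.f

    def add(self, value: int) -> "BinaryOutcomeData":
        """Counts with one extra observation of ``value`` appended."""
        if value == 1:
            return BinaryOutcomeData(s=self.s + 1, f=self.f)
        if value == 0:
            return BinaryOutcomeData(s=self.s, f=self.f + 1)
        raise ValueError("value must be 0 or 1")

    def remove(self, value: int) -> "BinaryOutcomeData":
        """Counts with one observation of ``value`` removed."""
        if value == 1:
            if self.s == 0:
                raise ValueError("no success to remove")
            return BinaryOutcomeData(s=self.s - 1, f=self.f)
        if value == 0:
            if self.f == 0:
                raise ValueError("no failure to remove")
            return BinaryOutcomeData(s=self.s, f=self.f - 1)
        raise ValueError("value must be 0 or 1")


@dataclass(frozen=True)
class PointMassModel:
    """All prior mass on a single Bernoulli rate ``theta0``."""

    theta0: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.theta0 <= 1.0:
            raise ValueError(f"theta0 must be in [0, 1], got {self.theta0}")
        if not self.label:
            object.__setattr__(self, "label", f"point({self.theta0:g})")


def _beta_interval_mass(a: float, b: float, lower: float, upper: float) -> float:
    """Mass of Beta(a, b) on [lower, upper].

    Near the right edge the direct difference of regularized incomplete
    beta values cancels catastrophically; the complement branch
    ``betaincc(lower) - betaincc(upper)`` avoids that.
    """
    if lower <= 0.0 and upper >= 1.0:
        return 1.0
    # canonical orientation: Beta(a,b) on [l,u] and Beta(b,a) on [1-u,1-l]
    # have the same mass; always evaluate the lexicographically smaller
    # parameterization so mirrored models get bit-identical masses
    lm_, um_ = 1.0 - upper, 1.0 - lower
    if (lm_, um_, b, a) < (lower, upper, a, b):
        a, b, lower, upper = b, a, lm_, um_
    # pick the branch that subtracts small numbers, not numbers near 1:
    # direct CDF difference when the interval sits in the left tail,
    # complement difference when it sits in the right tail
    iu = float(special.betainc(a, b, upper))
    if iu <= 0.5:
        return iu - float(special.betainc(a, b, lower))
    icl = float(special.betaincc(a, b, lower))
    if icl <= 0.5:
        return icl - float(special.betaincc(a, b, upper))
    return iu - float(special.betainc(a, b, lower))


@dataclass(frozen=True)
class BetaIntervalModel:
    """A Beta(base_a, base_b) prior truncated and renormalized to [lower, upper].

    Open versus closed endpoints are immaterial under a continuous prior
    (zero-measure boundaries); only ``lower < upper`` is enforced. With
    ``lower=0, upper=1`` this is the untruncated conjugate beta model.
    """

    base_a: float
    base_b: float
    lower: float = 0.0
    upper: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.base_a <= 0 or self.base_b <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(
                f"require 0 <= lower < upper <= 1, got [{self.lower}, {self.upper}]"
            )
        if self.prior_interval_mass() <= PRIOR_MASS_FLOOR:
            raise ValueError(
                f"base Beta({self.base_a}, {self.base_b}) places mass "
                f"<= {PRIOR_MASS_FLOOR} on [{self.lower}, {self.upper}]"
            )
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"beta({self.base_a:g},{self.base_b:g})[{self.lower:g},{self.upper:g}]",
            )

    def prior_interval_mass(self) -> float:
        return _beta_interval_mass(self.base_a, self.base_b, self.lower, self.upper)

    def posterior_interval_mass(self, data: BinaryOutcomeData) -> float:
        return _beta_interval_mass(
            self.base_a + data.s, self.base_b + data.f, self.lower, self.upper
        )


@dataclass(frozen=True)
class DiscreteGridModel:
    """A discrete prior over a finite grid of Bernoulli rates."""

    grid_values: tuple[float, ...]
    prior_weights: tuple[float, ...]
    label: str = "grid"

    def __init__(
        self,
        grid_values: Sequence[float],
        prior_weights: Sequence[float],
        label: str = "grid",
    ):
        gv = tuple(float(v) for v in grid_values)
        pw = tuple(float(w) for w in prior_weights)
        if len(gv) != len(pw):
            raise ValueError("grid_values and prior_weights must have equal length")
        if len(set(gv)) != len(gv):
            raise ValueError("grid values must be distinct")
        if any(not 0.0 <= v <= 1.0 for v in gv):
            raise ValueError("grid values must lie in [0, 1]")
        if any(w < 0 for w in pw):
            raise ValueError("prior weights must be nonnegative")
        if abs(sum(pw) - 1.0) > 1e-12:
            raise ValueError(f"prior weights must sum to 1, got {sum(pw)}")
        object.__setattr__(self, "grid_values", gv)
        object.__setattr__(self, "prior_weights", pw)
        object.__setattr__(self, "label", label)


Model = Union[PointMassModel, BetaIntervalModel, DiscreteGridModel]


def _log_bernoulli(theta: float, s: int, f: int) -> float:
    """log theta^s (1-theta)^f with the 0*log 0 := 0 convention."""
    out = 0.0
    if s > 0:
        out += NEG_INF if theta == 0.0 else s * math.log(theta)
    if f > 0:
        out += NEG_INF if theta == 1.0 else f * math.log1p(-theta)
    return out


def log_marginal_likelihood(model: Model, data: BinaryOutcomeData) -> float:
    """Exact log marginal likelihood log p(y | M), ordered-sequence convention.

    Returns ``-inf`` (not an error) when the data are impossible under the
    model, e.g. a failure under a point mass at theta = 1.
    """
    s, f = data.s, data.f
    if isinstance(model, PointMassModel):
        return _check_log(_log_bernoulli(model.theta0, s, f))
    if isinstance(model, BetaIntervalModel):
        a, b = model.base_a, model.base_b
        lm = special.betaln(a + s, b + f) - special.betaln(a, b)
        post_mass = model.posterior_interval_mass(data)
        prior_mass = model.prior_interval_mass()
        lm += (math.log(post_mass) if post_mass > 0 else NEG_INF) - math.log(prior_mass)
        return _check_log(lm)
    if isinstance(model, DiscreteGridModel):
        terms = [
            (math.log(w) if w > 0 else NEG_INF) + _log_bernoulli(t, s, f)
            for t, w in zip(model.grid_values, model.prior_weights)
        ]
        finite = [t for t in terms if t > NEG_INF]
        if not finite:
            return NEG_INF
        return _check_log(float(special.logsumexp(finite)))
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def posterior_density(
    model: BetaIntervalModel, data: BinaryOutcomeData, theta
) -> np.ndarray | float:
    """Posterior density of theta under an interval model.

    The posterior is Beta(a+s, b+f) truncated and renormalized to the
    model's interval; the density is 0 outside it and integrates to 1 over
    [0, 1]. ``theta`` may be a scalar or an array.
    """
    if not isinstance(model, BetaIntervalModel):
        raise TypeError("posterior_density is defined for interval models")
    theta_arr = np.asarray(theta, dtype=float)
    if np.any((theta_arr < 0) | (theta_arr > 1)):
        raise ValueError("theta must lie in [0, 1]")
    a, b = model.base_a + data.s, model.base_b + data.f
    mass = model.posterior_interval_mass(data)
    if mass <= 0:
        raise ZeroProbabilityError("posterior interval mass underflowed to zero")
    dens = stats.beta.pdf(theta_arr, a, b) / mass
    # half-open support [lower, upper) so partitioned intervals tile [0, 1]
    # without double-counting shared cutpoints (upper = 1 is included);
    # the endpoint convention is zero-measure and affects no integral
    if model.upper >= 1.0:
        inside = theta_arr >= model.lower
    else:
        inside = (theta_arr >= model.lower) & (theta_arr < model.upper)
    dens = np.where(inside, dens, 0.0)
    if np.ndim(theta) == 0:
        return float(dens)
    return dens


def posterior_predictive_success(model: Model, data: BinaryOutcomeData) -> float:
    """p(y_new = 1 | y, M), via the ratio of marginal likelihoods.

    Equals ``theta0`` for a point model and the truncated-posterior mean for
    an interval model. Raises :class:`ZeroProbabilityError` when the
    conditioning data have probability zero under the model.
    """
    lm = log_marginal_likelihood(model, data)
    if lm == NEG_INF:
        raise ZeroProbabilityError(
            f"data have zero probability under {getattr(model, 'label', model)}; "
            "the posterior predictive is undefined"
        )
    if isinstance(model, PointMassModel):
        return model.theta0
    lm_plus = log_marginal_likelihood(model, data.add(1))
    return math.exp(lm_plus - lm)


def grid_posterior(model: DiscreteGridModel, data: BinaryOutcomeData) -> np.ndarray:
    """Posterior probabilities over the grid, p(k | y) ∝ w_k θ_k^s (1-θ_k)^f."""
    log_terms = np.array(
        [
            (math.log(w) if w > 0 else NEG_INF) + _log_bernoulli(t, data.s, data.f)
            for t, w in zip(model.grid_values, model.prior_weights)
        ]
    )
    if np.all(np.isneginf(log_terms)):
        raise ZeroProbabilityError("data impossible at every grid value")
    log_norm = special.logsumexp(log_terms[~np.isneginf(log_terms)])
    with np.errstate(over="ignore"):
        post = np.exp(log_terms - log_norm)
    post[np.isneginf(log_terms)] = 0.0
    return post / post.sum()
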
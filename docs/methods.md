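# Methods

## Model and likelihood convention

All inference concerns n exchangeable binary outcomes with success
probability θ. The likelihood of an ordered sequence with s successes and
f failures is θˢ(1−θ)ᶠ; marginal likelihoods integrate this against the
model's prior. The package states its convention once, globally: the
*ordered-sequence* likelihood, with no binomial coefficient. Every
quantity the package reports — Bayes factors, posterior model
probabilities, posterior predictives, LOO conditionals, grid posteriors —
is a ratio in which the coefficient cancels, and a property test verifies
that injecting the log-coefficient leaves all such ratios unchanged.

Three conjugate families are supported.

* **Point mass at θ₀.** log p(y|M) = s·log θ₀ + f·log(1−θ₀), with
  0·log 0 := 0. A point mass at 1 encodes a general law; a single failure
  sends its marginal likelihood to exactly zero.
* **Interval-truncated beta.** For θ ~ Beta(a, b) renormalized to [l, u],

      log p(y|M) = log B(a+s, b+f) − log B(a, b)
                   + log P_{a+s,b+f}[l, u] − log P_{a,b}[l, u],

  where P_{α,β}[l, u] is the Beta(α, β) mass of the interval. The
  posterior is Beta(a+s, b+f) truncated to [l, u]; the predictive success
  probability is its mean, computed as the marginal-likelihood ratio
  p(y ⊕ 1 | M) / p(y | M).
* **Discrete grid.** log p(y|M) = logsumexp_k [log w_k + s·log θ_k +
  f·log(1−θ_k)]; the grid posterior normalizes the same terms.

## Numerical choices

* Beta-function work is in log space (`betaln`, `logsumexp`). Interval
  masses use the regularized incomplete beta with a branch rule that
  subtracts small numbers rather than numbers near 1: the direct CDF
  difference when the interval sits in the distribution's left tail, the
  survival-function difference when it sits in the right tail. An interval
  and its mirror image (a↔b, [l,u]→[1−u,1−l]) are evaluated through one
  canonical orientation, so mirrored models produce bit-identical masses
  and the predictive mirror symmetry p → 1−p holds to better than 1e-12.
* Truncation intervals must carry base-prior mass above 1e-12; below that
  floor construction fails loudly rather than returning unstable ratios.
* Interval supports are treated as [l, u) with u = 1 closed. Endpoint
  conventions are zero-measure and affect no probability or integral; the
  half-open choice makes the density of a partitioned prior tile [0, 1]
  without double-counting cutpoints, so the BMA mixture density equals the
  unpartitioned posterior density pointwise, including at the cutpoints.
* A marginal likelihood of zero is represented as −inf, never NaN; models
  with −inf marginals stay in comparison reports with posterior
  probability exactly 0. Conditioning *on* zero-probability data (an
  undefined conditional) raises `ZeroProbabilityError`.

## Exact LOO and stacking

By exchangeability p(y_i | y₋ᵢ, M) depends on i only through the value
y_i, so each model contributes one pair (q0, q1) computed as marginal
ratios p(y)/p(y₋ᵢ); a refit oracle (numerically re-deriving the truncated
posterior on y₋ᵢ) confirms the shortcut to 1e-12 in the tests. Entries for
a value absent from the data are not applicable; entries whose reduced
data have zero marginal are undefined (0/0) and flagged.

The stacking objective
(f/n)·log(Σ w_k q0_k) + (s/n)·log(Σ w_k q1_k) is concave in w. It is
maximized by multiplicative (EM-style) updates
w_k ← w_k · [(f/n)·q0_k/c0 + (s/n)·q1_k/c1], which preserve the simplex,
increase the objective monotonically, and approach boundary optima
(weights exactly 0 or 1) geometrically. Convergence requires objective
improvement < 1e-12 and weight change < 1e-8 (cap 1e5 iterations); weights
below 1e-6 are then snapped to 0 and renormalized, kept only if that costs
< 1e-10 objective. Models with undefined applicable entries are excluded
from the simplex with weight fixed at 0: their conditional is 0/0 and any
positive weight is dominated. A *flat optimum* flag is set when shifting
1e-3 of weight along some feasible edge changes the objective by < 1e-10
(e.g. duplicated models); the weights are then not identified — only the
combined predictive is — and the solver returns the maximizer it found.
Tests cross-check the optimizer against a dense simplex grid search
(step .001) on every fixture.

The stacking *posterior* mixture (`stacking_posterior_density`) averages
per-model truncated posteriors under the stacking weights. It is provided
to make the contrast with BMA visible and is labelled illustrative:
stacking is defined for predictive distributions, and its originators do
not propose averaging parameter posteriors this way.

## Partition equivalence

`partition_models(a, b, cutpoints)` cuts one Beta(a, b) prior into
interval models whose prior model probabilities equal the base prior's
interval masses. For any such partition, BMA is *identical* to posterior
inference under the unpartitioned prior: the posterior model probabilities
are the unpartitioned posterior's interval masses, the BMA posterior
density equals the Beta(a+s, b+f) density pointwise, and the BMA
predictive equals (a+s)/(a+b+n). The suite verifies this to relative
error 1e-10 on a 1001-point grid over randomized bases, cutpoint sets and
data with s, f ≤ 30 — so whether a problem is called "model comparison"
or "parameter estimation" is a matter of description, not of result.

## Prequential decomposition

The marginal likelihood factors exactly into one-step-ahead forecasts,
p(y|M) = Π p(y_i | y₁:ᵢ₋₁, M). `one_step_ahead_predictives` records the
factors and checks the accumulated log product against the directly
computed log marginal (identity holds to 1e-10 across families and random
sequences). `check_order_invariance` applies seed-pinned random
permutations (default 20 — the identity is exact, so more permutations add
nothing) and reports the maximum spread, defined as 0 when every order
gives −inf. The LOO conditionals are *not* any ordered product of these
factors — each LOO factor conditions on all n−1 remaining observations —
which is exactly why accumulating one-step forecasts (the marginal
likelihood) and averaging n−1-conditioned forecasts (LOO) can rank models
differently; `examples/prequential_decomposition.py` walks through this.

## Synthetic data and scenarios

`generate_bernoulli(n, theta, seed)` draws an ordered i.i.d. Bernoulli
sequence from `numpy.random.default_rng(seed)`; identical seeds give
identical sequences. It emulates exactly what every analysis here assumes
— exchangeable binary outcomes with a fixed rate — and nothing more: no
overdispersion, serial dependence, or drift, so passing tests speak to the
correctness of the computations under exchangeability, not to robustness
against misspecified dependence structure.

Four fixed scenarios package the worked examples: `fig2_bernoulli` (the
three-interval partition with s = f = 10), `tumor_grid` (θ_k = 2⁻ᵏ,
k = 1..10, uniform prior over k, 1 take in 6 attempts), `general_law`
(point mass at 1 vs uniform, n all-success observations; default n = 2,
the two-white-swans case, configurable because the stacking result is
independent of n), and `single_failure` (same models, n−1 successes and
one failure; default n = 20). Success encodes the law-consistent outcome
("take", white swan). Scenario data are stored as counts; where an order
is needed the canonical order is all successes first.

## Comparisons at printed precision

Reference values quoted in the tests are printed to 4 decimals (LOO
densities, combined densities) or 2 decimals (the .99 posterior model
probability); tests compare after rounding half-to-even at that precision.
Stacking weights are compared within 1e-3.

## Limitations

* Only Bernoulli outcome data and the three conjugate families; no MCMC,
  no non-conjugate likelihoods, no approximate LOO (PSIS) and no
  pseudo-BMA-type weights.
* Interval masses rely on scipy's regularized incomplete beta; for
  extremely concentrated posteriors (far beyond the tested s, f ≤ 50
  range) a truncation interval deep in a tail can underflow, which
  surfaces as a −inf marginal rather than a wrong number.
* The stacking optimizer handles the binary-outcome objective (two mixture
  terms); it is not a general simplex solver for arbitrary LOO matrices.
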
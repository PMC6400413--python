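"""Parameter estimation or model comparison? A discrete-grid example.

The probability that a transplanted tumor "takes" in a certain mouse cross
is theta = (1/2)^k, where k is the number of genes controlling
transplantability (all must be present). With k known to be between 1 and
10 and equally likely a priori, 1 take out of 6 attempts yields a posterior
over k that can be read either as a parameter posterior or as posterior
model probabilities — the two descriptions are the same computation.
"""

import numpy as np

from bernstack import BinaryOutcomeData, grid_posterior, scenario

sc = scenario("tumor_grid")
model = sc.model_set.models[0]
post = grid_posterior(model, sc.data)

print("data: 1 take out of 6 attempts")
print(f"{'k':>3} {'theta=2^-k':>12} {'p(k|y)':>9}")
for k, (theta, p) in enumerate(zip(model.grid_values, post), start=1):
    print(f"{k:>3} {theta:>12.6f} {p:>9.4f}")

print("\nposterior mode: k =", int(np.argmax(post)) + 1)
pred = float(np.sum(post * np.asarray(model.grid_values)))
print("predictive P(next transplant takes):", round(pred, 4))
# The mode at k = 3 says three genes are most plausible; the predictive
# averages 2^-k over the posterior (Bayesian model averaging over k).
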
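"""A general law ("all swans are white") versus an unknown-quantity model.

The law is a point mass at theta = 1; the rival assigns theta a uniform
prior. With only successes observed, the Bayes factor favors the law in
proportion to n + 1, while the stacking weight on the law is exactly 1 for
every n — it does not grow with evidence. A single failure falsifies the
law outright: its marginal likelihood is 0 and its posterior probability
drops to exactly 0.
"""

from bernstack import (
    BetaIntervalModel,
    BinaryOutcomeData,
    ModelSet,
    PointMassModel,
    bayes_factor,
    loo_predictive_table,
    optimize_stacking_weights,
)

law = PointMassModel(1.0, label="general_law")
uniform = BetaIntervalModel(1, 1, label="uniform")

print("all-success data:")
for n in (2, 5, 10, 100):
    data = BinaryOutcomeData(s=n, f=0)
    bf = bayes_factor(law, uniform, data)
    ms = ModelSet([law, uniform], prior_probs=[0.5, 0.5])
    sol = optimize_stacking_weights(loo_predictive_table(ms, data))
    print(f"  n={n:>3}: Bayes factor law vs uniform = {bf:g}, "
          f"stacking weight on law = {sol.weights[0]:.3f}")

data = BinaryOutcomeData(s=19, f=1)
print("\n19 successes and a single failure:")
print("  Bayes factor law vs uniform =", bayes_factor(law, uniform, data))
# The Bayes factor registers accumulating evidence (3, 6, 11, 101) and a
# lone failure drives it to exactly 0; the stacking weight is 1 regardless
# of n, so it cannot express how firmly the law is established.
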
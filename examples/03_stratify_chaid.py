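"""Discover risk-class boundaries with a CHAID tree on the score.

Scores a 100,000-patient synthetic cohort, grows the chi-square
classification tree (depth 3, parent >= 1000, child >= 500, alpha = 0.05)
on score vs 1-year death, and prints the resulting score intervals.
"""

import mcds

bundle = mcds.simulate_cohort(mcds.SimulationParams(n_patients=100_000, seed=2),
                              include_claims=False)
survival = mcds.build_survival(bundle["cohort"], bundle["outcomes"])
truth = bundle["truth"].set_index("patient_id")
weights = mcds.default_weights()
score = truth[weights.conditions].to_numpy() @ weights.weights.to_numpy()
event = survival.set_index("patient_id").loc[truth.index, "event"].to_numpy()

tree = mcds.grow_tree(score, event, mcds.ChaidParams())
from mcds.chaid import render_tree
print(render_tree(tree))

scheme = mcds.extract_boundaries(tree)
print(f"\n{scheme.n_classes} data-driven classes: {scheme.labels()}")
print(f"shipped default classes:  {mcds.DEFAULT_SCHEME.labels()}")
# Each leaf is a score interval whose death rate differs significantly from
# its neighbours'; the boundaries depend on the cohort, so they need not
# coincide exactly with the shipped six-class default.
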
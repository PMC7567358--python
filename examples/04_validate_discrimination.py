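"""Validate the score's discrimination: AUC, DeLong CI, KM and log-rank.

Scores a synthetic cohort, measures the c-statistic with a DeLong 95%
confidence interval, compares the score against a deliberately
uninformative comparator with the paired DeLong test, and summarizes
1-year Kaplan-Meier survival by risk class with the k-sample log-rank test.
"""

import numpy as np
import pandas as pd

import mcds

bundle = mcds.simulate_cohort(mcds.SimulationParams(n_patients=50_000, seed=3),
                              include_claims=False)
survival = mcds.build_survival(bundle["cohort"], bundle["outcomes"])
truth = bundle["truth"].set_index("patient_id")
weights = mcds.default_weights()
profiles = truth[weights.conditions]
scores = mcds.score_profiles(profiles, weights)

rng = np.random.default_rng(0)
comparators = pd.DataFrame({
    "patient_id": scores["patient_id"],
    "noise_index": rng.normal(size=len(scores)),
})

report = mcds.validation_report(scores, survival, comparators)
print(f"AUC {report['auc']:.3f} (95% CI [{report['ci_low']:.3f}-{report['ci_high']:.3f}]), "
      f"{report['n_pos']} deaths / {report['n_neg']} survivors")
print(f"log-rank chi2 {report['logrank']['chi_square']:.1f} "
      f"(df {report['logrank']['df']}, p {report['logrank']['p']:.2e})")
print("1-year KM survival by class:",
      {c: round(s, 4) for c, s in report["km_final_survival"].items()})
comp = report["comparisons"]["noise_index"]
print(f"vs. noise comparator: its AUC {comp['auc']:.3f}, "
      f"paired DeLong chi2 {comp['chi_square']:.1f} (p {comp['p']:.2e})")
# Survival falls monotonically across classes and the log-rank test rejects
# equality; the noise comparator sits at AUC ~0.5 and loses the paired test.
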
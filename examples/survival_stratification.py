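"""Kaplan-Meier stratification and Cox modelling by the spectral cutoff.

Splits the cohort at the cost-weighted t_b threshold, compares
progression-free survival between arms with the log-rank test, and fits a
Cox proportional-hazards model with backward Wald elimination on the
spectral dichotomy plus gender.
"""

import numpy as np
import pandas as pd

from ftirsurv import (
    backward_wald,
    compute_patient_features,
    dichotomize,
    generate_cohort,
    km_estimate,
    logrank_test,
    paper_like_config,
    roc_curve,
    select_cutoff,
    survival_at,
)

records, spectra, _ = generate_cohort(paper_like_config(seed=1))
features = compute_patient_features(spectra)
outcome = {r.patient_id: int(bool(r.pfs_event) or bool(r.os_event)) for r in records}

roc = roc_curve([f.t_b for f in features], [outcome[f.patient_id] for f in features])
cut = select_cutoff(roc, cost_ratio=2.0, feature="t_b")
groups = dichotomize(features, cut)

by_id = {r.patient_id: r for r in records}
arms = {}
for label, name in ((1, "high-risk"), (0, "low-risk")):
    ids = [pid for pid, g in groups.items() if g == label]
    t = [by_id[i].pfs_months for i in ids]
    e = [by_id[i].pfs_event for i in ids]
    arms[name] = (t, e)
    s36 = survival_at(km_estimate(t, e), 36.0)
    print(f"{name:9s} ({cut.rule_text() if label else 'complement'}): "
          f"n = {len(ids)}, 3-year PFS = {100 * s36:.1f}%")

chi2, p = logrank_test(*arms["high-risk"], *arms["low-risk"])
print(f"log-rank: chi2 = {chi2:.2f}, p = {p:.5g}")

# multivariate: spectral dichotomy + gender, backward Wald elimination
ids = [f.patient_id for f in features]
X = pd.DataFrame(
    {
        "t_b_high": [float(groups[i]) for i in ids],
        "male_gender": [float(by_id[i].gender == "male") for i in ids],
    },
    index=ids,
)
model = backward_wald(X, [by_id[i].pfs_months for i in ids],
                      [by_id[i].pfs_event for i in ids], alpha_remove=0.10)
print("\nCox PFS model after backward Wald elimination:")
print(model.summary().round(4).to_string())
if model.elimination_trace:
    for name, pval in model.elimination_trace:
        print(f"removed {name} (Wald p = {pval:.3f})")
# hr is the hazard ratio exp(beta); its 95% CI excluding 1 marks an
# independent prognostic effect at the 5% level.
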
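"""Detection power at low sequencing depth: measurement-error model vs Cox.

Simulates a censored cohort at mean junction-read depth 5 (where isoform-
ratio point estimates are very noisy and ~half the patients have no reads
at all) and compares the true-positive rate at 5% false-positive rate of
the measurement-error model against Cox regression on PSI point estimates.
The printed TPRs show the benefit of modelling read-count uncertainty;
the gap closes as depth grows.
"""

import numpy as np

import isosurv as iv

for depth in (5, 50):
    scenario = iv.Scenario(n_subjects=600, n_exons=500, alt_fraction=0.10,
                           mean_depth=depth, seed=2)
    out = iv.benchmark_cohort(iv.simulate_scenario(scenario))
    line = f"mean depth {depth:>3}:"
    for method in ("isosurv", "cox"):
        p = out[method]
        ok = np.isfinite(p)
        roc = iv.roc_from_pvalues(p[ok], out["truth"][ok])
        line += (f"  {method}: AUC={roc.auc:.3f} "
                 f"TPR@5%FPR={roc.tpr_at[0.05]:.3f}")
    print(line)
print("\nHigher TPR at the same FPR = more survival-associated exons "
      "detected at matched specificity.")
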
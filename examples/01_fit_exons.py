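"""Fit the measurement-error survival model to a small simulated cohort.

Simulates 200 exon-skipping events for 150 patients (20% survival-
associated), fits every exon against its survival data, and prints the
top associations.  Each row shows the fitted survival coefficient beta
(log hazard-ratio per unit inclusion level: negative = higher inclusion,
better survival), the likelihood-ratio statistic, the calibrated p-value
and the BH-adjusted FDR.
"""

import numpy as np

import isosurv as iv

scenario = iv.Scenario(n_subjects=150, n_exons=200, alt_fraction=0.2,
                       mean_depth=30, seed=1)
cohort = iv.simulate_scenario(scenario)

# every simulated exon carries its own survival dataset; fit each one
rows = []
for i, (exon, records) in enumerate(zip(cohort.counts, cohort.records)):
    fitter = iv.SurvivFitter(records)
    prep = fitter.prepare(exon)
    fit, ll0 = fitter.fit(prep)
    stat, _ = iv.lrt_pvalue(fit.loglik_alt, ll0)
    rows.append((exon.exon_id, cohort.true_beta[i], fit.beta_hat, stat,
                 fitter.exon_pvalue(prep)))

fdr = iv.bh_fdr([r[4] for r in rows])
rows = [r + (q,) for r, q in zip(rows, fdr)]
rows.sort(key=lambda r: r[4])

print(f"{'exon':<10}{'true_beta':>10}{'beta_hat':>10}{'lrt':>8}"
      f"{'pvalue':>10}{'fdr':>10}")
for r in rows[:10]:
    print(f"{r[0]:<10}{r[1]:>10.2f}{r[2]:>10.2f}{r[3]:>8.2f}"
          f"{r[4]:>10.2e}{r[5]:>10.2e}")

n_hits = int(np.sum(fdr <= 0.10))
n_true = int((cohort.true_beta != 0).sum())
print(f"\n{n_hits} exons at FDR<=10%; {n_true} truly associated "
      "(top hits should recover true effects with matching signs)")
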
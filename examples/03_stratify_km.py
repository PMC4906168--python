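"""Stratify patients by an exon's inclusion level and compare survival.

Builds one exon whose inclusion level is bimodal across patients (a
high-inclusion subpopulation near PSI 0.9 and a low-inclusion one near
0.55) with a strong protective effect (beta = -2: higher inclusion, lower
hazard).  Patients are split into two groups by exact 1-D two-means
clustering of the PSI point estimates; the Kaplan-Meier survival
probabilities per group and the log-rank p-value quantify the survival
separation an analyst would see.
"""

import numpy as np

import isosurv as iv

rng = np.random.default_rng(7)
n = 300
psi_true = np.where(rng.uniform(size=n) < 0.5,
                    rng.normal(0.90, 0.04, n),
                    rng.normal(0.55, 0.06, n)).clip(0, 1)
depth = rng.poisson(60, size=n)
ic, sc = iv.simulate_counts(psi_true, depth, 2, 1, rng)
exon = iv.ExonCounts("STAT-like", tuple(f"P{i:03d}" for i in range(n)),
                     ic, sc, 2, 1)
records = iv.simulate_survival(psi_true, -2.0, iv.ConstantBaseline(1.0), rng,
                               patient_ids=exon.patients)
records = iv.apply_censoring(records, 0.3, rng)

psi = iv.psi_point_estimates(exon)
ok = np.isfinite(psi)
groups = iv.two_means_stratify(psi[ok])
records_ok = [r for r, keep in zip(records, ok) if keep]

horizon = float(np.median([r.time for r in records_ok]))
for g, name in [(1, "high inclusion"), (0, "low inclusion")]:
    sub = [r for r, lab in zip(records_ok, groups) if lab == g]
    km = iv.kaplan_meier(sub)
    print(f"{name:>15}: n={len(sub):>3}  mean PSI="
          f"{psi[ok][groups == g].mean():.2f}  "
          f"S(t={horizon:.2f})={float(km.at(horizon)):.2f}")

p = iv.logrank_test(groups, records_ok)
print(f"\nlog-rank p = {p:.2e}  (higher-inclusion patients survive longer "
      "under the protective effect)")
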
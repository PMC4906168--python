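# isosurv

Survival analysis of mRNA isoform variation from RNA-seq junction counts.

Large clinical RNA-seq cohorts make it possible to ask whether alternative
splicing — most commonly the inclusion level ψ (PSI, per cent spliced in)
of an exon-skipping event — is associated with patient survival.  The
obstacle is that ψ is never observed: it is estimated from small junction
read counts, and the estimation error varies enormously across patients
and exons.  Treating noisy point estimates as known covariates (the
conventional Cox-regression approach) throws away patients with no reads
and dilutes the signal of patients with few.

`isosurv` implements a **measurement-error proportional-hazards model**
for this problem.  For each exon, patient *k*'s hazard is
λ₀(t)·exp(β·ψ<sub>k</sub>), and the inclusion read count IC<sub>k</sub> is
binomial with success probability f(ψ<sub>k</sub>), the effective-length-
normalized inclusion-read proportion.  The per-exon likelihood integrates
the survival model against the binomial read model and an empirical prior
on ψ, so every patient contributes exactly as much covariate information
as their coverage supports.  Each exon is tested for β = 0 with a
calibrated score test (a likelihood-ratio test is also reported), with
Benjamini–Hochberg FDR across exons.  The package ships with:

* `isosurv.model` — the measurement-error likelihood, fitting and testing;
* `isosurv.cox` — the conventional Cox-on-point-estimates comparator;
* `isosurv.simulate` — a generative engine for realistic synthetic cohorts
  (overdispersed Gamma–Poisson depths, Beta/Gamma inclusion hierarchy,
  proportional-hazards survival, censoring);
* `isosurv.evaluate` — ROC/TPR benchmarking, Harrell's C-index,
  Kaplan–Meier, log-rank, exact 1-D two-means stratification;
* `isosurv.prognosis` — survival-predictor construction (univariate
  screening, L1-penalized Cox) with Monte Carlo cross-validation;
* a thin `isosurv` command-line interface over the same functions.

See `docs/methods.md` for the model, priors, test construction and
numerical details.

## Worked example

Simulate a 150-patient cohort with 200 exon-skipping events (20%
survival-associated) and fit every exon:

```python
import isosurv as iv

cohort = iv.simulate_scenario(
    iv.Scenario(n_subjects=150, n_exons=200, alt_fraction=0.2,
                mean_depth=30, seed=1)
)
fitter = iv.SurvivFitter(cohort.records[0])
fit, ll0 = fitter.fit(cohort.counts[0])
print(fit.beta_hat, fitter.exon_pvalue(cohort.counts[0]))
```

Running `python examples/01_fit_exons.py` prints the top associations:

```
exon       true_beta  beta_hat     lrt    pvalue       fdr
exon00044      -3.20     -6.66   17.80  1.76e-05  3.51e-03
exon00088       3.76     10.00   11.74  1.33e-03  9.18e-02
exon00112       1.73      6.58    8.51  1.59e-03  9.18e-02
exon00183       1.80      2.72    9.51  1.84e-03  9.18e-02
...
```

`beta_hat` is the fitted log hazard ratio per unit inclusion level
(negative = higher exon inclusion, better survival), `lrt` the
likelihood-ratio statistic, `pvalue` the calibrated per-exon test and
`fdr` its Benjamini–Hochberg adjustment; the strongest simulated effects
surface at the top with matching signs.  The other examples benchmark
detection power against Cox regression at low sequencing depth
(`02_power_vs_cox.py`), stratify patients by an exon's inclusion level
into Kaplan–Meier groups (`03_stratify_km.py`), and run the
cross-validated survival-prediction comparison of clinical, expression and
splicing predictors (`04_prediction_cv.py`).

The same workflow is available from the shell on TSV tables:

```sh
isosurv simulate --out-prefix sim/ --n-exons 500 --n-subjects 150 --seed 1
isosurv fit --counts sim/counts.tsv --survival sim/survival.tsv --out results.tsv
isosurv evaluate --results results.tsv --truth sim/truth.tsv --out metrics.json
```

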
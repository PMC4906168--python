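"""Scoring and stratification: ROC/TPR metrics, Harrell C-index,
Kaplan-Meier curves, exact 1-D two-means clustering and the log-rank test,
plus helpers that benchmark the measurement-error model against the Cox
comparator on simulated cohorts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .cox import cox_fit
from .io import SurvivalRecord, psi_point_estimates
from .model import SurvivConfig, SurvivFitter
from .simulate import SimulatedCohort

__all__ = [
    "RocSummary",
    "KmCurve",
    "roc_from_pvalues",
    "concordance_index",
    "kaplan_meier",
    "two_means_stratify",
    "logrank_test",
    "benchmark_cohort",
]


@dataclass(frozen=True)
class RocSummary:
    auc: float
    tpr_at: dict[float, float]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve: steps only at event times, starts at 1."""

    times: np.ndarray
    surv_prob: np.ndarray

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([1.0], self.surv_prob))
        return padded[idx]


def roc_from_pvalues(pvalues, truth_labels, fpr_levels=(0.05,)) -> RocSummary:
    """Empirical ROC of a p-value detector against simulation truth labels.

    Score is -p (smaller p ranks higher).  AUC by trapezoid over the full
    curve; TPR at a requested FPR uses the largest threshold whose empirical
    FPR does not exceed the level (step convention, no interpolation).
    """
    p = np.asarray(pvalues, dtype=float)
    y = np.asarray(truth_labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("pvalues and truth_labels length mismatch")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both truth classes must be present")
    y_sorted = y[np.argsort(p, kind="stable")]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # collapse tied p-values: keep the last index of each tied block
    p_sorted = np.sort(p, kind="stable")
    distinct = np.append(np.diff(p_sorted) != 0, True)
    tpr = np.concatenate(([0.0], tps[distinct] / n_pos))
    fpr = np.concatenate(([0.0], fps[distinct] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    tpr_at = {}
    for level in fpr_levels:
        if not 0.0 < level < 1.0:
            raise ValueError("FPR levels must lie in (0, 1)")
        tpr_at[level] = float(tpr[fpr <= level].max())
    return RocSummary(auc=auc, tpr_at=tpr_at)


def concordance_index(risk_scores, records: Sequence[SurvivalRecord]) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when the earlier observed time belongs to a patient
    with an observed event and the times differ (pairs tied in time with
    both events are ignored).  Concordant: the earlier-failing patient has
    the higher risk score; score ties count 0.5.
    """
    risk = np.asarray(risk_scores, dtype=float)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if risk.shape != times.shape:
        raise ValueError("risk_scores and records length mismatch")
    # usable pairs (i, j): t_i < t_j and event_i = 1
    dt = times[:, None] < times[None, :]
    usable = dt & (events[:, None] == 1)
    # censored j at the same time as an event i is usable (j outlived i)
    tie_t = (times[:, None] == times[None, :]) & (events[:, None] == 1) & (
        events[None, :] == 0
    )
    usable |= tie_t
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no comparable pairs")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = float((usable & higher).sum()) + 0.5 * float((usable & tied).sum())
    return concordant / n_usable


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Product-limit estimator of the survival function with right censoring."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return KmCurve(np.array([]), np.array([]))
    n_at_risk = (times[None, :] >= ev_times[:, None]).sum(axis=1)
    deaths = ((times[None, :] == ev_times[:, None]) & (events[None, :] == 1)).sum(axis=1)
    surv = np.cumprod(1.0 - deaths / n_at_risk)
    return KmCurve(ev_times, surv)


def two_means_stratify(values) -> np.ndarray:
    """Exact 1-D two-means clustering by enumerating sorted splits.

    Returns binary labels; 1 marks the higher-mean cluster.  Deterministic:
    among splits with equal within-group SSE the smallest high group wins.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = x.size
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs * xs)
    k = np.arange(1, n)  # low group size
    sse_low = csum2[k - 1] - csum[k - 1] ** 2 / k
    sum_hi = csum[-1] - csum[k - 1]
    sse_hi = (csum2[-1] - csum2[k - 1]) - sum_hi**2 / (n - k)
    best = int(np.argmin(sse_low + sse_hi)) + 1
    labels = np.zeros(n, dtype=int)
    labels[order[best:]] = 1
    return labels


def logrank_test(groups, records: Sequence[SurvivalRecord]) -> float:
    """Two-group log-rank test; returns the chi-square(1) p-value."""
    g = np.asarray(groups, dtype=int)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if g.shape != times.shape:
        raise ValueError("groups and records length mismatch")
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two non-empty groups required")
    ev_times = np.unique(times[events == 1])
    obs1 = exp1 = var = 0.0
    for t in ev_times:
        at_risk = times >= t
        n_tot = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d_tot = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (g == 1)).sum()
        obs1 += d1
        exp1 += d_tot * n1 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 1.0
    stat = (obs1 - exp1) ** 2 / var
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# cohort benchmarking (measurement-error model vs Cox comparator)
# ---------------------------------------------------------------------------


def benchmark_cohort(
    cohort: SimulatedCohort,
    config: SurvivConfig | None = None,
    methods: Sequence[str] = ("isosurv", "cox"),
    cox_on_true_psi: bool = False,
) -> dict[str, np.ndarray]:
    """Per-exon p-values from both detectors on a simulated cohort.

    Every exon is fitted against its own survival dataset (the generator
    simulates survival from that exon's inclusion levels); the baseline
    hazard for the measurement-error model is the Nelson-Aalen plug-in from
    that dataset's patients.  Returns arrays keyed by method name plus the
    truth labels; exons failing a method's preconditions get p = NaN.
    """
    config = config or SurvivConfig()
    out: dict[str, np.ndarray] = {"truth": cohort.truth_labels.copy()}
    n = len(cohort.counts)
    if "isosurv" in methods:
        pvals = np.full(n, np.nan)
        for i, (exon, recs) in enumerate(zip(cohort.counts, cohort.records)):
            fitter = SurvivFitter(recs, config=config)
            prep = fitter.prepare(exon)
            if prep["n_covered"] < config.min_patients:
                continue
            pvals[i] = fitter.exon_pvalue(prep)
        out["isosurv"] = pvals
    if "cox" in methods:
        pvals = np.full(n, np.nan)
        for i, (exon, recs) in enumerate(zip(cohort.counts, cohort.records)):
            psi = (
                cohort.true_psi[i]
                if cox_on_true_psi
                else psi_point_estimates(exon)
            )
            try:
                pvals[i] = cox_fit(psi, recs, exon_id=exon.exon_id).p_value
            except ValueError:
                continue
        out["cox"] = pvals
    return out
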
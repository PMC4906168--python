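"""Conventional Cox regression on PSI point estimates (the comparator).

Single-covariate Cox proportional-hazards fit by Newton-Raphson on the
Breslow partial likelihood, with a likelihood-ratio test against beta = 0.
Patients with missing PSI (zero junction reads) are dropped per exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .io import ExonCounts, SurvivalRecord, psi_point_estimates

logger = logging.getLogger("isosurv")

__all__ = ["CoxResult", "cox_fit", "cox_fit_all", "breslow_partial_loglik"]

_BETA_CAP = 20.0


@dataclass(frozen=True)
class CoxResult:
    exon_id: str
    beta_hat: float
    se: float
    lrt_stat: float
    p_value: float
    flag: str = "ok"  # ok | degenerate | separation | not_converged


def _risk_set_layout(times: np.ndarray):
    """Ascending sort order plus, per position, the start of its time-tie group."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    # first index of each tie group (Breslow: tied deaths share the risk set)
    group_start = np.searchsorted(t_sorted, t_sorted, side="left")
    return order, group_start


def _partial_terms(x, delta, order, group_start, beta):
    """Breslow partial log-likelihood, score and information at beta."""
    xs = x[order]
    ds = delta[order]
    exb = np.exp(beta * xs)
    s0 = np.cumsum(exb[::-1])[::-1]
    s1 = np.cumsum((xs * exb)[::-1])[::-1]
    s2 = np.cumsum((xs * xs * exb)[::-1])[::-1]
    s0g, s1g, s2g = s0[group_start], s1[group_start], s2[group_start]
    ev = ds == 1
    r1 = s1g[ev] / s0g[ev]
    ll = float(np.sum(beta * xs[ev] - np.log(s0g[ev])))
    score = float(np.sum(xs[ev] - r1))
    info = float(np.sum(s2g[ev] / s0g[ev] - r1 * r1))
    return ll, score, info


def breslow_partial_loglik(
    linear_predictor, times, events
) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor.

    Used both by the single-covariate fit and as the held-out score when
    tuning the L1 penalty of the multivariate prediction model.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    order, group_start = _risk_set_layout(t)
    lps = lp[order]
    ds = d[order]
    elp = np.exp(lps - lps.max())
    s0 = np.cumsum(elp[::-1])[::-1][group_start]
    ev = ds == 1
    return float(np.sum(lps[ev] - lps.max() - np.log(s0[ev])))


def cox_fit(
    psi_point,
    records: Sequence[SurvivalRecord],
    exon_id: str = "",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Fit a single-covariate Cox model with Breslow ties and LRT vs beta=0.

    Patients with non-finite covariate values are dropped.  A constant
    covariate yields a degenerate result (beta=0, p=1); a monotone partial
    likelihood (perfect separation) yields a flagged result with |beta|
    capped.
    """
    x = np.asarray(psi_point, dtype=float)
    times = np.array([r.time for r in records], dtype=float)
    delta = np.array([r.event for r in records], dtype=int)
    if x.shape != times.shape:
        raise ValueError("covariate and records length mismatch")
    keep = np.isfinite(x)
    x, times, delta = x[keep], times[keep], delta[keep]
    if x.size == 0:
        raise ValueError(f"exon {exon_id!r}: no patients with observed covariate")
    if delta.sum() < 2:
        raise ValueError(f"exon {exon_id!r}: fewer than 2 events")
    if np.ptp(x) == 0:
        return CoxResult(exon_id, 0.0, np.inf, 0.0, 1.0, flag="degenerate")

    order, group_start = _risk_set_layout(times)
    ll0, _, _ = _partial_terms(x, delta, order, group_start, 0.0)
    beta, ll = 0.0, ll0
    flag = "not_converged"
    for _ in range(max_iter):
        _, score, info = _partial_terms(x, delta, order, group_start, beta)
        if info <= 0:
            break
        step = score / info
        if abs(step) < tol:
            flag = "ok"
            break
        # step-halving to guarantee ascent; cap to keep exp() finite
        new_beta = float(np.clip(beta + step, -2 * _BETA_CAP, 2 * _BETA_CAP))
        for _ in range(30):
            ll_new, _, _ = _partial_terms(x, delta, order, group_start, new_beta)
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta, ll = new_beta, ll_new
        if abs(beta) > _BETA_CAP:
            beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
            flag = "separation"
            break
    ll, score, info = _partial_terms(x, delta, order, group_start, beta)
    if flag == "not_converged" and abs(score) < 1e-4:
        flag = "ok"
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    stat = max(0.0, 2.0 * (ll - ll0))
    p = float(chi2.sf(stat, df=1))
    return CoxResult(exon_id, float(beta), float(se), stat, max(p, 5e-324), flag=flag)


def cox_fit_all(
    counts: Sequence[ExonCounts], records: Sequence[SurvivalRecord]
) -> list[CoxResult]:
    """Cox comparator over a cohort: one fit per exon on PSI point estimates."""
    order = {r.patient_id: i for i, r in enumerate(records)}
    results: list[CoxResult] = []
    n_dropped = 0
    for exon in counts:
        psi = psi_point_estimates(exon)
        if tuple(exon.patients) != tuple(order):
            idx = np.array([order[p] for p in exon.patients], dtype=int)
            full = np.full(len(records), np.nan)
            full[idx] = psi
            psi = full
        try:
            results.append(cox_fit(psi, records, exon_id=exon.exon_id))
        except ValueError:
            n_dropped += 1
    if n_dropped:
        logger.info("cox_fit_all: %d exons dropped (missing PSI or <2 events)", n_dropped)
    return results
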
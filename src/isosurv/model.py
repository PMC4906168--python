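"""Measurement-error proportional-hazards model for exon-inclusion levels.

For each exon-skipping event the hazard of patient k is modelled as

    lambda_k(t) = lambda0(t) * exp(beta * psi_k),

where psi_k is the patient's (latent) exon-inclusion level.  psi_k is not
observed directly: the inclusion-junction read count IC_k is binomial with
total n_k = IC_k + SC_k and success probability p_k = f(psi_k), the
length-normalized inclusion-read proportion.  The per-patient likelihood
integrates the proportional-hazards survival density against the binomial
read model and a prior on psi:

    L_k(beta) = int_0^1  lambda0(t_k)^{d_k} e^{d_k beta psi}
                         exp(-Lambda0(t_k) e^{beta psi})
                         Binom(IC_k | n_k, f(psi)) pi(psi) dpsi,

with d_k the event indicator.  Lambda0 is the Nelson-Aalen plug-in estimated
once from all patients and held fixed while beta is maximized.  The null
hypothesis beta = 0 is tested per exon by a likelihood-ratio test against a
chi-square with one degree of freedom, with Benjamini-Hochberg FDR control
across exons.

The integral is evaluated by Gauss-Legendre quadrature on [0, 1] with all
binomial terms kept in log space (log-sum-exp).

Because the Nelson-Aalen plug-in is computed from the marginal survival
data, it already absorbs the cohort-average hazard level; fitting beta
against it with no compensating degree of freedom deflates the score in the
constant-covariate direction and makes the LRT conservative.  The fit
therefore profiles a per-exon log-hazard intercept alpha (a baseline scale,
hazard = lambda0(t) * exp(alpha + beta*psi)) under both hypotheses.  With
the Nelson-Aalen plug-in the null profile is alpha-hat = 0 exactly, so the
null log-likelihood is unchanged and the LRT keeps one degree of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betaln, digamma, gammaln
from scipy.stats import beta as beta_dist, chi2
from statsmodels.stats.multitest import multipletests

from .baseline import BaselineHazard, ConstantBaseline, nelson_aalen
from .io import ExonCounts, SurvivalRecord, SurvivResult

logger = logging.getLogger("isosurv")

__all__ = [
    "SurvivConfig",
    "SurvivFitter",
    "FitResult",
    "length_normalization",
    "survival_loglik_terms",
    "exon_loglik",
    "fit_beta",
    "lrt_pvalue",
    "bh_fdr",
    "fit_all_exons",
]

_TINY_P = 5e-324  # smallest subnormal; keeps p-values inside (0, 1]


@dataclass(frozen=True)
class SurvivConfig:
    """Numerical configuration of the per-exon likelihood maximization.

    quadrature_points: Gauss-Legendre nodes on [0, 1] (>= 8).
    psi_prior: prior on the latent inclusion level.  'empirical-beta'
        (default) is a noise-deconvolved method-of-moments Beta fitted per
        exon to the inclusion-read proportions, adapting the prior to each
        exon's inclusion distribution; 'uniform' is the flat reference;
        'mixture' blends the two with mass ``empirical_weight`` on the
        empirical component.
    empirical_weight: mass of the empirical Beta component under 'mixture'.
    beta_bounds: finite search interval for beta, must contain 0.
    tol: gradient tolerance of the (alpha, beta) maximizer.
    min_patients: coverage filter -- exons with fewer patients having
        n_k >= 1 are dropped from cohort-level fits.
    test: 'score' (default) derives the per-exon p-value from the null
        score statistic studentized by its exact permutation variance,
        which stays chi-square(1)-calibrated under informative censoring
        and tight priors; 'lrt' uses the plain chi-square tail of the
        likelihood-ratio statistic.
    """

    quadrature_points: int = 64
    psi_prior: str = "empirical-beta"
    empirical_weight: float = 1.0
    beta_bounds: tuple[float, float] = (-10.0, 10.0)
    tol: float = 1e-6
    max_iter: int = 200
    min_patients: int = 5
    test: str = "score"

    def __post_init__(self) -> None:
        if self.quadrature_points < 8:
            raise ValueError("quadrature_points must be >= 8")
        lo, hi = self.beta_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= 0.0 <= hi):
            raise ValueError("beta_bounds must be finite and contain 0")
        if self.psi_prior not in ("uniform", "empirical-beta", "mixture"):
            raise ValueError(f"unknown psi_prior {self.psi_prior!r}")
        if not 0.0 <= self.empirical_weight <= 1.0:
            raise ValueError("empirical_weight must lie in [0, 1]")
        if self.test not in ("score", "lrt"):
            raise ValueError(f"unknown test {self.test!r}")


class FitResult(NamedTuple):
    beta_hat: float
    loglik_alt: float
    converged: bool
    at_bound: bool


def length_normalization(psi, l_inc: int = 2, l_skip: int = 1):
    """Map an inclusion level to the expected inclusion-read proportion.

    p = f(psi) = l_inc*psi / (l_inc*psi + l_skip*(1-psi)); inverse of the
    PSI point estimator.  Fixed points at 0 and 1; identity when lengths
    are equal.
    """
    psi_arr = np.asarray(psi, dtype=float)
    if np.any(psi_arr < 0) or np.any(psi_arr > 1):
        raise ValueError("psi must lie in [0, 1]")
    if l_inc < 1 or l_skip < 1:
        raise ValueError("effective lengths must be >= 1")
    num = l_inc * psi_arr
    out = num / (num + l_skip * (1.0 - psi_arr))
    return out if out.ndim else float(out)


def survival_loglik_terms(
    record: SurvivalRecord, psi: float, beta: float, baseline
) -> float:
    """PH log-density (event) or log-survival (censored) contribution.

    event * (log lambda0(t) + beta*psi) - Lambda0(t) * exp(beta*psi), with
    the Nelson-Aalen increment at the event's own time as the hazard mass.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    lam = float(baseline.cumulative(record.time))
    term = -lam * math.exp(beta * psi)
    if record.event:
        mass = float(baseline.hazard_mass(record.time))
        term += math.log(mass) + beta * psi
    return term


@lru_cache(maxsize=None)
def _gauss_legendre_unit(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    nodes, weights = (x + 1.0) / 2.0, w / 2.0
    nodes.setflags(write=False)  # cached arrays are shared across fitters
    weights.setflags(write=False)
    return nodes, weights


def _moment_p_prior(ic: np.ndarray, sc: np.ndarray) -> tuple[float, float] | None:
    """Method-of-moments Beta prior on the inclusion-read proportion p.

    The raw per-patient proportions carry binomial sampling noise on top of
    the biological spread; the moment fit subtracts the expected binomial
    variance (deconvolution) so the prior matches the latent spread rather
    than the noisy point estimates.  Returns None when too few informative
    patients exist (caller falls back to the uniform prior).
    """
    n = ic + sc
    keep = n > 0
    if keep.sum() < 5:
        return None
    phat = ic[keep] / n[keep]
    m = float(np.mean(phat))
    m = min(max(m, 1e-3), 1.0 - 1e-3)
    v_obs = float(np.var(phat))
    v_binom = m * (1.0 - m) * float(np.mean(1.0 / n[keep]))
    v_lat = max(v_obs - v_binom, 1e-4)
    s = m * (1.0 - m) / v_lat - 1.0
    s = min(max(s, 0.01), 1e4)
    return m * s, (1.0 - m) * s


_THETA_LO, _THETA_HI = -6.0, 8.0  # bounds on (log a, log b)


def _empirical_p_prior(
    ic: np.ndarray,
    sc: np.ndarray,
    log_binom_unif: np.ndarray | None = None,
    p_unif: np.ndarray | None = None,
    log_w: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Empirical Beta prior on the inclusion-read proportion p.

    Fitted per exon by maximizing the marginal (beta-binomial-style)
    likelihood of the counts over (a, b), evaluated by quadrature on the
    uniform grid; the moment/deconvolution estimate initializes the search
    and serves as fallback.  Marginal maximum likelihood deconvolves the
    binomial noise far more efficiently than moments when most patients
    have only a handful of reads.
    """
    mom = _moment_p_prior(ic, sc)
    if mom is None:
        return None
    if log_binom_unif is None or p_unif is None or log_w is None:
        return mom
    n = ic + sc
    keep = n > 0
    lb = log_binom_unif[keep]
    lp = np.log(p_unif)
    l1p = np.log1p(-p_unif)
    n_pat = int(keep.sum())

    def neg_ll_grad(theta: np.ndarray):
        a, b = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        lpdf = (a - 1) * lp + (b - 1) * l1p - betaln(a, b)
        mat = lb + (log_w + lpdf)[None, :]
        m = mat.max(axis=1)
        w = np.exp(mat - m[:, None])
        s = w.sum(axis=1)
        ll = float(np.sum(m + np.log(s)))
        post = w / s[:, None]
        e_lp = float(np.sum(post @ lp))
        e_l1p = float(np.sum(post @ l1p))
        dg_ab = digamma(a + b)
        d_a = (e_lp - n_pat * (digamma(a) - dg_ab)) * a
        d_b = (e_l1p - n_pat * (digamma(b) - dg_ab)) * b
        return -ll, -np.array([d_a, d_b])

    res = minimize(
        neg_ll_grad,
        x0=np.log(np.clip(mom, 1e-3, 1e3)),
        jac=True,
        method="L-BFGS-B",
        bounds=[(_THETA_LO, _THETA_HI)] * 2,
        options={"maxiter": 30, "ftol": 1e-6},
    )
    if not np.all(np.isfinite(res.x)):
        return mom
    a, b = np.exp(np.clip(res.x, _THETA_LO, _THETA_HI))
    return float(a), float(b)


class SurvivFitter:
    """Shared survival-side quantities for fitting many exons on one cohort.

    Precomputes Lambda0(t_k) and the event-time hazard masses once; per exon
    only the binomial log-pmf matrix over the quadrature grid is built.
    """

    def __init__(
        self,
        records: Sequence[SurvivalRecord],
        baseline: BaselineHazard | ConstantBaseline | None = None,
        config: SurvivConfig | None = None,
    ) -> None:
        self.records = list(records)
        self.config = config or SurvivConfig()
        self.baseline = baseline if baseline is not None else nelson_aalen(records)
        times = np.array([r.time for r in self.records], dtype=float)
        self.times = times
        self.delta = np.array([r.event for r in self.records], dtype=float)
        self.cumhaz = np.asarray(self.baseline.cumulative(times), dtype=float)
        mass = np.asarray(self.baseline.hazard_mass(times), dtype=float)
        # the event log-mass term is constant in beta and psi
        self.log_mass_sum = float(np.sum(self.delta * np.log(mass)))
        # risk-set layout for the Breslow baseline profile (Breslow ties)
        self._sort = np.argsort(times, kind="stable")
        t_sorted = times[self._sort]
        self._group_start = np.searchsorted(t_sorted, t_sorted, side="left")
        self._group_end = np.searchsorted(t_sorted, t_sorted, side="right") - 1
        self._event_sorted = self.delta[self._sort] == 1
        self.nodes, self._weights = _gauss_legendre_unit(self.config.quadrature_points)
        # coarser grid for the 2-parameter empirical-prior fit
        self._prior_nodes, self._prior_weights = _gauss_legendre_unit(
            min(32, self.config.quadrature_points)
        )
        self._order = {r.patient_id: i for i, r in enumerate(self.records)}

    # -- per-exon preparation ------------------------------------------------

    def prepare(self, exon: ExonCounts) -> dict:
        """Align an exon to the cohort and build its binomial log-pmf matrix."""
        if tuple(exon.patients) == tuple(self._order):
            ic, sc = exon.ic, exon.sc
        else:
            try:
                idx = np.array([self._order[p] for p in exon.patients], dtype=int)
            except KeyError as exc:
                raise ValueError(
                    f"exon {exon.exon_id!r}: patient {exc.args[0]!r} absent "
                    "from survival cohort"
                ) from None
            if len(idx) != len(self.records):
                raise ValueError(
                    f"exon {exon.exon_id!r}: patient set does not cover the cohort"
                )
            ic = np.zeros(len(self.records), dtype=np.int64)
            sc = np.zeros(len(self.records), dtype=np.int64)
            ic[idx], sc[idx] = exon.ic, exon.sc
        n = ic + sc
        # Integration grid: each prior component is integrated on Gauss-
        # Legendre nodes pushed through its own quantile function
        # (substitution u = F(p)), so the grid follows the prior mass however
        # tight the fitted component is, and the quadrature weights stay the
        # plain GL weights scaled by the component mass.
        w_emp = {
            "uniform": 0.0,
            "empirical-beta": 1.0,
            "mixture": self.config.empirical_weight,
        }[self.config.psi_prior]
        log_choose = (gammaln(n + 1) - gammaln(ic + 1) - gammaln(sc + 1))[:, None]

        def binom_at(p_grid: np.ndarray) -> np.ndarray:
            return (
                log_choose
                + ic[:, None] * np.log(p_grid)[None, :]
                + sc[:, None] * np.log1p(-p_grid)[None, :]
            )

        params = None
        if w_emp > 0:
            p_coarse = np.asarray(
                length_normalization(self._prior_nodes, exon.l_inc, exon.l_skip)
            )
            params = _empirical_p_prior(ic, sc, binom_at(p_coarse), p_coarse,
                                        np.log(self._prior_weights))
        if params is None or w_emp < 1.0:
            p_unif = np.asarray(
                length_normalization(self.nodes, exon.l_inc, exon.l_skip)
            )
            log_binom_unif = binom_at(p_unif)
        if params is None:
            nodes, log_binom = self.nodes, log_binom_unif
            log_w = np.log(self._weights)
        else:
            p_beta = np.clip(beta_dist.ppf(self.nodes, *params), 1e-12, 1.0 - 1e-12)
            # invert the length normalization: psi such that f(psi) = p
            psi_beta = p_beta * exon.l_skip / (
                p_beta * exon.l_skip + (1.0 - p_beta) * exon.l_inc
            )
            if w_emp >= 1.0:
                nodes, log_binom = psi_beta, binom_at(p_beta)
                log_w = np.log(self._weights)
            else:
                nodes = np.concatenate([self.nodes, psi_beta])
                log_binom = np.concatenate(
                    [log_binom_unif, binom_at(p_beta)], axis=1
                )
                log_w = np.log(
                    np.concatenate(
                        [(1.0 - w_emp) * self._weights, w_emp * self._weights]
                    )
                )
        return {"exon_id": exon.exon_id, "log_binom": log_binom,
                "log_w": log_w, "nodes": nodes,
                "n_covered": int((n > 0).sum())}

    # -- likelihood ----------------------------------------------------------

    def loglik(self, prep: dict, beta: float, alpha: float = 0.0) -> float:
        """Marginal log-likelihood of the exon at fixed (beta, alpha)."""
        ll, _ = self._loglik_grad(prep, beta, alpha, want_grad=False)
        return ll

    def _loglik_grad(
        self, prep: dict, beta: float, alpha: float, want_grad: bool = True
    ) -> tuple[float, np.ndarray | None]:
        """Log-likelihood and its gradient in (alpha, beta).

        One matrix pass: the posterior weights over the quadrature grid give
        the expectations needed for both partial derivatives.
        """
        nodes = prep["nodes"]
        bpsi = beta * nodes
        ebpsi = np.exp(bpsi + alpha)
        haz = self.cumhaz[:, None] * ebpsi[None, :]
        a = (
            prep["log_binom"]
            + prep["log_w"][None, :]
            + self.delta[:, None] * (bpsi[None, :] + alpha)
            - haz
        )
        m = a.max(axis=1)
        w = np.exp(a - m[:, None])
        s = w.sum(axis=1)
        ll = float(np.sum(m + np.log(s))) + self.log_mass_sum
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log-likelihood for exon {prep['exon_id']!r} at "
                f"beta={beta}, alpha={alpha}"
            )
        if not want_grad:
            return ll, None
        post = w / s[:, None]
        e_haz = (post * haz).sum(axis=1)
        e_haz_psi = (post * haz * nodes[None, :]).sum(axis=1)
        e_psi = (post * nodes[None, :]).sum(axis=1)
        d_alpha = float(np.sum(self.delta - e_haz))
        d_beta = float(np.sum(self.delta * e_psi - e_haz_psi))
        return ll, np.array([d_alpha, d_beta])

    # -- Breslow baseline profile -------------------------------------------

    def _breslow_baseline(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Breslow baseline given per-patient hazard weights w = E[e^{b psi}].

        Returns (Lambda at each patient's time, hazard mass at each
        patient's own time), with all tied deaths sharing the risk set.
        """
        srt = self._sort
        ws = w[srt]
        s0 = np.cumsum(ws[::-1])[::-1][self._group_start]
        incr = np.where(self._event_sorted, 1.0 / s0, 0.0)
        cum = np.cumsum(incr)[self._group_end]
        lam = np.empty_like(cum)
        lam[srt] = cum
        deaths_at = np.zeros(len(srt))
        np.add.at(deaths_at, self._group_start, self._event_sorted.astype(float))
        mass_sorted = deaths_at[self._group_start] / s0
        mass = np.empty_like(mass_sorted)
        mass[srt] = mass_sorted
        return lam, np.maximum(mass, 1e-300)

    def profile_loglik(self, prep: dict, beta: float, n_em: int = 30) -> float:
        """Marginal log-likelihood at beta with the baseline profiled out.

        Alternates posterior expectations of e^{beta psi} with Breslow
        baseline updates (EM) until the log-likelihood stabilizes; at
        beta = 0 the profile is the Nelson-Aalen plug-in itself.  Profiling
        the whole baseline (not only its scale) is what keeps beta-hat
        consistent when a strong covariate effect distorts the shape of the
        cohort-marginal hazard; an unconverged profile attenuates it.
        """
        nodes = prep["nodes"]
        ebpsi = np.exp(beta * nodes)
        base = (
            prep["log_binom"]
            + prep["log_w"][None, :]
            + self.delta[:, None] * (beta * nodes)[None, :]
        )
        lam = self.cumhaz
        ll = -np.inf
        mass = None
        for _ in range(max(1, n_em)):
            a = base - lam[:, None] * ebpsi[None, :]
            m = a.max(axis=1)
            w = np.exp(a - m[:, None])
            s = w.sum(axis=1)
            weights = (w / s[:, None]) @ ebpsi
            lam, mass = self._breslow_baseline(weights)
            a = base - lam[:, None] * ebpsi[None, :]
            m = a.max(axis=1)
            s = np.exp(a - m[:, None]).sum(axis=1)
            ll_new = float(np.sum(m + np.log(s))
                           + np.sum(self.delta * np.log(mass)))
            if abs(ll_new - ll) < 1e-9 * (1.0 + abs(ll_new)):
                ll = ll_new
                break
            ll = ll_new
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite profile log-likelihood for exon "
                f"{prep['exon_id']!r} at beta={beta}"
            )
        return ll

    def fit_null(self, prep: dict) -> float:
        """Null (beta = 0) log-likelihood; the baseline profile at beta = 0
        is the Nelson-Aalen estimator of the records themselves."""
        return self.profile_loglik(prep, 0.0, n_em=1)

    def fit(self, exon: ExonCounts | dict) -> tuple[FitResult, float]:
        """Maximize the baseline-profiled likelihood over beta.

        Returns (FitResult, loglik_null).  With an externally supplied
        baseline the profile still re-estimates the Breslow baseline from
        the records; the supplied baseline only seeds the EM.
        """
        prep = exon if isinstance(exon, dict) else self.prepare(exon)
        ll0 = self.fit_null(prep)
        lo, hi = self.config.beta_bounds
        if lo == hi:
            return FitResult(lo, self.profile_loglik(prep, lo), True, False), ll0
        res = minimize_scalar(
            lambda b: -self.profile_loglik(prep, b),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": self.config.tol, "maxiter": self.config.max_iter},
        )
        beta_hat, ll_alt = float(res.x), float(-res.fun)
        converged = bool(res.success)
        if ll_alt < ll0:  # optimizer missed; the null is admissible
            beta_hat, ll_alt = 0.0, ll0
        span = hi - lo
        at_bound = min(beta_hat - lo, hi - beta_hat) < 1e-3 * span
        return FitResult(beta_hat, ll_alt, converged, at_bound), ll0

    def score_test(self, exon: ExonCounts | dict) -> tuple[float, float]:
        """(statistic, p-value) of the calibrated null score test."""
        prep = exon if isinstance(exon, dict) else self.prepare(exon)
        return _score_test(self, prep)

    def exon_pvalue(self, exon: ExonCounts | dict) -> float:
        """Per-exon p-value under the configured test ('score' or 'lrt')."""
        prep = exon if isinstance(exon, dict) else self.prepare(exon)
        if self.config.test == "score":
            return _score_test(self, prep)[1]
        fit, ll0 = self.fit(prep)
        return lrt_pvalue(fit.loglik_alt, ll0, tol=self.config.tol)[1]


def _score_test(fitter: "SurvivFitter", prep: dict) -> tuple[float, float]:
    """Null score statistic with exact permutation-variance studentization.

    At beta = 0 the score for beta (with the baseline-scale nuisance alpha
    profiled out) is U = sum_k (psibar_k - c)(delta_k - Lambda_k), where
    psibar_k is the posterior-mean inclusion level given the counts and c
    the hazard-weighted cohort mean.  Under the null the pairing of the
    count-derived covariate with the martingale residuals is exchangeable,
    so Var(U) = S_xx * S_ee / (n - 1) exactly -- a studentization that
    stays correct under informative censoring, where the model-based
    information of the plug-in-baseline likelihood does not.
    """
    nodes = prep["nodes"]
    a = (
        prep["log_binom"]
        + prep["log_w"][None, :]
        - fitter.cumhaz[:, None] * np.ones_like(nodes)[None, :]
    )
    m = a.max(axis=1)
    w = np.exp(a - m[:, None])
    post = w / w.sum(axis=1, keepdims=True)
    psibar = post @ nodes
    eps = fitter.delta - fitter.cumhaz
    lam_sum = float(np.sum(fitter.cumhaz))
    if lam_sum <= 0:
        return 0.0, 1.0
    x = psibar - np.sum(fitter.cumhaz * psibar) / lam_sum
    n = len(eps)
    sxx = float(np.sum((x - x.mean()) ** 2))
    see = float(np.sum((eps - eps.mean()) ** 2))
    var = sxx * see / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    stat = float(np.sum(x * eps)) ** 2 / var
    return stat, max(float(chi2.sf(stat, df=1)), _TINY_P)


def _logsumexp_1d(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + math.log(float(np.sum(np.exp(x - m))))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def exon_loglik(
    exon: ExonCounts,
    records: Sequence[SurvivalRecord],
    beta: float,
    baseline=None,
    config: SurvivConfig | None = None,
    alpha: float = 0.0,
) -> float:
    """Marginal log-likelihood of one exon at fixed beta (see module docs)."""
    fitter = SurvivFitter(records, baseline=baseline, config=config)
    return fitter.loglik(fitter.prepare(exon), beta, alpha)


def fit_beta(
    exon: ExonCounts,
    records: Sequence[SurvivalRecord],
    baseline=None,
    config: SurvivConfig | None = None,
) -> FitResult:
    """Maximize the marginal likelihood over beta for one exon."""
    fitter = SurvivFitter(records, baseline=baseline, config=config)
    fit, _ = fitter.fit(exon)
    return fit


def lrt_pvalue(loglik_alt: float, loglik_null: float, tol: float = 1e-6):
    """Likelihood-ratio statistic (floored at 0) and chi-square(1) p-value."""
    if loglik_alt < loglik_null - max(tol, 1e-9) * (1.0 + abs(loglik_null)):
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}"
        )
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    p = float(chi2.sf(stat, df=1))
    return stat, max(p, _TINY_P)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_all_exons(
    counts: Sequence[ExonCounts],
    records: Sequence[SurvivalRecord],
    config: SurvivConfig | None = None,
    baseline=None,
) -> list[SurvivResult]:
    """Fit every exon against a shared cohort and BH-adjust across exons.

    The baseline hazard is estimated once from all patients.  Exons failing
    the coverage filter (fewer than ``config.min_patients`` patients with
    n_k >= 1) are dropped and logged.
    """
    config = config or SurvivConfig()
    fitter = SurvivFitter(records, baseline=baseline, config=config)
    results: list[SurvivResult] = []
    n_filtered = 0
    for exon in counts:
        prep = fitter.prepare(exon)
        if prep["n_covered"] < config.min_patients:
            n_filtered += 1
            continue
        fit, ll0 = fitter.fit(prep)
        stat, p = lrt_pvalue(fit.loglik_alt, ll0, tol=config.tol)
        if config.test == "score":
            _, p = _score_test(fitter, prep)
        results.append(
            SurvivResult(
                exon_id=exon.exon_id,
                beta_hat=fit.beta_hat,
                loglik_alt=fit.loglik_alt,
                loglik_null=ll0,
                lrt_stat=stat,
                p_value=p,
                converged=fit.converged,
                at_bound=fit.at_bound,
            )
        )
    if n_filtered:
        logger.info("fit_all_exons: %d exons dropped by coverage filter", n_filtered)
    if not results:
        logger.warning("fit_all_exons: no exons retained")
        return []
    fdr = bh_fdr([r.p_value for r in results])
    return [dataclasses.replace(r, fdr=float(q)) for r, q in zip(results, fdr)]
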
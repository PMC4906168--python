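import math

import numpy as np
import pytest
from scipy.stats import binom

from isosurv import (
    ConstantBaseline,
    ExonCounts,
    SurvivalRecord,
    bh_fdr,
    exon_loglik,
    fit_all_exons,
    fit_beta,
    length_normalization,
    lrt_pvalue,
    nelson_aalen,
    survival_loglik_terms,
)
from isosurv.model import SurvivConfig, SurvivFitter


def brute_force_loglik(exon, records, beta, alpha=0.0, n_grid=10001,
                       prior="uniform"):
    """Independent Riemann-sum (midpoint) integration of the marginal
    likelihood; mirrors the model definition, not its implementation."""
    base = nelson_aalen(records)
    psis = (np.arange(n_grid) + 0.5) / n_grid
    weights = np.full(n_grid, 1.0 / n_grid)
    if prior != "uniform":
        a, b = prior
        pdf = psis ** (a - 1) * (1 - psis) ** (b - 1)
        weights = pdf / pdf.sum()
    p = length_normalization(psis, exon.l_inc, exon.l_skip)
    ll = 0.0
    for k, rec in enumerate(records):
        lam = float(base.cumulative(rec.time))
        surv = np.exp(-lam * np.exp(beta * psis + alpha))
        if rec.event:
            surv *= float(base.hazard_mass(rec.time)) * np.exp(beta * psis + alpha)
        lik = binom.pmf(exon.ic[k], exon.ic[k] + exon.sc[k], p)
        ll += math.log(float(np.sum(surv * lik * weights)))
    return ll


@pytest.mark.parametrize("psi,l_inc,l_skip,expected", [
    (0.5, 2, 1, 2 / 3),
    (0.0, 2, 1, 0.0),
    (1.0, 2, 1, 1.0),
    (0.3, 3, 3, 0.3),
])
def test_length_normalization_values(psi, l_inc, l_skip, expected):
    assert length_normalization(psi, l_inc, l_skip) == pytest.approx(expected)


def test_length_normalization_inverts_psi_estimate():
    from isosurv import estimate_psi

    for ic, sc in [(7, 3), (1, 9), (20, 1)]:
        est = estimate_psi(ic, sc, 2, 1)
        p = length_normalization(est.psi, 2, 1)
        assert p == pytest.approx(ic / (ic + sc))
    with pytest.raises(ValueError):
        length_normalization(1.2, 2, 1)


def test_survival_loglik_terms_closed_form():
    # censored at t=1 under a unit constant baseline: log S = -exp(beta*psi)
    base = ConstantBaseline(1.0)
    rec = SurvivalRecord("a", 1.0, 0)
    assert survival_loglik_terms(rec, 0.0, -1.0, base) == pytest.approx(-1.0)
    # beta=0: contribution independent of psi
    assert survival_loglik_terms(rec, 0.3, 0.0, base) == pytest.approx(
        survival_loglik_terms(rec, 0.9, 0.0, base)
    )
    # higher inclusion at beta=-1 improves survival by Lambda0*(1-e^-1)
    diff = survival_loglik_terms(rec, 1.0, -1.0, base) - survival_loglik_terms(
        rec, 0.0, -1.0, base
    )
    assert diff == pytest.approx(1.0 - math.exp(-1.0))


def test_exon_loglik_factorizes_at_null(toy_records):
    # single patient, IC=SC=5, equal lengths, uniform prior, censored:
    # binomial factor integrates to C(10,5)*B(6,6) = 1/11
    exon = ExonCounts("e", ("a",), np.array([5]), np.array([5]), 1, 1)
    rec = [SurvivalRecord("a", 1.0, 0)]
    base = ConstantBaseline(1.0)
    config = SurvivConfig(psi_prior="uniform")
    ll = exon_loglik(exon, rec, 0.0, baseline=base, config=config)
    # survival part: log S = -1; binomial part: log(1/11)
    assert ll == pytest.approx(-1.0 + math.log(1 / 11), abs=1e-10)


def test_exon_loglik_matches_riemann_oracle(small_null_cohort):
    config = SurvivConfig(psi_prior="uniform")
    rng = np.random.default_rng(0)
    for i in rng.choice(len(small_null_cohort.counts), size=5, replace=False):
        exon = small_null_cohort.counts[i]
        recs = small_null_cohort.records[i]
        beta = float(rng.uniform(-2, 2))
        mine = exon_loglik(exon, recs, beta, config=config)
        oracle = brute_force_loglik(exon, recs, beta)
        assert mine == pytest.approx(oracle, abs=1e-5)


def test_quadrature_refinement_converges(small_null_cohort):
    exon = small_null_cohort.counts[0]
    recs = small_null_cohort.records[0]
    coarse = exon_loglik(exon, recs, -1.3,
                         config=SurvivConfig(quadrature_points=64,
                                             psi_prior="uniform"))
    fine = exon_loglik(exon, recs, -1.3,
                       config=SurvivConfig(quadrature_points=512,
                                           psi_prior="uniform"))
    assert coarse == pytest.approx(fine, abs=1e-6)


def test_fit_beta_recovers_sign():
    from isosurv.simulate import Scenario, simulate_scenario

    scenario = Scenario(n_subjects=250, n_exons=4, alt_fraction=1.0,
                        mean_depth=80, beta_pool=(-3.0,), censoring=False,
                        seed=9)
    cohort = simulate_scenario(scenario)
    for exon, recs in zip(cohort.counts, cohort.records):
        fit = fit_beta(exon, recs)
        assert fit.beta_hat < 0


def test_fit_beta_degenerate_bounds(small_null_cohort):
    exon = small_null_cohort.counts[0]
    recs = small_null_cohort.records[0]
    config = SurvivConfig(beta_bounds=(0.0, 0.0))
    fit = fit_beta(exon, recs, config=config)
    fitter = SurvivFitter(recs, config=config)
    assert fit.beta_hat == 0.0
    assert fit.loglik_alt == pytest.approx(
        fitter.loglik(fitter.prepare(exon), 0.0)
    )


@pytest.mark.parametrize("stat,expected_p", [
    (0.0, 1.0),
    (3.841458820694124, 0.05),
    (10.827566170662733, 0.001),
])
def test_lrt_pvalue_chi2_quantiles(stat, expected_p):
    got_stat, p = lrt_pvalue(stat / 2.0, 0.0)
    assert got_stat == pytest.approx(stat)
    assert p == pytest.approx(expected_p, rel=1e-6)


def test_lrt_pvalue_consistency_error():
    with pytest.raises(ValueError):
        lrt_pvalue(-5.0, -1.0)


def test_bh_fdr_step_up():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_fdr([0.4]), [0.4])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 0.0])


def test_fit_all_exons_shared_cohort(small_null_cohort):
    recs = small_null_cohort.records[0]
    exons = small_null_cohort.counts[:3]
    results = fit_all_exons(exons + [exons[0]], recs)
    assert len(results) == 4
    # duplicated exon: identical beta and p
    assert results[3].p_value == results[0].p_value
    assert results[3].beta_hat == results[0].beta_hat
    # order equivariance
    rev = fit_all_exons(exons[::-1], recs)
    assert [r.exon_id for r in rev] == [r.exon_id for r in results[:3]][::-1]
    assert rev[-1].p_value == results[0].p_value


def test_fit_all_exons_coverage_filter(small_null_cohort):
    recs = small_null_cohort.records[0]
    n = len(recs)
    empty = ExonCounts("empty", tuple(r.patient_id for r in recs),
                       np.zeros(n, dtype=int), np.zeros(n, dtype=int))
    results = fit_all_exons([small_null_cohort.counts[0], empty], recs)
    assert [r.exon_id for r in results] == [small_null_cohort.counts[0].exon_id]
    assert fit_all_exons([empty], recs) == []
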
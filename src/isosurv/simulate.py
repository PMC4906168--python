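"""Generative engine for synthetic exon-skipping survival cohorts.

The generator mirrors the characteristics of large clinical RNA-seq cohorts
(TCGA invasive ductal carcinoma scale): 600 subjects, 20,000 exons per
experiment with 10% survival-associated, overdispersed Gamma-Poisson
junction-read depths (rate 0.05), exon-level mean inclusion drawn from
Beta(0.51, 0.36) and between-patient inclusion spread from
Gamma(1.31, 15.04), proportional-hazards survival times with the patient's
inclusion level as the covariate, and 85% random censoring with censor
times uniform on 10-90% of the death time.

Each simulated exon carries its own survival dataset, because the survival
times of an experiment are generated from that exon's inclusion levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .baseline import BaselineHazard, ConstantBaseline
from .io import ExonCounts, SurvivalRecord
from .model import length_normalization

__all__ = [
    "DEFAULT_BETA_POOL",
    "Scenario",
    "SimulatedCohort",
    "simulate_depths",
    "simulate_psi",
    "simulate_counts",
    "simulate_survival",
    "apply_censoring",
    "simulate_scenario",
    "resample_depths_from_table",
    "simulate_prediction_dataset",
]

# Fixed synthetic pool of survival coefficients for alternative exons:
# 50 magnitudes evenly spanning [1, 4], both signs.  Stands in for effect
# sizes drawn from strongly survival-associated exons of a real cohort.
_MAGS = np.linspace(1.0, 4.0, 50)
DEFAULT_BETA_POOL = tuple(np.concatenate([_MAGS, -_MAGS]))


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one simulation experiment."""

    n_subjects: int = 600
    n_exons: int = 20000
    alt_fraction: float = 0.10
    mean_depth: float = 20.0
    gamma_rate: float = 0.05
    psi_mean_beta_params: tuple[float, float] = (0.51, 0.36)
    psi_sd_gamma_params: tuple[float, float] = (1.31, 15.04)
    beta_pool: tuple[float, ...] = DEFAULT_BETA_POOL
    censoring: bool = True
    censor_fraction: float = 0.85
    baseline: BaselineHazard | ConstantBaseline = field(
        default_factory=lambda: ConstantBaseline(1.0)
    )
    l_inc: int = 2
    l_skip: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_exons < 1:
            raise ValueError("n_subjects and n_exons must be positive")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")
        if self.mean_depth <= 0 or self.gamma_rate <= 0:
            raise ValueError("mean_depth and gamma_rate must be positive")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValueError("censor_fraction must lie in [0, 1]")
        if self.alt_fraction > 0 and len(self.beta_pool) == 0:
            raise ValueError("beta_pool must be nonempty when alt_fraction > 0")


@dataclass
class SimulatedCohort:
    """Counts, per-exon survival datasets, and the generating truth."""

    counts: list[ExonCounts]
    records: list[list[SurvivalRecord]]  # one survival dataset per exon
    true_beta: np.ndarray  # per exon; 0 marks null exons
    true_psi: np.ndarray  # (n_exons, n_subjects) latent inclusion levels

    @property
    def truth_labels(self) -> np.ndarray:
        """1 for survival-associated (alternative) exons, 0 for null."""
        return (self.true_beta != 0).astype(int)


def simulate_depths(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson total junction read counts per patient.

    lambda_k ~ Gamma(shape = rate * mean_depth, rate), n_k ~ Poisson(lambda_k):
    E[n] = mean_depth, Var[n] = mean_depth * (1 + 1/rate) (overdispersed).
    """
    shape = scenario.gamma_rate * scenario.mean_depth
    lam = rng.gamma(shape, 1.0 / scenario.gamma_rate, size=scenario.n_subjects)
    return rng.poisson(lam)


def simulate_psi(
    scenario: Scenario, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Exon-level mean inclusion and per-patient inclusion levels.

    psi ~ Beta(a, b); sigma ~ Gamma(shape, rate); psi_k ~ Normal(psi, sigma^2)
    truncated to [0, 1].
    """
    a, b = scenario.psi_mean_beta_params
    shape, rate = scenario.psi_sd_gamma_params
    psi = float(rng.beta(a, b))
    sigma = float(rng.gamma(shape, 1.0 / rate))
    if sigma == 0.0:
        return psi, np.full(scenario.n_subjects, psi)
    lo, hi = (0.0 - psi) / sigma, (1.0 - psi) / sigma
    psi_k = truncnorm.rvs(lo, hi, loc=psi, scale=sigma,
                          size=scenario.n_subjects, random_state=rng)
    return psi, np.asarray(psi_k)


def simulate_counts(
    psi_k: np.ndarray,
    n_k: np.ndarray,
    l_inc: int,
    l_skip: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """IC_k ~ Binomial(n_k, f(psi_k)); SC_k = n_k - IC_k."""
    p = np.asarray(length_normalization(psi_k, l_inc, l_skip))
    ic = rng.binomial(np.asarray(n_k, dtype=np.int64), p)
    return ic, np.asarray(n_k, dtype=np.int64) - ic


def simulate_survival(
    psi_k: np.ndarray,
    beta: float,
    baseline: BaselineHazard | ConstantBaseline,
    rng: np.random.Generator,
    patient_ids: Sequence[str] | None = None,
) -> list[SurvivalRecord]:
    """Uncensored PH survival times by inverse-transform sampling.

    t_k = Lambda0^{-1}(-log U * exp(-beta * psi_k)).  With a step-function
    baseline, targets above the top of Lambda0 are administratively censored
    at the largest event time (event = 0).
    """
    psi_k = np.asarray(psi_k, dtype=float)
    u = rng.uniform(size=psi_k.shape)
    target = -np.log(u) * np.exp(-beta * psi_k)
    times, exceeded = baseline.inverse(target)
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(psi_k.size)]
    return [
        SurvivalRecord(pid, float(t), 0 if exc else 1)
        for pid, t, exc in zip(patient_ids, np.atleast_1d(times),
                               np.atleast_1d(exceeded))
    ]


def apply_censoring(
    records: Sequence[SurvivalRecord],
    censor_fraction: float,
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Randomly censor exactly round(fraction * n) subjects.

    Censored subjects get event = 0 and a censor time uniform on 10-90% of
    their death time.
    """
    if not 0.0 <= censor_fraction <= 1.0:
        raise ValueError("censor_fraction must lie in [0, 1]")
    n = len(records)
    n_censor = int(round(censor_fraction * n))
    chosen = rng.choice(n, size=n_censor, replace=False)
    fracs = rng.uniform(0.10, 0.90, size=n_censor)
    out: list[SurvivalRecord] = list(records)
    for i, frac in zip(chosen, fracs):
        rec = records[i]
        out[i] = SurvivalRecord(rec.patient_id, rec.time * float(frac), 0)
    return out


def simulate_scenario(scenario: Scenario) -> SimulatedCohort:
    """Compose depths, inclusion levels, counts and survival for all exons.

    Alternative exons (the first round(alt_fraction * n_exons) of the truth
    vector before shuffling) draw beta uniformly from the pool; null exons
    have beta = 0.  Fully reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n_alt = int(round(scenario.alt_fraction * scenario.n_exons))
    betas = np.zeros(scenario.n_exons)
    if n_alt:
        pool = np.asarray(scenario.beta_pool, dtype=float)
        betas[:n_alt] = rng.choice(pool, size=n_alt, replace=True)
        rng.shuffle(betas)
    patient_ids = [f"P{i:04d}" for i in range(scenario.n_subjects)]
    counts: list[ExonCounts] = []
    records: list[list[SurvivalRecord]] = []
    true_psi = np.empty((scenario.n_exons, scenario.n_subjects))
    for e in range(scenario.n_exons):
        n_k = simulate_depths(scenario, rng)
        _, psi_k = simulate_psi(scenario, rng)
        ic, sc = simulate_counts(psi_k, n_k, scenario.l_inc, scenario.l_skip, rng)
        recs = simulate_survival(psi_k, betas[e], scenario.baseline, rng,
                                 patient_ids=patient_ids)
        if scenario.censoring:
            recs = apply_censoring(recs, scenario.censor_fraction, rng)
        counts.append(
            ExonCounts(f"exon{e:05d}", tuple(patient_ids), ic, sc,
                       scenario.l_inc, scenario.l_skip)
        )
        records.append(recs)
        true_psi[e] = psi_k
    return SimulatedCohort(counts, records, betas, true_psi)


def resample_depths_from_table(
    empirical_counts,
    scale: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap read depths from an empirical count table, rescaled.

    Samples with replacement from user-supplied total junction counts,
    multiplies by ``scale`` (10-300% emulates shallower/deeper sequencing)
    and rounds to the nearest integer.
    """
    counts = np.asarray(empirical_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empirical count table is empty")
    if not 0.0 < scale <= 3.0:
        raise ValueError("scale must lie in (0, 3]")
    draws = rng.choice(counts, size=size, replace=True)
    return np.rint(draws * scale).astype(np.int64)


# ---------------------------------------------------------------------------
# synthetic data for the prediction / cross-validation protocol
# ---------------------------------------------------------------------------


def simulate_prediction_dataset(
    n_patients: int = 150,
    n_clinical: int = 4,
    n_genes: int = 20,
    n_splicing: int = 20,
    n_informative: int = 3,
    effect: float = 1.2,
    readout_noise: float = 0.8,
    mean_depth: float = 50.0,
    censor_fraction: float = 0.3,
    seed: int = 0,
):
    """One shared-cohort dataset for exercising the survival-prediction CV.

    Survival is driven by a latent per-patient prognosis factor z ~ N(0, 1)
    (hazard rate exp(effect * z)); the first ``n_informative`` features of
    each class are noisy readouts of z (clinical and gene features
    z + Normal(0, readout_noise); informative inclusion levels shift with z)
    while the remaining features are pure noise.  Survival times are
    exponential given z and a fraction of subjects is randomly censored.
    Returns (clinical_df, gene_df, splicing_counts, records, truth) where
    truth lists the informative feature ids.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    pids = [f"P{i:04d}" for i in range(n_patients)]
    z = rng.normal(size=n_patients)

    def readout(j: int, informative: bool) -> np.ndarray:
        if not informative:
            return rng.normal(size=n_patients)
        sign = 1.0 if j % 2 == 0 else -1.0
        return sign * z + readout_noise * rng.normal(size=n_patients)

    clin = pd.DataFrame(
        {f"clin{j}": readout(j, j < n_informative) for j in range(n_clinical)},
        index=pids,
    )
    genes = pd.DataFrame(
        {f"gene{j}": readout(j, j < n_informative) for j in range(n_genes)},
        index=pids,
    )
    psi_latent = np.empty((n_splicing, n_patients))
    truth = [f"clin{j}" for j in range(min(n_informative, n_clinical))]
    truth += [f"gene{j}" for j in range(min(n_informative, n_genes))]
    for j in range(n_splicing):
        if j < n_informative:
            sign = 1.0 if j % 2 == 0 else -1.0
            shift = 0.15 * (sign * z + readout_noise * rng.normal(size=n_patients))
            psi_latent[j] = np.clip(0.5 + shift, 0.01, 0.99)
            truth.append(f"ex{j:03d}")
        else:
            psi_latent[j] = rng.beta(2, 2, size=n_patients)
    times = rng.exponential(np.exp(-effect * z))
    records = [SurvivalRecord(p, float(t), 1) for p, t in zip(pids, times)]
    records = apply_censoring(records, censor_fraction, rng)
    depth = rng.poisson(mean_depth, size=(n_splicing, n_patients))
    splicing = []
    for j in range(n_splicing):
        ic, sc = simulate_counts(psi_latent[j], depth[j], 2, 1, rng)
        splicing.append(ExonCounts(f"ex{j:03d}", tuple(pids), ic, sc, 2, 1))
    return clin, genes, splicing, records, truth
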
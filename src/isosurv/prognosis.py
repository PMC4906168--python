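"""Survival-predictor construction and Monte Carlo cross-validation.

Compares predictor classes (clinical, gene expression, alternative
splicing) by repeated two-fold cross-validation: in each round patients are
split 50/50; candidate features are screened on the training half by
univariate survival regression (the measurement-error model for splicing
count features, Cox regression for point-valued features, P <= 0.01);
molecular features are z-scored with training statistics; an L1-penalized
Cox model combines the selected features; and the held-out half is scored
by Harrell's C-index.  Splits are shared across predictor classes within a
round, so per-round C-indexes are paired and model classes are compared by
a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .cox import breslow_partial_loglik, cox_fit
from .evaluate import concordance_index
from .io import ExonCounts, SurvivalRecord, psi_point_estimates
from .model import SurvivConfig, SurvivFitter

logger = logging.getLogger("isosurv")

__all__ = [
    "FeatureTable",
    "PredictionModel",
    "CvReport",
    "univariate_screen",
    "zscore_normalize",
    "l1_cox_fit",
    "monte_carlo_cv",
    "compare_models",
]


@dataclass
class FeatureTable:
    """Per-patient features of one class.

    ``values`` holds point-valued features (patients x features).  Splicing
    tables additionally carry the raw count pairs (``counts``) used for
    measurement-error screening; their point values are PSI estimates.
    """

    klass: str  # clinical | gene | splicing
    values: pd.DataFrame
    counts: list[ExonCounts] | None = None

    @classmethod
    def from_splicing_counts(
        cls, counts: Sequence[ExonCounts]
    ) -> "FeatureTable":
        if not counts:
            raise ValueError("empty splicing count collection")
        values = pd.DataFrame(
            {e.exon_id: psi_point_estimates(e) for e in counts},
            index=list(counts[0].patients),
        )
        return cls("splicing", values, counts=list(counts))


@dataclass(frozen=True)
class PredictionModel:
    """Sparse linear risk model: risk = X @ coef (on the scaled feature space)."""

    feature_names: tuple[str, ...]
    coefs: np.ndarray
    alpha: float
    train_mean: np.ndarray
    train_sd: np.ndarray
    scale_mask: np.ndarray  # which features were z-scored

    def risk_scores(self, values: pd.DataFrame) -> np.ndarray:
        x = values.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        x = np.where(np.isfinite(x), x, self.train_mean)  # mean-impute missing
        scaled = np.where(
            self.scale_mask, (x - self.train_mean) / self.train_sd, x
        )
        return scaled @ self.coefs


@dataclass
class CvReport:
    """Per-round test-set C-indexes, one column per model."""

    c_index: pd.DataFrame  # rounds x models

    def summary(self) -> pd.DataFrame:
        return self.c_index.agg(["median", lambda s: s.quantile(0.25),
                                 lambda s: s.quantile(0.75)]).set_axis(
            ["median", "q25", "q75"]
        )


# ---------------------------------------------------------------------------
# screening and scaling
# ---------------------------------------------------------------------------


def univariate_screen(
    table: FeatureTable,
    records: Sequence[SurvivalRecord],
    threshold: float = 0.01,
    config: SurvivConfig | None = None,
) -> list[str]:
    """Select features univariately associated with survival (P <= threshold).

    Splicing count features are screened with the measurement-error model;
    clinical and gene features with single-covariate Cox regression.
    Features whose fit fails a precondition are skipped.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    pids = [r.patient_id for r in records]
    selected: list[str] = []
    if table.klass == "splicing" and table.counts is not None:
        config = config or SurvivConfig()
        order = {p: i for i, p in enumerate(table.counts[0].patients)}
        idx = np.array([order[p] for p in pids], dtype=int)
        fitter = SurvivFitter(records, config=config)
        for exon in table.counts:
            sub = ExonCounts(exon.exon_id, tuple(pids), exon.ic[idx],
                             exon.sc[idx], exon.l_inc, exon.l_skip)
            prep = fitter.prepare(sub)
            if prep["n_covered"] < config.min_patients:
                continue
            if fitter.exon_pvalue(prep) <= threshold:
                selected.append(exon.exon_id)
        return selected
    values = table.values.loc[pids]
    for name in values.columns:
        try:
            res = cox_fit(values[name].to_numpy(dtype=float), records, exon_id=name)
        except ValueError:
            continue
        if res.flag != "separation" and res.p_value <= threshold:
            selected.append(name)
    return selected


def zscore_normalize(
    train_values: pd.DataFrame, test_values: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale both folds by the training mean and SD (n-1 denominator).

    Constant training features are dropped from both folds (logged); no test
    information leaks into the scaling.
    """
    mean = train_values.mean()
    sd = train_values.std(ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("zscore_normalize: dropping %d constant features",
                    int((~keep).sum()))
    cols = train_values.columns[keep]
    return (
        (train_values[cols] - mean[cols]) / sd[cols],
        (test_values[cols] - mean[cols]) / sd[cols],
    )


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------


def _surv_array(records: Sequence[SurvivalRecord]):
    from sksurv.util import Surv

    return Surv.from_arrays(
        event=np.array([bool(r.event) for r in records]),
        time=np.array([r.time for r in records]),
    )


def _default_alpha_grid(x: np.ndarray, records, n_alphas: int = 50) -> np.ndarray:
    """Data-driven penalty grid from coxnet's own regularization path."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, fit_baseline_model=False,
                                   n_alphas=10, alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, _surv_array(records))
    alpha_max = float(model.alphas_[0])
    return np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)


def _coxnet_path(x: np.ndarray, records, alphas: np.ndarray) -> np.ndarray:
    """Coefficient path (n_features x n_alphas) of an L1 Cox fit.

    Each penalty is fitted independently: coxnet's warm-started path can
    terminate early on user-supplied grids, silently dropping alphas.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    y = _surv_array(records)
    coefs = np.zeros((x.shape[1], len(alphas)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, a in enumerate(alphas):
            model = CoxnetSurvivalAnalysis(
                alphas=[float(a)], l1_ratio=1.0, fit_baseline_model=False
            )
            try:
                model.fit(x, y)
            except (ValueError, ArithmeticError):
                continue
            coefs[:, j] = model.coef_[:, 0]
    return coefs


def l1_cox_fit(
    values: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    penalty_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    scale_mask: np.ndarray | None = None,
) -> PredictionModel:
    """L1-penalized Cox fit with the penalty tuned by internal k-fold CV.

    The penalty maximizing the held-out Breslow partial log-likelihood over
    a 50-point log grid is selected, then the model is refitted on the full
    training data at that penalty.  ``values`` must already be on its final
    scale (see :func:`zscore_normalize`); ``scale_mask`` only records which
    columns were scaled so test-set features can be transformed identically.
    """
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit")
    x = values.to_numpy(dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x, axis=0))
    times = np.array([r.time for r in records], dtype=float)
    if penalty_grid is None:
        penalty_grid = _default_alpha_grid(x, records)
    alphas = np.sort(np.asarray(penalty_grid, dtype=float))[::-1]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    folds = np.array_split(order, cv_folds)
    cv_ll = np.zeros(len(alphas))
    for hold in folds:
        mask = np.ones(len(records), dtype=bool)
        mask[hold] = False
        if events[mask].sum() < 2 or events[~mask].sum() < 1:
            continue
        train_recs = [records[i] for i in np.flatnonzero(mask)]
        try:
            path = _coxnet_path(x[mask], train_recs, alphas)
        except (ValueError, ArithmeticError):
            continue
        lp_test = x[~mask] @ path  # (n_test, n_alphas)
        for j in range(len(alphas)):
            cv_ll[j] += breslow_partial_loglik(lp_test[:, j], times[~mask],
                                               events[~mask])
    best = int(np.argmax(cv_ll))
    path = _coxnet_path(x, list(records), alphas)
    coefs = path[:, best]
    if not np.any(coefs):
        logger.info("l1_cox_fit: all coefficients shrunk to zero")
    mean = np.zeros(x.shape[1])
    sd = np.ones(x.shape[1])
    if scale_mask is None:
        scale_mask = np.zeros(x.shape[1], dtype=bool)
    return PredictionModel(
        feature_names=tuple(values.columns),
        coefs=coefs,
        alpha=float(alphas[best]),
        train_mean=mean,
        train_sd=sd,
        scale_mask=np.asarray(scale_mask, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------


def _assemble(
    tables: Sequence[FeatureTable],
    selected: Mapping[int, list[str]],
    train_ids: list[str],
    test_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-concatenate selected features; z-score molecular classes."""
    train_parts, test_parts, masks = [], [], []
    for i, table in enumerate(tables):
        cols = selected.get(i, [])
        if not cols:
            continue
        tr = table.values.loc[train_ids, cols]
        te = table.values.loc[test_ids, cols]
        if table.klass in ("gene", "splicing"):
            tr, te = zscore_normalize(tr, te)
            masks.append(np.ones(tr.shape[1], dtype=bool))
        else:
            masks.append(np.zeros(tr.shape[1], dtype=bool))
        train_parts.append(tr)
        test_parts.append(te)
    if not train_parts:
        empty = pd.DataFrame(index=train_ids)
        return empty, pd.DataFrame(index=test_ids), np.zeros(0, dtype=bool)
    return (
        pd.concat(train_parts, axis=1),
        pd.concat(test_parts, axis=1),
        np.concatenate(masks),
    )


def monte_carlo_cv(
    models: Mapping[str, Sequence[FeatureTable]],
    records: Sequence[SurvivalRecord],
    rounds: int = 100,
    split: float = 0.5,
    seed: int = 0,
    threshold: float = 0.01,
    config: SurvivConfig | None = None,
    screen_on_full_cohort: bool = False,
    max_retries: int = 20,
) -> CvReport:
    """Repeated random-split cross-validation of survival predictors.

    Each round draws one train/test split shared by every model class
    (paired design).  Screening, scaling and penalized fitting all happen
    inside the training half; the test half is only scored.  Rounds whose
    test half has fewer than 2 events are redrawn (logged, up to
    ``max_retries``).  ``screen_on_full_cohort=True`` is a deliberately
    leaky diagnostic mode and is never the default.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    pids = [r.patient_id for r in records]
    n_train = int(round(split * len(records)))
    rows = []
    if screen_on_full_cohort:
        logger.warning("monte_carlo_cv: screening on the FULL cohort (leaky mode)")
        full_selected = {
            name: {i: univariate_screen(t, list(records), threshold, config)
                   for i, t in enumerate(tables)}
            for name, tables in models.items()
        }
    for _ in range(rounds):
        for _attempt in range(max_retries):
            perm = rng.permutation(len(records))
            tr_idx, te_idx = perm[:n_train], perm[n_train:]
            ev = np.array([records[i].event for i in te_idx])
            ev_tr = np.array([records[i].event for i in tr_idx])
            if ev.sum() >= 2 and ev_tr.sum() >= 2:
                break
            logger.info("monte_carlo_cv: redrawing split with <2 events")
        train_recs = [records[i] for i in tr_idx]
        test_recs = [records[i] for i in te_idx]
        train_ids = [pids[i] for i in tr_idx]
        test_ids = [pids[i] for i in te_idx]
        row = {}
        for name, tables in models.items():
            if screen_on_full_cohort:
                selected = full_selected[name]
            else:
                selected = {
                    i: univariate_screen(t, train_recs, threshold, config)
                    for i, t in enumerate(tables)
                }
            tr_x, te_x, scale_mask = _assemble(tables, selected, train_ids, test_ids)
            if tr_x.shape[1] == 0:
                row[name] = 0.5  # no predictors selected: uninformative model
                continue
            model = l1_cox_fit(tr_x, train_recs,
                               seed=int(rng.integers(2**31)),
                               scale_mask=scale_mask)
            risk = te_x.to_numpy(dtype=float) @ model.coefs
            if not np.any(model.coefs):
                row[name] = 0.5
                continue
            row[name] = concordance_index(risk, test_recs)
        rows.append(row)
    return CvReport(pd.DataFrame(rows))


def compare_models(report: CvReport, pair: tuple[str, str]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-round C-indexes."""
    a, b = pair
    for name in pair:
        if name not in report.c_index.columns:
            raise ValueError(f"model {name!r} not present in report")
    da = report.c_index[a].to_numpy()
    db = report.c_index[b].to_numpy()
    if da.shape != db.shape:
        raise ValueError("mismatched round counts")
    diff = da - db
    if np.all(diff == 0):
        return 1.0
    return float(wilcoxon(da, db, alternative="two-sided").pvalue)
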
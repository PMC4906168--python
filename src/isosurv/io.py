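"""Domain types, TSV readers/writers and exon-inclusion (PSI) point estimation.

The on-disk contract is plain tab-separated text with a header row:

* survival table: ``patient_id, time, event`` (time in days, event 1 = death
  observed, 0 = censored);
* counts table: ``exon_id, l_inc, l_skip`` followed by a pair of columns
  ``<patient>_IC, <patient>_SC`` per patient, holding the inclusion-junction
  and skipping-junction read counts of each exon-skipping event;
* results table: one row per exon with the fitted survival coefficient,
  log-likelihoods, LRT statistic, p-value and BH-adjusted FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("isosurv")

__all__ = [
    "SurvivalRecord",
    "ExonCounts",
    "PsiEstimate",
    "SurvivResult",
    "SchemaError",
    "ValidationError",
    "read_survival_table",
    "read_counts_table",
    "write_counts_table",
    "estimate_psi",
    "psi_point_estimates",
    "write_results_table",
    "read_results_table",
    "write_survival_table",
    "align_cohort",
]


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class ValidationError(ValueError):
    """A row violates a type invariant (addressable by row / exon / patient)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days and event indicator (1 = death)."""

    patient_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: time must be positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass
class ExonCounts:
    """Per-exon inclusion/skipping junction read counts over a patient cohort.

    ``l_inc`` / ``l_skip`` are the effective lengths (number of unique
    isoform-specific read positions) of the inclusion and skipping isoforms.
    For junction-only counting of an exon-skipping event the inclusion isoform
    has two junctions and the skipping isoform one, hence the (2, 1) default.
    """

    exon_id: str
    patients: tuple[str, ...]
    ic: np.ndarray
    sc: np.ndarray
    l_inc: int = 2
    l_skip: int = 1

    def __post_init__(self) -> None:
        self.ic = np.asarray(self.ic, dtype=np.int64)
        self.sc = np.asarray(self.sc, dtype=np.int64)
        self.patients = tuple(self.patients)
        if self.ic.shape != self.sc.shape or self.ic.shape != (len(self.patients),):
            raise ValidationError(f"exon {self.exon_id!r}: count/patient shape mismatch")
        if (self.ic < 0).any() or (self.sc < 0).any():
            bad = self.patients[int(np.argmax((self.ic < 0) | (self.sc < 0)))]
            raise ValidationError(f"exon {self.exon_id!r}, patient {bad!r}: negative count")
        if self.l_inc < 1 or self.l_skip < 1:
            raise ValidationError(f"exon {self.exon_id!r}: effective lengths must be >= 1")

    @property
    def n_total(self) -> np.ndarray:
        """Total junction read count per patient, n = IC + SC."""
        return self.ic + self.sc


@dataclass(frozen=True)
class PsiEstimate:
    """Point estimate of the exon-inclusion level (PSI) for one patient."""

    psi: float
    n_total: int

    @property
    def missing(self) -> bool:
        return self.n_total == 0


@dataclass(frozen=True)
class SurvivResult:
    """Per-exon fit of the measurement-error PH model and its LRT."""

    exon_id: str
    beta_hat: float
    loglik_alt: float
    loglik_null: float
    lrt_stat: float
    p_value: float
    fdr: float = math.nan
    converged: bool = True
    at_bound: bool = False


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_DIALECT = {"id": "patient_id", "time": "time", "event": "event"}


def read_survival_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[SurvivalRecord]:
    """Read a survival TSV into validated records, preserving row order.

    ``dialect`` maps the logical names ``id``/``time``/``event`` to the
    actual column names in the file.
    """
    colmap = dict(_DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", comment="#")
    for logical, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} (for {logical!r}) in {path}")
    records: list[SurvivalRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        pid = str(getattr(row, colmap["id"]))
        if pid in seen:
            raise ValidationError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            rec = SurvivalRecord(pid, float(getattr(row, colmap["time"])),
                                 int(getattr(row, colmap["event"])))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_survival_table(records: Sequence[SurvivalRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _int_column(values: pd.Series, exon_ids: pd.Series, col: str) -> np.ndarray:
    arr = pd.to_numeric(values, errors="coerce")
    bad = arr.isna() | (arr % 1 != 0) | (arr < 0)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValidationError(
            f"exon {exon_ids.iloc[i]!r}, column {col!r}: "
            f"count {values.iloc[i]!r} is not a nonnegative integer"
        )
    return arr.to_numpy(dtype=np.int64)


def read_counts_table(path) -> list[ExonCounts]:
    """Read an exon-skipping junction-count TSV into per-exon count vectors."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("exon_id", "l_inc", "l_skip"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    count_cols = [c for c in df.columns if c not in ("exon_id", "l_inc", "l_skip")]
    patients: list[str] = []
    for c in count_cols:
        if c.endswith("_IC"):
            pid = c[: -len("_IC")]
            if f"{pid}_SC" not in df.columns:
                raise SchemaError(f"column {c!r} has no matching {pid}_SC")
            patients.append(pid)
        elif not c.endswith("_SC"):
            raise SchemaError(f"unrecognized column {c!r} (expect <patient>_IC/_SC)")
    exons: list[ExonCounts] = []
    if df.empty:
        return exons
    lengths_inc = _int_column(df["l_inc"], df["exon_id"], "l_inc")
    lengths_skip = _int_column(df["l_skip"], df["exon_id"], "l_skip")
    ic_mat = np.column_stack(
        [_int_column(df[f"{p}_IC"], df["exon_id"], f"{p}_IC") for p in patients]
    )
    sc_mat = np.column_stack(
        [_int_column(df[f"{p}_SC"], df["exon_id"], f"{p}_SC") for p in patients]
    )
    for i in range(len(df)):
        exons.append(
            ExonCounts(
                exon_id=str(df["exon_id"].iloc[i]),
                patients=tuple(patients),
                ic=ic_mat[i],
                sc=sc_mat[i],
                l_inc=int(lengths_inc[i]),
                l_skip=int(lengths_skip[i]),
            )
        )
    return exons


def write_counts_table(exons: Sequence[ExonCounts], path) -> None:
    if not exons:
        pd.DataFrame(columns=["exon_id", "l_inc", "l_skip"]).to_csv(
            path, sep="\t", index=False
        )
        return
    patients = exons[0].patients
    data: dict[str, list] = {
        "exon_id": [e.exon_id for e in exons],
        "l_inc": [e.l_inc for e in exons],
        "l_skip": [e.l_skip for e in exons],
    }
    for j, p in enumerate(patients):
        data[f"{p}_IC"] = [int(e.ic[j]) for e in exons]
        data[f"{p}_SC"] = [int(e.sc[j]) for e in exons]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSI point estimation
# ---------------------------------------------------------------------------


def estimate_psi(ic: int, sc: int, l_inc: int = 2, l_skip: int = 1) -> PsiEstimate:
    """Effective-length-normalized PSI point estimate.

    psi-hat = (IC / l_I) / (IC / l_I + SC / l_S); undefined (missing) when
    IC + SC = 0. This inverts the length-normalization p = f(psi) that maps
    an inclusion level to the expected inclusion-read proportion.
    """
    if l_inc < 1 or l_skip < 1:
        raise ValueError("effective lengths must be >= 1")
    if ic < 0 or sc < 0:
        raise ValueError("counts must be nonnegative")
    n = ic + sc
    if n == 0:
        return PsiEstimate(math.nan, 0)
    num = ic / l_inc
    return PsiEstimate(num / (num + sc / l_skip), n)


def psi_point_estimates(exon: ExonCounts) -> np.ndarray:
    """Vector of PSI point estimates across patients, NaN where n = 0."""
    ic = exon.ic.astype(float)
    sc = exon.sc.astype(float)
    num = ic / exon.l_inc
    den = num + sc / exon.l_skip
    with np.errstate(invalid="ignore"):
        psi = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return psi


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ("exon_id", "beta", "loglik_alt", "loglik_null", "lrt", "pvalue", "fdr")


def write_results_table(results: Sequence[SurvivResult], path) -> None:
    """Write fit results as TSV with a stable column order (see module docs)."""
    df = pd.DataFrame(
        {
            "exon_id": [r.exon_id for r in results],
            "beta": [r.beta_hat for r in results],
            "loglik_alt": [r.loglik_alt for r in results],
            "loglik_null": [r.loglik_null for r in results],
            "lrt": [r.lrt_stat for r in results],
            "pvalue": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
        },
        columns=list(_RESULT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10e")


def read_results_table(path) -> list[SurvivResult]:
    df = pd.read_csv(path, sep="\t")
    for col in _RESULT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    return [
        SurvivResult(
            exon_id=str(r.exon_id),
            beta_hat=float(r.beta),
            loglik_alt=float(r.loglik_alt),
            loglik_null=float(r.loglik_null),
            lrt_stat=float(r.lrt),
            p_value=float(r.pvalue),
            fdr=float(r.fdr),
        )
        for r in df.itertuples(index=False)
    ]


def align_cohort(
    exons: Sequence[ExonCounts], records: Sequence[SurvivalRecord]
) -> tuple[list[ExonCounts], list[SurvivalRecord]]:
    """Inner-join counts and survival on patient_id; drop the rest with a warning."""
    if not exons:
        return [], list(records)
    count_patients = set(exons[0].patients)
    surv_patients = {r.patient_id for r in records}
    shared = [r.patient_id for r in records if r.patient_id in count_patients]
    dropped = (count_patients - surv_patients) | (surv_patients - count_patients)
    if dropped:
        logger.warning(
            "align_cohort: dropping %d patients absent from one table", len(dropped)
        )
    kept_records = [r for r in records if r.patient_id in count_patients]
    order = {p: i for i, p in enumerate(exons[0].patients)}
    idx = np.array([order[p] for p in shared], dtype=int)
    aligned = [
        ExonCounts(e.exon_id, tuple(shared), e.ic[idx], e.sc[idx], e.l_inc, e.l_skip)
        for e in exons
    ]
    return aligned, kept_records
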
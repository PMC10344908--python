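"""Cohort assembly: labels, standardization, pair expansion and splitting.

Training examples are (T, D, S) triplets: a patient's standardized
transcriptome T, the fingerprint D of one prescribed drug, and a survival
signal S. Two label schemes are used:

* stage I (classification): short-lived patients — deceased within
  ``short_max_days`` (default 1000) — get y = 0; long-lived patients — a
  survival lower bound (days-to-death or days-to-last-follow-up) above
  ``long_min_days`` (default 1200) — get y = 1. Patients between the
  thresholds carry too little signal either way and are excluded. Censored
  patients with a long enough follow-up count as long-lived: the follow-up
  time is a lower bound on survival.
* stage II (regression): deceased patients only, labelled with
  log(months-to-death) where a month is 365.25/12 = 30.4375 days.

Multi-drug patients (tandem or combination prescriptions) contribute one
example per drug, all sharing the same expression vector. Splitting is by
patient — every pair of one patient lands in a single fold — and stratified,
so a patient's transcriptome never leaks across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .chem import DrugRecord

logger = logging.getLogger(__name__)

__all__ = [
    "VitalStatus", "ClinicalRecord", "ExpressionMatrix", "TrainingExample",
    "DAYS_PER_MONTH", "SHORT_MAX_DAYS", "LONG_MIN_DAYS",
    "standardize_expression", "build_stage1_cohort", "build_stage2_cohort",
    "days_to_log_months", "log_months_to_days", "expand_patient_drug_pairs",
    "split_cohort", "read_clinical_tsv", "read_expression",
]

DAYS_PER_MONTH = 365.25 / 12  # 30.4375
SHORT_MAX_DAYS = 1000
LONG_MIN_DAYS = 1200


class VitalStatus(str, Enum):
    DECEASED = "deceased"
    ALIVE_OR_CENSORED = "alive_or_censored"


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    vital_status: VitalStatus
    days_to_death: float | None = None
    days_to_last_followup: float | None = None
    drugs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.vital_status is VitalStatus.DECEASED \
                and self.days_to_death is None:
            raise ValueError(f"patient {self.patient_id!r}: deceased but "
                             "days_to_death missing")
        if self.vital_status is VitalStatus.ALIVE_OR_CENSORED \
                and self.days_to_last_followup is None:
            raise ValueError(f"patient {self.patient_id!r}: censored but "
                             "days_to_last_followup missing")

    @property
    def survival_lower_bound(self) -> float:
        """Exact days for the deceased, censoring time otherwise."""
        if self.vital_status is VitalStatus.DECEASED:
            return self.days_to_death
        return self.days_to_last_followup


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (FPKM-like, or z-scores)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression shape does not match ids")

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[idx, :], self.standardized)


@dataclass(frozen=True)
class TrainingExample:
    patient_id: str
    expression: np.ndarray     # standardized, over the pruned DAG's genes
    fingerprint: np.ndarray
    drug_name: str
    label: float               # y in {0,1} (stage I) or log months (stage II)


def standardize_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (population SD).

    Constant genes become all-zero with a logged warning, which keeps the
    encoder's input dimension stable across cohorts. Raises if `m` is
    already standardized or empty.
    """
    if m.standardized:
        raise ValueError("expression matrix is already standardized")
    if m.values.size == 0:
        raise ValueError("empty expression matrix")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant gene(s) standardized to zero: %s",
                       int(constant.sum()),
                       ", ".join(np.array(m.gene_ids)[constant][:10]))
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (m.values - mu) / safe_sd
    z[constant, :] = 0.0
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), z,
                            standardized=True)


def days_to_log_months(days: float) -> float:
    """ln(days / 30.4375); inverse of :func:`log_months_to_days`."""
    if days <= 0:
        raise ValueError(f"days must be positive, got {days}")
    return math.log(days / DAYS_PER_MONTH)


def log_months_to_days(log_months: float) -> float:
    return math.exp(log_months) * DAYS_PER_MONTH


def build_stage1_cohort(records: list[ClinicalRecord],
                        short_max_days: int = SHORT_MAX_DAYS,
                        long_min_days: int = LONG_MIN_DAYS,
                        ) -> list[tuple[ClinicalRecord, int]]:
    """Label patients short-lived (0) / long-lived (1) for classification.

    y = 0 iff deceased with days_to_death < short_max_days; y = 1 iff the
    survival lower bound exceeds long_min_days; everyone else is excluded.
    """
    if short_max_days > long_min_days:
        raise ValueError("short_max_days must be <= long_min_days")
    if not records:
        logger.warning("empty clinical record list; empty stage-1 cohort")
        return []
    out: list[tuple[ClinicalRecord, int]] = []
    n_excluded = 0
    for rec in records:
        if rec.vital_status is VitalStatus.DECEASED \
                and rec.days_to_death < short_max_days:
            out.append((rec, 0))
        elif rec.survival_lower_bound > long_min_days:
            out.append((rec, 1))
        else:
            n_excluded += 1
    logger.info("stage-1 cohort: %d labeled (%d short, %d long), %d excluded",
                len(out), sum(1 for _, y in out if y == 0),
                sum(1 for _, y in out if y == 1), n_excluded)
    return out


def build_stage2_cohort(records: list[ClinicalRecord],
                        ) -> list[tuple[ClinicalRecord, float]]:
    """Deceased patients with positive days-to-death, labelled log months."""
    out: list[tuple[ClinicalRecord, float]] = []
    for rec in records:
        if rec.vital_status is not VitalStatus.DECEASED:
            continue
        if rec.days_to_death <= 0:
            logger.warning("patient %s excluded: nonpositive days_to_death",
                           rec.patient_id)
            continue
        out.append((rec, days_to_log_months(rec.days_to_death)))
    return out


def expand_patient_drug_pairs(
    cohort: list[tuple[ClinicalRecord, float]],
    drug_library: dict[str, DrugRecord],
    expression: ExpressionMatrix,
) -> list[TrainingExample]:
    """One training example per (patient, drug) pair.

    Patients with several prescribed drugs contribute one example per drug,
    sharing a single expression vector. Drugs absent from the library (no
    SMILES/fingerprint) are skipped and counted.
    """
    if not expression.standardized:
        raise ValueError("expression must be standardized before pairing")
    examples: list[TrainingExample] = []
    n_missing = 0
    sample_pos = {s: i for i, s in enumerate(expression.sample_ids)}
    for rec, label in cohort:
        if rec.patient_id not in sample_pos:
            logger.warning("patient %s has no expression column; skipped",
                           rec.patient_id)
            continue
        expr = expression.values[:, sample_pos[rec.patient_id]]
        for drug in rec.drugs:
            if drug not in drug_library:
                n_missing += 1
                continue
            examples.append(TrainingExample(
                rec.patient_id, expr, drug_library[drug].fingerprint,
                drug, float(label)))
    if n_missing:
        logger.info("%d (patient, drug) pair(s) dropped: drug not in library",
                    n_missing)
    return examples


def split_cohort(examples: list[TrainingExample], val_fraction: float = 0.2,
                 seed: int = 0, stratify: str = "auto",
                 ) -> tuple[list[TrainingExample], list[TrainingExample]]:
    """Patient-level stratified train/validation split.

    All pairs of one patient land in one fold. Stratification is by binary
    label for classification cohorts and by label quartile for regression
    cohorts (`stratify='auto'` picks based on the label set; 'none'
    disables). Deterministic given `seed`.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0,1), got {val_fraction}")
    by_patient: dict[str, list[TrainingExample]] = {}
    for ex in examples:
        by_patient.setdefault(ex.patient_id, []).append(ex)
    patients = sorted(by_patient)
    if len(patients) < 2:
        raise ValueError("need >= 2 distinct patients to split")

    labels = np.array([by_patient[p][0].label for p in patients])
    if stratify == "none":
        strata = np.zeros(len(patients), dtype=int)
    elif set(np.unique(labels)) <= {0.0, 1.0}:
        strata = labels.astype(int)
    else:  # regression: quartile bins of the per-patient label
        qs = np.quantile(labels, [0.25, 0.5, 0.75])
        strata = np.searchsorted(qs, labels, side="left")

    rng = np.random.default_rng(seed)
    val_patients: set[str] = set()
    for s in np.unique(strata):
        members = [p for p, st in zip(patients, strata) if st == s]
        rng.shuffle(members)
        n_val = int(round(val_fraction * len(members)))
        val_patients.update(members[:n_val])
    train = [ex for p in patients if p not in val_patients
             for ex in by_patient[p]]
    val = [ex for p in patients if p in val_patients
           for ex in by_patient[p]]
    return train, val


# ---------------------------------------------------------------------------
# file formats

def read_clinical_tsv(path: str) -> list[ClinicalRecord]:
    """Read the clinical table.

    Columns: patient_id, vital_status ('deceased'/'alive_or_censored'),
    days_to_death, days_to_last_followup (either may be empty), drugs
    (semicolon-separated names).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        records.append(ClinicalRecord(
            patient_id=row.patient_id,
            vital_status=VitalStatus(row.vital_status),
            days_to_death=float(row.days_to_death)
            if row.days_to_death != "" else None,
            days_to_last_followup=float(row.days_to_last_followup)
            if row.days_to_last_followup != "" else None,
            drugs=tuple(d for d in row.drugs.split(";") if d),
        ))
    return records


def read_expression(path: str, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table with a header row of sample ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy(dtype=np.float64))
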
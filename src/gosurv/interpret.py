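"""Attention-based interpretation and in-silico optimal drug selection.

Two interpretability outputs come from the encoder's attention weights:

* per patient, terms whose attention weight exceeds a depth-banded cutoff
  are flagged "most discriminating" (strict >). Near the root a parent has
  many children so weights are diluted and a low cutoff (0.05) suffices;
  deeper terms have fewer siblings, so the bar rises (0.1 at depth 2, 0.2
  from depth 3 down).
* across patients, terms are ranked by their mean attention weight; terms
  with mean >= 0.15 (inclusive) form the cohort-level discriminating set.

Drug selection is an exhaustive in-silico scan: a trained regression model
predicts months-to-death for a patient paired with every retained library
drug; the argmax is the optimal drug D*, ties broken by lexicographic name.
The improvement statistics compare the predicted optimal survival with the
patient's observed survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .chem import DrugRecord
from .cohort import DAYS_PER_MONTH, ExpressionMatrix
from .vnn import AttentionReport, ModelState, forward_batch

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_ATTENTION_CUTOFFS", "DrugSelectionResult",
           "CohortImprovementSummary", "flag_discriminating_terms",
           "aggregate_attention", "select_optimal_drug",
           "cohort_improvement_stats", "nearest_patients"]

#: depth band -> strict lower cutoff on the attention weight
DEFAULT_ATTENTION_CUTOFFS = {(0, 1): 0.05, (2, 2): 0.1, (3, None): 0.2}


@dataclass
class DrugSelectionResult:
    patient_id: str
    prescribed_drug: str | None
    observed_months: float | None
    predicted_months: dict[str, float]   # drug -> positive months
    optimal_drug: str
    predicted_optimal_months: float
    improved: bool | None = None
    relative_improvement: float | None = None


@dataclass
class CohortImprovementSummary:
    fraction_with_better_alternative: float
    median_observed_months: float
    median_optimal_months: float
    fraction_relative_improvement_ge_threshold: float
    max_fold_change: float
    n_patients: int


def _cutoff_for_depth(depth: int, cutoffs: dict) -> float:
    for (lo, hi), cut in cutoffs.items():
        if depth >= lo and (hi is None or depth <= hi):
            return cut
    raise ValueError(f"no attention cutoff covers depth {depth}")


def flag_discriminating_terms(
        report: AttentionReport,
        cutoffs: dict = DEFAULT_ATTENTION_CUTOFFS) -> AttentionReport:
    """Flag terms with attention weight strictly above their depth's cutoff.

    Mutates and returns `report`. Raising a cutoff can only remove flags.
    """
    for term, w in report.weights.items():
        if term not in report.depths:
            raise ValueError(f"term {term!r} has no recorded depth")
        report.flags[term] = w > _cutoff_for_depth(report.depths[term],
                                                   cutoffs)
    return report


def aggregate_attention(reports: list[AttentionReport],
                        min_avg: float = 0.15) -> pd.DataFrame:
    """Rank terms by mean attention weight across patients.

    A term is averaged over the reports where it appears (count reported).
    Returns terms with mean weight >= `min_avg` (inclusive), sorted
    descending, as a DataFrame (term, mean_weight, n_patients, depth).
    """
    if not reports:
        raise ValueError("need at least one attention report")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    depths: dict[str, int] = {}
    for rep in reports:
        for term, w in rep.weights.items():
            sums[term] = sums.get(term, 0.0) + w
            counts[term] = counts.get(term, 0) + 1
            depths[term] = rep.depths[term]
    rows = [(t, sums[t] / counts[t], counts[t], depths[t]) for t in sums]
    df = pd.DataFrame(rows, columns=["term", "mean_weight", "n_patients",
                                     "depth"])
    df = df[df["mean_weight"] >= min_avg]
    return df.sort_values(["mean_weight", "term"],
                          ascending=[False, True]).reset_index(drop=True)


def select_optimal_drug(model: ModelState, expression: np.ndarray,
                        drug_library: dict[str, DrugRecord],
                        patient_id: str = "",
                        prescribed_drug: str | None = None,
                        observed_months: float | None = None,
                        ) -> DrugSelectionResult:
    """Exhaustively score every library drug for one patient.

    The stage-2 model predicts log months for the patient paired with each
    drug; predictions are back-transformed to months. The optimal drug
    attains the maximum, ties broken by lexicographic drug name. The
    library should already be restricted to drugs retained by the rare-drug
    filter.
    """
    if not drug_library:
        raise ValueError("drug library is empty")
    if model.stage != "stage2":
        raise ValueError("optimal-drug selection needs a stage-2 "
                         "(regression) model")
    names = sorted(drug_library)
    X = np.tile(np.asarray(expression, float), (len(names), 1))
    FP = np.stack([drug_library[n].fingerprint for n in names]).astype(float)
    log_months = forward_batch(model, X, FP, train_mode=False).data.ravel()
    months = np.exp(log_months)
    predicted = {n: float(m) for n, m in zip(names, months)}
    # max over lexicographically sorted names returns the first maximal
    # element, i.e. the lexicographically smallest among ties
    best = max(names, key=lambda n: predicted[n])
    res = DrugSelectionResult(
        patient_id=patient_id, prescribed_drug=prescribed_drug,
        observed_months=observed_months, predicted_months=predicted,
        optimal_drug=best, predicted_optimal_months=predicted[best])
    if observed_months is not None and observed_months > 0:
        res.improved = (best != prescribed_drug
                        and res.predicted_optimal_months > observed_months)
        res.relative_improvement = ((res.predicted_optimal_months
                                     - observed_months) / observed_months)
    return res


def cohort_improvement_stats(results: list[DrugSelectionResult],
                             rel_threshold: float = 0.05,
                             ) -> CohortImprovementSummary:
    """Cohort-level summary of the in-silico drug scan.

    `fraction_with_better_alternative` counts patients whose optimal drug
    differs from the prescription AND whose predicted optimal survival
    exceeds the observed survival. The optimal-months median is taken over
    max(observed, predicted optimal) per patient — a patient keeps their
    prescription when no alternative beats it. Records without positive
    observed months are excluded with a warning.
    """
    usable = []
    for r in results:
        if r.observed_months is None or r.observed_months <= 0:
            logger.warning("patient %s excluded from improvement stats: "
                           "no positive observed survival", r.patient_id)
            continue
        usable.append(r)
    if not usable:
        raise ValueError("no usable drug-selection results")
    better = [r for r in usable
              if r.optimal_drug != r.prescribed_drug
              and r.predicted_optimal_months > r.observed_months]
    observed = np.array([r.observed_months for r in usable])
    optimal = np.array([max(r.observed_months, r.predicted_optimal_months)
                        for r in usable])
    rel = np.array([(o - b) / b for o, b in zip(optimal, observed)])
    fold = np.array([r.predicted_optimal_months / r.observed_months
                     for r in usable])
    return CohortImprovementSummary(
        fraction_with_better_alternative=len(better) / len(usable),
        median_observed_months=float(np.median(observed)),
        median_optimal_months=float(np.median(optimal)),
        fraction_relative_improvement_ge_threshold=float(
            (rel >= rel_threshold).mean()),
        max_fold_change=float(fold.max()),
        n_patients=len(usable),
    )


def nearest_patients(expr: ExpressionMatrix, patient_id: str,
                     n: int = 9) -> pd.DataFrame:
    """Rank other patients by cosine similarity of unit-normalized
    transcriptomes; returns the top `n` (patient, similarity)."""
    if patient_id not in expr.sample_ids:
        raise ValueError(f"patient {patient_id!r} not in expression matrix")
    if len(expr.sample_ids) - 1 < n:
        raise ValueError(f"need at least {n} other patients")
    V = expr.values.T  # samples x genes
    norms = np.linalg.norm(V, axis=1)
    zero = np.array(expr.sample_ids)[norms == 0]
    if zero.size:
        raise ValueError(f"zero-norm expression vector(s): {zero[:5]}")
    U = V / norms[:, None]
    qi = expr.sample_ids.index(patient_id)
    sims = U @ U[qi]
    order = [i for i in np.argsort(-sims, kind="stable") if i != qi]
    top = order[:n]
    return pd.DataFrame({"patient_id": [expr.sample_ids[i] for i in top],
                         "cosine_similarity": sims[top]})
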
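"""Attention flagging/aggregation and in-silico drug selection."""

import numpy as np
import pytest

from gosurv.cohort import ExpressionMatrix
from gosurv.interpret import (DrugSelectionResult, aggregate_attention,
                              cohort_improvement_stats,
                              flag_discriminating_terms, nearest_patients,
                              select_optimal_drug)
from gosurv.vnn import AttentionReport, forward_encoder, forward_head


def report(weights, depths, patient="p"):
    return AttentionReport(patient_id=patient, weights=dict(weights),
                           depths=dict(depths),
                           activations={t: 0.0 for t in weights})


class TestFlagging:
    @pytest.mark.parametrize("depth,weight,flagged", [
        (1, 0.06, True), (1, 0.05, False),      # strict > at 0.05
        (0, 0.051, True),
        (2, 0.11, True), (2, 0.1, False),       # 0.1 band
        (3, 0.15, False), (3, 0.21, True),      # 0.2 band
        (7, 0.21, True),                        # deep terms share the band
    ])
    def test_depth_banded_cutoffs(self, depth, weight, flagged):
        rep = report({"t": weight}, {"t": depth})
        assert flag_discriminating_terms(rep).flags["t"] is flagged

    def test_singleton_weight_one_flagged_in_every_band(self):
        for depth in (0, 1, 2, 3, 9):
            rep = report({"t": 1.0}, {"t": depth})
            assert flag_discriminating_terms(rep).flags["t"]

    def test_missing_depth_is_an_error(self):
        rep = AttentionReport("p", {"t": 0.5}, {}, {})
        with pytest.raises(ValueError, match="depth"):
            flag_discriminating_terms(rep)

    def test_raising_cutoffs_never_adds_flags(self):
        rng = np.random.default_rng(0)
        terms = {f"t{i}": float(w) for i, w in
                 enumerate(rng.uniform(0, 1, 30))}
        depths = {t: int(d) for t, d in
                  zip(terms, rng.integers(0, 5, 30))}
        low = flag_discriminating_terms(report(terms, depths)).flags
        high = flag_discriminating_terms(
            report(terms, depths),
            cutoffs={(0, 1): 0.2, (2, 2): 0.3, (3, None): 0.5}).flags
        assert all(low[t] or not high[t] for t in terms)


class TestAggregation:
    def test_inclusive_threshold(self):
        reps = [report({"t": 0.2}, {"t": 1}, "p1"),
                report({"t": 0.1}, {"t": 1}, "p2")]
        table = aggregate_attention(reps, min_avg=0.15)
        assert list(table["term"]) == ["t"]  # mean exactly 0.15 kept
        assert table["mean_weight"][0] == pytest.approx(0.15)

    def test_absent_terms_averaged_over_present_reports(self):
        reps = [report({"a": 0.4, "b": 0.2}, {"a": 1, "b": 1}, "p1"),
                report({"a": 0.2}, {"a": 1}, "p2")]
        table = aggregate_attention(reps, min_avg=0.0)
        row = table.set_index("term")
        assert row.loc["a", "mean_weight"] == pytest.approx(0.3)
        assert row.loc["a", "n_patients"] == 2
        assert row.loc["b", "mean_weight"] == pytest.approx(0.2)
        assert row.loc["b", "n_patients"] == 1

    def test_zero_threshold_returns_all_sorted(self):
        reps = [report({"a": 0.1, "b": 0.5, "c": 0.3},
                       {"a": 1, "b": 1, "c": 1})]
        table = aggregate_attention(reps, min_avg=0.0)
        assert list(table["term"]) == ["b", "c", "a"]

    def test_needs_at_least_one_report(self):
        with pytest.raises(ValueError):
            aggregate_attention([], 0.15)


class TestDrugSelection:
    def test_equals_exhaustive_rescoring_oracle(self, tiny_model, toy_dag,
                                                tiny_library):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=len(toy_dag.genes()))
        res = select_optimal_drug(tiny_model, expr, tiny_library,
                                  patient_id="p")
        # oracle: score each drug through the single-sample API
        emb, _ = forward_encoder(tiny_model, expr)
        months = {}
        for name, rec in tiny_library.items():
            from gosurv.vnn import forward_drug
            demb = forward_drug(tiny_model, rec.fingerprint)
            months[name] = float(np.exp(forward_head(tiny_model, emb,
                                                     demb)))
        assert res.predicted_months == pytest.approx(months)
        assert res.optimal_drug == max(sorted(months), key=months.get)
        assert len(res.predicted_months) == len(tiny_library)

    def test_tie_breaks_lexicographically(self, tiny_model, toy_dag,
                                          tiny_library):
        # two names, same molecule -> identical predictions
        from gosurv.chem import DrugRecord, smiles_to_fingerprint
        fp = smiles_to_fingerprint("CCO", n_bits=64)
        lib = {"zeta": DrugRecord("zeta", "CCO", fp),
               "alpha": DrugRecord("alpha", "CCO", fp)}
        expr = np.zeros(len(toy_dag.genes()))
        res = select_optimal_drug(tiny_model, expr, lib)
        assert res.optimal_drug == "alpha"

    def test_needs_stage2_model_and_nonempty_library(self, tiny_model,
                                                     tiny_library, toy_dag):
        expr = np.zeros(len(toy_dag.genes()))
        with pytest.raises(ValueError, match="empty"):
            select_optimal_drug(tiny_model, expr, {})
        tiny_model.stage = "stage1"
        try:
            with pytest.raises(ValueError, match="stage-2"):
                select_optimal_drug(tiny_model, expr, tiny_library)
        finally:
            tiny_model.stage = "stage2"


def selection(pid, prescribed, observed, months):
    best = max(sorted(months), key=months.get)
    res = DrugSelectionResult(
        patient_id=pid, prescribed_drug=prescribed,
        observed_months=observed, predicted_months=months,
        optimal_drug=best, predicted_optimal_months=months[best])
    res.improved = best != prescribed and months[best] > observed
    res.relative_improvement = (months[best] - observed) / observed
    return res


class TestImprovementStats:
    def test_counts_strictly_better_different_drugs(self):
        results = [selection(f"p{i}", "a", 10.0,
                             {"a": 10.0, "b": 12.0 if i < 3 else 9.0})
                   for i in range(10)]
        s = cohort_improvement_stats(results)
        assert s.fraction_with_better_alternative == pytest.approx(0.3)

    def test_fold_change(self):
        res = [selection("p", "a", 24.7, {"a": 20.0, "b": 73.4})]
        s = cohort_improvement_stats(res)
        assert s.max_fold_change == pytest.approx(73.4 / 24.7)
        assert s.max_fold_change == pytest.approx(2.97, abs=0.01)

    def test_no_alternatives_leaves_medians_equal(self):
        res = [selection(f"p{i}", "a", 10.0 + i, {"a": 5.0})
               for i in range(5)]
        s = cohort_improvement_stats(res)
        assert s.fraction_with_better_alternative == 0.0
        assert s.median_observed_months == s.median_optimal_months

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        res = [selection(f"p{i}", "a", float(rng.uniform(5, 50)),
                         {"a": float(rng.uniform(5, 50)),
                          "b": float(rng.uniform(5, 50))})
               for i in range(20)]
        a = cohort_improvement_stats(res)
        b = cohort_improvement_stats(res[::-1])
        assert a == b

    def test_nonpositive_observed_excluded(self, caplog):
        import logging
        good = selection("p1", "a", 10.0, {"a": 11.0, "b": 9.0})
        bad = selection("p2", "a", 10.0, {"a": 5.0})
        bad.observed_months = 0.0
        with caplog.at_level(logging.WARNING):
            s = cohort_improvement_stats([good, bad])
        assert s.n_patients == 1
        assert "p2" in caplog.text


class TestNearestPatients:
    def _expr(self):
        # P0 and P1 identical direction; P2 orthogonal to P0
        values = np.array([[1.0, 2.0, 0.0, 3.0],
                           [1.0, 2.0, 0.0, 0.1],
                           [0.0, 0.0, 5.0, 2.0]])
        return ExpressionMatrix(["g1", "g2", "g3"],
                                ["P0", "P1", "P2", "P3"], values)

    def test_duplicate_direction_ranks_first_with_similarity_one(self):
        top = nearest_patients(self._expr(), "P0", n=2)
        assert top["patient_id"][0] == "P1"
        assert top["cosine_similarity"][0] == pytest.approx(1.0)

    def test_orthogonal_vector_scores_zero(self):
        top = nearest_patients(self._expr(), "P0", n=3)
        row = top.set_index("patient_id")
        assert row.loc["P2", "cosine_similarity"] == pytest.approx(0.0)

    def test_returns_n_others_self_excluded(self):
        rng = np.random.default_rng(13)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)],
            [f"P{i}" for i in range(12)],
            rng.uniform(0.1, 5, size=(5, 12)))
        top = nearest_patients(m, "P4", n=9)
        assert len(top) == 9
        assert "P4" not in set(top["patient_id"])

    def test_zero_norm_vector_is_an_error(self):
        m = ExpressionMatrix(["g1"], ["P0", "P1"],
                             np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="zero-norm"):
            nearest_patients(m, "P0", n=1)
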
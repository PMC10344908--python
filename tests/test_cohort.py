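"""Label construction, standardization, pair expansion and splitting."""

import logging
import math

import numpy as np
import pytest

from gosurv.cohort import (DAYS_PER_MONTH, ExpressionMatrix,
                           build_stage1_cohort, build_stage2_cohort,
                           days_to_log_months, expand_patient_drug_pairs,
                           log_months_to_days, read_clinical_tsv,
                           split_cohort, standardize_expression)
from tests.conftest import make_record


class TestStandardize:
    def test_zscore_values(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"],
                             np.array([[1.0, 2.0, 3.0]]))
        z = standardize_expression(m)
        np.testing.assert_allclose(z.values[0],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_gene_becomes_zero_with_warning(self, caplog):
        m = ExpressionMatrix(["g"], ["a", "b", "c"],
                             np.array([[5.0, 5.0, 5.0]]))
        with caplog.at_level(logging.WARNING):
            z = standardize_expression(m)
        np.testing.assert_array_equal(z.values[0], [0, 0, 0])
        assert "constant" in caplog.text

    def test_double_standardization_guarded(self, small_expression):
        with pytest.raises(ValueError, match="already standardized"):
            standardize_expression(small_expression)

    def test_rows_have_zero_mean_unit_sd(self, small_expression):
        assert np.allclose(small_expression.values.mean(axis=1), 0,
                           atol=1e-9)
        assert np.allclose(small_expression.values.std(axis=1), 1,
                           atol=1e-6)


class TestStage1Labels:
    @pytest.mark.parametrize("death,expected", [(999, 0), (1250, 1)])
    def test_deceased_threshold_sides(self, death, expected):
        cohort = build_stage1_cohort([make_record("p", death=death)])
        assert [(r.patient_id, y) for r, y in cohort] == [("p", expected)]

    def test_deceased_between_thresholds_excluded(self):
        assert build_stage1_cohort([make_record("p", death=1100)]) == []

    @pytest.mark.parametrize("follow,n", [(1201, 1), (800, 0)])
    def test_censored_lower_bound(self, follow, n):
        recs = [make_record("p", "alive_or_censored", follow=follow)]
        cohort = build_stage1_cohort(recs)
        assert len(cohort) == n
        if cohort:
            assert cohort[0][1] == 1  # follow-up is a survival lower bound

    def test_empty_records_warns_not_raises(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert build_stage1_cohort([]) == []
        assert "empty" in caplog.text

    def test_threshold_order_validated(self):
        with pytest.raises(ValueError):
            build_stage1_cohort([make_record("p", death=1.0)],
                                short_max_days=1300, long_min_days=1200)


class TestStage2Labels:
    def test_deceased_gets_log_months_label(self):
        cohort = build_stage2_cohort([make_record("p", death=913.125)])
        assert cohort[0][1] == pytest.approx(math.log(30.0))

    def test_censored_excluded(self):
        recs = [make_record("p", "alive_or_censored", follow=5000)]
        assert build_stage2_cohort(recs) == []

    def test_zero_day_death_excluded_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert build_stage2_cohort([make_record("p", death=0)]) == []
        assert "p" in caplog.text


class TestLogMonths:
    def test_one_month_is_zero(self):
        assert days_to_log_months(DAYS_PER_MONTH) == 0.0

    def test_thirty_months(self):
        assert days_to_log_months(913.125) == pytest.approx(math.log(30))

    @pytest.mark.parametrize("days", [1.0, 30.4375, 999.9, 123456.0])
    def test_round_trip(self, days):
        assert log_months_to_days(days_to_log_months(days)) == \
            pytest.approx(days, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            days_to_log_months(0)


class TestPairExpansion:
    def test_multi_drug_patient_shares_expression(self, tiny_library,
                                                  small_expression):
        cohort = [(make_record("P0", death=100,
                               drugs=["apixol", "benzem"]), 0.5)]
        ex = expand_patient_drug_pairs(cohort, tiny_library,
                                       small_expression)
        assert len(ex) == 2
        assert ex[0].expression is ex[1].expression
        assert {e.drug_name for e in ex} == {"apixol", "benzem"}

    def test_unknown_drug_dropped(self, tiny_library, small_expression):
        cohort = [(make_record("P0", death=100, drugs=["nosuch"]), 0.5)]
        assert expand_patient_drug_pairs(cohort, tiny_library,
                                         small_expression) == []

    def test_single_drug_single_example(self, tiny_library,
                                        small_expression):
        cohort = [(make_record("P1", death=100, drugs=["cyclor"]), 1.0)]
        ex = expand_patient_drug_pairs(cohort, tiny_library,
                                       small_expression)
        assert len(ex) == 1 and ex[0].label == 1.0


class TestSplit:
    def _examples(self, n_patients, tiny_library, small_expression=None):
        import numpy as np
        rng = np.random.default_rng(3)
        from gosurv.cohort import TrainingExample
        fp = next(iter(tiny_library.values())).fingerprint
        out = []
        for i in range(n_patients):
            label = float(i % 2)
            for d in (["apixol", "benzem"] if i % 3 == 0 else ["apixol"]):
                out.append(TrainingExample(f"P{i}", rng.normal(size=4),
                                           fp, d, label))
        return out

    def test_split_is_by_patient(self, tiny_library):
        ex = self._examples(10, tiny_library)
        tr, va = split_cohort(ex, 0.2, seed=5)
        assert {e.patient_id for e in tr} & {e.patient_id for e in va} \
            == set()
        assert len(tr) + len(va) == len(ex)

    def test_deterministic_given_seed(self, tiny_library):
        ex = self._examples(12, tiny_library)
        a = split_cohort(ex, 0.25, seed=9)
        b = split_cohort(ex, 0.25, seed=9)
        assert [e.patient_id for e in a[1]] == [e.patient_id for e in b[1]]

    def test_stratified_within_one_patient(self, tiny_library):
        ex = self._examples(20, tiny_library)
        _, va = split_cohort(ex, 0.2, seed=2)
        val_patients = {e.patient_id: e.label for e in va}
        counts = {0.0: 0, 1.0: 0}
        for lab in val_patients.values():
            counts[lab] += 1
        assert abs(counts[0.0] - counts[1.0]) <= 1

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, tiny_library, frac):
        ex = self._examples(4, tiny_library)
        with pytest.raises(ValueError):
            split_cohort(ex, frac, seed=0)


def test_clinical_tsv_round_trip(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "patient_id\tvital_status\tdays_to_death\tdays_to_last_followup"
        "\tdrugs\n"
        "P0\tdeceased\t500\t\tdrugA;drugB\n"
        "P1\talive_or_censored\t\t1300.5\tdrugA\n")
    records = read_clinical_tsv(str(path))
    assert records[0].days_to_death == 500
    assert records[0].drugs == ("drugA", "drugB")
    assert records[1].days_to_last_followup == 1300.5
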
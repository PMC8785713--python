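"""Logistic fits, AUC, Nagelkerke R^2, DeLong, LRT, trend test, severity."""

import numpy as np
import pandas as pd
import pytest

from taigrade.cohort import PatientRecord
from taigrade.evaluation import (
    auc_roc,
    cochran_armitage_trend,
    compare_grading_systems,
    delong_test,
    delong_variance,
    fit_logistic,
    fit_null,
    likelihood_ratio_test,
    nagelkerke_r2,
    percentage,
    render_severity_table,
    severity_table,
)
from taigrade.grading import grades_wide
from taigrade.io import cohort_to_frame
from taigrade.lesions import LesionMap, LesionSite

from .oracles import pairwise_auc

from taigrade.evaluation import _midrank_placements


def _frame_with_outcome(n_unfav, n_fav, rng=None):
    n = n_unfav + n_fav
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "unfavorable": [1] * n_unfav + [0] * n_fav,
            "age": rng.uniform(15, 82, n),
            "gcs": rng.integers(3, 16, n),
            "pupils": rng.choice(
                ["responsive", "unilaterally_unresponsive", "bilaterally_unresponsive"], n
            ),
        }
    )


class TestPercentage:
    def test_round_trip_fraction(self):
        assert percentage(183, 351, 1) == 52.1
        with pytest.raises(ValueError):
            percentage(1, 0)


class TestFitLogistic:
    def test_intercept_only_probability_equals_prevalence(self):
        frame = _frame_with_outcome(183, 168)
        null = fit_null(frame)
        assert np.allclose(null.fitted_probs, 183 / 351)
        assert null.aic == pytest.approx(2 - 2 * null.log_likelihood)

    def test_adding_a_predictor_never_decreases_loglik(self):
        frame = _frame_with_outcome(120, 140)
        small = fit_logistic(frame, ["age"])
        big = fit_logistic(frame, ["age", "gcs"])
        assert big.log_likelihood >= small.log_likelihood - 1e-8

    def test_pupils_expand_to_two_indicators(self):
        frame = _frame_with_outcome(50, 50)
        m = fit_logistic(frame, ["pupils"])
        assert m.n_params == 3  # intercept + 2 levels

    def test_single_class_outcome_rejected(self):
        frame = _frame_with_outcome(10, 0)
        with pytest.raises(ValueError):
            fit_logistic(frame, ["age"])

    def test_perfect_separation_falls_back_with_warning(self):
        frame = _frame_with_outcome(30, 30)
        frame["sep"] = frame["unfavorable"] * 10.0  # perfectly separating
        with pytest.warns(RuntimeWarning):
            m = fit_logistic(frame, ["sep"])
        assert m.separation_flag
        assert np.isfinite(m.log_likelihood)


class TestAUC:
    def test_tied_pair_toy_example(self):
        assert auc_roc([2, 3, 1, 2], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_perfect_and_null_scores(self):
        assert auc_roc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 10_000)
        assert abs(auc_roc(rng.random(10_000), labels) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([1, 2], [1, 1])

    def test_matches_pairwise_count_oracle_on_small_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 6, n).astype(float)  # integer scores force ties
            assert auc_roc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        frame = _frame_with_outcome(80, 90)
        null = fit_null(frame)
        assert nagelkerke_r2(null, null.log_likelihood) == 0.0

    def test_hand_worked_case(self):
        m = type("M", (), {"log_likelihood": -2.0, "n": 4})
        assert nagelkerke_r2(m, 4 * np.log(0.5)) == pytest.approx(0.4272, abs=5e-5)

    def test_saturated_fit_approaches_one(self):
        m = type("M", (), {"log_likelihood": -1e-9, "n": 50})
        assert nagelkerke_r2(m, 50 * np.log(0.5)) == pytest.approx(1.0, abs=1e-6)

    def test_model_below_null_rejected(self):
        m = type("M", (), {"log_likelihood": -10.0, "n": 4})
        with pytest.raises(ValueError):
            nagelkerke_r2(m, -1.0)

    def test_bounded_on_fitted_models(self):
        frame = _frame_with_outcome(100, 120)
        null = fit_null(frame)
        for preds in (["age"], ["age", "gcs", "pupils"]):
            r2 = nagelkerke_r2(fit_logistic(frame, preds), null.log_likelihood)
            assert 0.0 <= r2 <= 1.0


class TestDeLong:
    def _paired_scores(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * (n // 3) + [0] * (n - n // 3))
        signal = labels + rng.normal(0, 1, n)
        a = signal + rng.normal(0, 0.5, n)
        b = signal + rng.normal(0, 0.8, n)
        return a, b, labels

    def test_identical_scores_give_unit_p(self):
        a, _, labels = self._paired_scores()
        with pytest.warns(RuntimeWarning):
            z, p, auc_a, auc_b = delong_test(a, a, labels)
        assert (z, p) == (0.0, 1.0)
        assert auc_a == auc_b

    def test_returned_aucs_match_auc_roc(self):
        a, b, labels = self._paired_scores(3)
        _, _, auc_a, auc_b = delong_test(a, b, labels)
        assert auc_a == pytest.approx(auc_roc(a, labels))
        assert auc_b == pytest.approx(auc_roc(b, labels))

    def test_mismatched_lengths_rejected(self):
        a, b, labels = self._paired_scores()
        with pytest.raises(ValueError):
            delong_test(a[:-1], b, labels)

    def test_variance_reduces_to_hanley_mcneil_without_ties(self):
        """Single-curve DeLong variance equals the Hanley-McNeil formula
        with U-statistic plug-ins for Q1/Q2, at large per-class counts."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = int(rng.integers(800, 1200))
            n = int(rng.integers(800, 1200))
            scores = np.concatenate([rng.normal(0.8, 1, m), rng.normal(0, 1, n)])
            labels = np.concatenate([np.ones(m, int), np.zeros(n, int)])
            v10, v01, A = _midrank_placements(scores, labels)
            k, l = n * v10, m * v01
            q2 = np.sum(k * (k - 1)) / (m * n * (n - 1))
            q1 = np.sum(l * (l - 1)) / (n * m * (m - 1))
            hm = (A * (1 - A) + (m - 1) * (q1 - A**2) + (n - 1) * (q2 - A**2)) / (m * n)
            assert abs(delong_variance(scores, labels) - hm) < 1e-6


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        frame = _frame_with_outcome(60, 70)
        m = fit_logistic(frame, ["age"])
        assert likelihood_ratio_test(m, m) == (0.0, 0, 1.0)

    def test_non_nested_models_rejected(self):
        frame = _frame_with_outcome(60, 70)
        a = fit_logistic(frame, ["age"])
        b = fit_logistic(frame, ["gcs"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    def test_informative_predictor_detected(self, small_cohort):
        frame = cohort_to_frame(small_cohort).merge(
            grades_wide(small_cohort), on="patient_id"
        )
        nested = fit_logistic(frame, ["age", "gcs", "pupils"])
        full = fit_logistic(frame, ["age", "gcs", "pupils", "grade_stockholm"])
        stat, df, p = likelihood_ratio_test(nested, full)
        assert df == 1 and stat > 0 and p < 0.001


class TestCochranArmitage:
    def test_flat_outcome_distribution_gives_near_zero_statistic(self):
        table = np.array([[30, 30, 30], [70, 70, 70]])
        z, p = cochran_armitage_trend(table, [0, 1, 2])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_reversing_category_order_flips_the_sign(self):
        table = np.array([[10, 20, 35], [40, 30, 15]])
        z1, p1 = cochran_armitage_trend(table, [0, 1, 2])
        z2, p2 = cochran_armitage_trend(table[:, ::-1], [0, 1, 2])
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage_trend(np.array([[0, 5], [0, 5]]), [0, 1])


def _hand_cohort():
    """Ten hand-written patients for a manual severity tally."""
    teg_susc = LesionSite("midbrain", "tegmentum", "unilateral", "susceptibility")
    pons_bi_flair = LesionSite("pons", "unspecified", "bilateral", "flair")
    pons_uni_flair = LesionSite("pons", "unspecified", "unilateral", "flair")
    splenium_dwi = LesionSite("corpus_callosum", "splenium", "not_applicable", "dwi")
    maps_and_gos = [
        (LesionMap([teg_susc]), 3),
        (LesionMap([teg_susc]), 2),
        (LesionMap([teg_susc, splenium_dwi]), 4),
        (LesionMap([pons_bi_flair]), 1),
        (LesionMap([pons_bi_flair]), 3),
        (LesionMap([pons_uni_flair]), 4),
        (LesionMap([splenium_dwi]), 2),
        (LesionMap(), 5),
        (LesionMap(), 3),
        (LesionMap(), 4),
    ]
    return [
        PatientRecord(
            patient_id=f"H{i}", age=40.0, gcs=6, pupils="responsive",
            rotterdam=3, scan_delay=4, lesions=m, gos=g,
        )
        for i, (m, g) in enumerate(maps_and_gos)
    ]


class TestSeverityTable:
    def test_hand_tally(self):
        table = severity_table(_hand_cohort()).set_index(["sequence", "lesion_type"])
        teg = table.loc[("susceptibility", "midbrain_tegmentum")]
        assert teg["n"] == 3
        assert teg["pct_unfavorable"] == pytest.approx(100 * 2 / 3)
        pons_bi = table.loc[("flair", "pons_bilateral")]
        assert pons_bi["n"] == 2 and pons_bi["pct_unfavorable"] == 100.0
        cc = table.loc[("dwi", "corpus_callosum_splenium")]
        assert cc["n"] == 2 and cc["pct_unfavorable"] == 50.0
        no_dwi = table.loc[("dwi", "no_detected_tai")]
        assert no_dwi["n"] == 8

    def test_zero_count_cells_render_as_dash(self):
        table = severity_table(_hand_cohort())
        empty = table[(table["sequence"] == "dwi") & (table["lesion_type"] == "pons_ventral")]
        assert empty["n"].item() == 0 and np.isnan(empty["pct_unfavorable"].item())
        rendered = render_severity_table(table)
        assert "-" in set(rendered["pct_unfavorable"])

    def test_bilateral_pons_more_severe_than_unilateral(self, ref_cohort):
        table = severity_table(ref_cohort).set_index(["sequence", "lesion_type"])
        for seq in ("dwi", "flair", "susceptibility"):
            bi = table.loc[(seq, "pons_bilateral"), "pct_unfavorable"]
            uni = table.loc[(seq, "pons_unilateral"), "pct_unfavorable"]
            assert bi > uni


@pytest.fixture(scope="module")
def graded_frame(small_cohort):
    return cohort_to_frame(small_cohort).merge(grades_wide(small_cohort), on="patient_id")


class TestCompareGradingSystems:

    def test_fifteen_models_reported(self, graded_frame):
        comp = compare_grading_systems(graded_frame)
        assert len(comp.models) == 15
        assert comp.models["pseudo_r2"].between(0, 1).all()
        assert np.isfinite(comp.models["aic"]).all()
        assert len(comp.delong) == 6  # pairwise among 4 univariate models

    def test_row_order_invariance(self, graded_frame):
        comp_a = compare_grading_systems(graded_frame)
        shuffled = graded_frame.sample(frac=1.0, random_state=1)
        comp_b = compare_grading_systems(shuffled)
        pd.testing.assert_frame_equal(comp_a.models, comp_b.models)

    def test_missing_grade_columns_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            compare_grading_systems(cohort_to_frame(small_cohort))
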
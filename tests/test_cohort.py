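"""Synthetic cohort generator: determinism, calibration, coupling, decay."""

import numpy as np
import pandas as pd
import pytest

from taigrade.cohort import (
    CohortConfig,
    apply_detectability_decay,
    generate_cohort,
    inject_missingness,
    sample_outcome,
)
from taigrade.grading import grade_stockholm
from taigrade.lesions import LesionMap, LesionSite


def _grade_frame(cohort):
    return pd.DataFrame(
        {
            "grade": [grade_stockholm(r.lesions).grade for r in cohort],
            "unfavorable": [r.unfavorable for r in cohort],
            "gcs": [r.gcs for r in cohort],
        }
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_patients=0),
            dict(tai_prevalence_target=1.5),
            dict(tai_prevalence_target=float("nan")),
            dict(missingness_rate=1.0),
            dict(grade_outcome_probs={1: 0.28, 2: 0.4, 3: 0.74, 4: 1.5}),
            dict(detectability_decay={"dwi": -0.1, "flair": 0.9, "susceptibility": 0.99}),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestGenerateCohort:
    def test_identical_seed_gives_identical_cohort(self):
        cfg = CohortConfig(n_patients=300, seed=42)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_patients=300, seed=1))
        b = generate_cohort(CohortConfig(n_patients=300, seed=2))
        assert a != b

    def test_zero_prevalence_target_gives_lesion_free_grade_one_cohort(self):
        cohort = generate_cohort(CohortConfig(n_patients=200, seed=0, tai_prevalence_target=0.0))
        assert all(len(r.lesions) == 0 for r in cohort)
        assert all(grade_stockholm(r.lesions).grade == 1 for r in cohort)

    def test_tai_prevalence_recovers_target(self, ref_cohort):
        prev = np.mean([len(r.lesions) > 0 for r in ref_cohort])
        assert abs(prev - 0.73) <= 0.02

    def test_overall_unfavorable_fraction_matches_reference_cohort(self, ref_cohort):
        # 183 unfavorable of 351 in the reference outcome distribution
        unf = np.mean([r.unfavorable for r in ref_cohort])
        assert abs(unf - 183 / 351) <= 0.02

    def test_grade_conditional_outcomes_within_binomial_tolerance(self, ref_cohort):
        df = _grade_frame(ref_cohort)
        targets = {1: 0.28, 2: 0.40, 3: 0.74, 4: 0.97}
        for g, group in df.groupby("grade"):
            p = targets[g]
            se = np.sqrt(p * (1 - p) / len(group))
            assert abs(group["unfavorable"].mean() - p) <= 2 * se + 1e-9, g

    def test_unfavorable_proportion_monotone_in_grade(self, ref_cohort):
        means = _grade_frame(ref_cohort).groupby("grade")["unfavorable"].mean()
        assert list(means.index) == [1, 2, 3, 4]
        assert means.is_monotonic_increasing

    def test_mean_gcs_strictly_decreases_with_grade(self, ref_cohort):
        means = _grade_frame(ref_cohort).groupby("grade")["gcs"].mean()
        assert all(np.diff(means.to_numpy()) < 0)

    def test_covariate_marginals_match_reference_distribution(self, ref_cohort):
        ages = np.array([r.age for r in ref_cohort])
        gcs = np.array([r.gcs for r in ref_cohort])
        assert 15 <= ages.min() and ages.max() <= 82
        assert abs(ages.mean() - 43.8) < 1.0
        assert np.median(gcs) == 4
        assert all(0 <= r.scan_delay <= 28 for r in ref_cohort)
        assert all(1 <= r.rotterdam <= 6 for r in ref_cohort)


class TestSampleOutcome:
    def test_rejects_out_of_range_grade(self):
        cfg = CohortConfig()
        with pytest.raises(ValueError):
            sample_outcome(0, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_outcome(5, cfg, np.random.default_rng(0))

    def test_zero_probability_grade_is_always_favorable(self):
        cfg = CohortConfig(grade_outcome_probs={1: 0.0, 2: 0.4, 3: 0.74, 4: 0.97})
        rng = np.random.default_rng(1)
        assert all(sample_outcome(1, cfg, rng) >= 4 for _ in range(500))

    def test_unfavorable_rate_tracks_grade_probability(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(7)
        draws = np.array([sample_outcome(4, cfg, rng) for _ in range(4000)])
        assert abs(np.mean(draws <= 3) - 0.97) < 0.012

    def test_gos_levels_split_within_halves(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(3)
        draws = np.array([sample_outcome(2, cfg, rng) for _ in range(4000)])
        assert set(draws) <= {1, 2, 3, 4, 5}
        unfav = draws[draws <= 3]
        # GOS 3 dominates the unfavorable half (136 of 183)
        assert np.mean(unfav == 3) > 0.6


class TestDetectabilityDecay:
    def _map(self):
        return LesionMap(
            [
                LesionSite("subcortical", "unspecified", "unilateral", "dwi"),
                LesionSite("subcortical", "unspecified", "bilateral", "flair"),
                LesionSite("thalamus", "unspecified", "unilateral", "susceptibility"),
            ]
        )

    def test_no_delay_keeps_everything(self):
        cfg = CohortConfig()
        out = apply_detectability_decay(self._map(), 0, cfg, np.random.default_rng(0))
        assert out == self._map()

    def test_unit_retention_keeps_everything_at_any_delay(self):
        cfg = CohortConfig(detectability_decay={"dwi": 1.0, "flair": 1.0, "susceptibility": 1.0})
        out = apply_detectability_decay(self._map(), 28, cfg, np.random.default_rng(0))
        assert out == self._map()

    def test_output_always_subset_of_input(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        for delay in (1, 7, 28):
            out = apply_detectability_decay(self._map(), delay, cfg, rng)
            assert out <= self._map()

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            apply_detectability_decay(self._map(), -1, CohortConfig(), np.random.default_rng(0))

    def test_dwi_fades_faster_than_susceptibility(self):
        """Monte-Carlo: late scans lose DWI lesions at a higher relative rate."""
        cfg = CohortConfig()
        m = self._map()
        rng = np.random.default_rng(11)
        kept = {1: {"dwi": 0, "susceptibility": 0}, 28: {"dwi": 0, "susceptibility": 0}}
        n = 5000
        for delay in (1, 28):
            for _ in range(n):
                out = apply_detectability_decay(m, delay, cfg, rng)
                for s in out:
                    if s.sequence in kept[delay]:
                        kept[delay][s.sequence] += 1
        assert kept[28]["dwi"] < kept[1]["dwi"]
        rel_dwi = kept[28]["dwi"] / kept[1]["dwi"]
        rel_susc = kept[28]["susceptibility"] / kept[1]["susceptibility"]
        assert rel_susc > rel_dwi


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, small_cohort):
        out = inject_missingness(small_cohort, 0.0, np.random.default_rng(0))
        assert out == list(small_cohort)

    def test_rate_one_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            inject_missingness(small_cohort, 1.0, np.random.default_rng(0))

    def test_masked_fraction_matches_rate(self, ref_cohort):
        out = inject_missingness(ref_cohort, 0.04, np.random.default_rng(8))
        cells = np.array(
            [[r.age is None, r.gcs is None, r.pupils is None, r.rotterdam is None] for r in out]
        )
        assert abs(cells.mean() - 0.04) <= 0.005

    def test_outcome_and_lesions_never_masked(self, small_cohort):
        out = inject_missingness(small_cohort, 0.5, np.random.default_rng(1))
        for orig, masked in zip(small_cohort, out):
            assert masked.gos == orig.gos
            assert masked.lesions == orig.lesions
            assert masked.scan_delay == orig.scan_delay
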
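"""Age-model construction, prediction, OLS fitting and cohort splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snapage import (
    AgeModel,
    Cohort,
    CohortSample,
    InsufficientDataError,
    LOCUS_ORDER,
    MissingPredictorError,
    SingularFitError,
    fit_age_model,
    predict_age,
    predict_cohort,
    published_model,
    split_cohort,
)

from conftest import make_profile

PUBLISHED_COEFFS = {
    "ELOVL2": 50.04231273,
    "FHL2": -11.16979445,
    "KLF14": 73.87032325,
    "C1orf132": -49.27304295,
    "TRIM59": 84.17900486,
}
PUBLISHED_INTERCEPT = 13.96381427


def normal_equations_oracle(design, ages):
    """Brute-force OLS via the normal equations X'X b = X'y."""
    xtx = design.T @ design
    return np.linalg.solve(xtx, design.T @ ages)


def cohort_from_matrix(levels, ages):
    samples = tuple(
        CohortSample(f"S{i}", float(age), make_profile(row, f"S{i}"))
        for i, (row, age) in enumerate(zip(levels, ages))
    )
    return Cohort(samples)


class TestPublishedModel:
    def test_constants_are_verbatim(self):
        model = published_model()
        assert model.intercept == PUBLISHED_INTERCEPT
        for locus, coeff in PUBLISHED_COEFFS.items():
            assert model.coefficient(locus) == coeff
        assert model.locus_order == LOCUS_ORDER
        assert model.provenance == "paper-published"

    def test_zero_profile_predicts_the_intercept(self):
        assert predict_age(published_model(), make_profile([0] * 5)) == PUBLISHED_INTERCEPT

    def test_all_ones_profile_sums_the_six_constants(self):
        # independent hand addition of the six printed constants
        assert predict_age(published_model(), make_profile([1] * 5)) == pytest.approx(
            161.61261771, abs=1e-9
        )

    def test_single_locus_contrasts_return_the_coefficients(self):
        model = published_model()
        base = predict_age(model, make_profile([0] * 5))
        for i, locus in enumerate(LOCUS_ORDER):
            unit = [0.0] * 5
            unit[i] = 1.0
            contrast = predict_age(model, make_profile(unit)) - base
            assert contrast == pytest.approx(PUBLISHED_COEFFS[locus], abs=1e-9)
        assert predict_age(model, make_profile([1, 0, 0, 0, 0])) == pytest.approx(
            64.00612700, abs=1e-9
        )


class TestPredictAge:
    def test_missing_locus_names_the_predictor(self):
        profile = make_profile({l: 0.5 for l in LOCUS_ORDER if l != "KLF14"})
        with pytest.raises(MissingPredictorError, match="KLF14"):
            predict_age(published_model(), profile)

    def test_output_is_not_clamped(self):
        high = make_profile({l: (1.0 if l in ("ELOVL2", "KLF14", "TRIM59") else 0.0) for l in LOCUS_ORDER})
        assert predict_age(published_model(), high) > 120

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_prediction_is_affine_in_the_profile(self, lam):
        model = published_model()
        p = make_profile([0.6, 0.3, 0.1, 0.5, 0.35])
        q = make_profile([0.4, 0.25, 0.2, 0.4, 0.3])
        mix = make_profile(
            [
                lam * p.level(l) + (1 - lam) * q.level(l)
                for l in LOCUS_ORDER
            ]
        )
        expected = lam * predict_age(model, p) + (1 - lam) * predict_age(model, q)
        assert predict_age(model, mix) == pytest.approx(expected, abs=1e-9)


class TestFitAgeModel:
    def test_matches_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(10, 51))
            levels = rng.uniform(0, 1, size=(n, 5))
            ages = rng.uniform(20, 80, size=n)
            fitted = fit_age_model(cohort_from_matrix(levels, ages))
            design = np.column_stack([np.ones(n), levels])
            beta = normal_equations_oracle(design, ages)
            assert fitted.intercept == pytest.approx(beta[0], rel=1e-8)
            for locus, ref in zip(LOCUS_ORDER, beta[1:]):
                assert fitted.coefficient(locus) == pytest.approx(ref, rel=1e-8)

    def test_recovers_generating_model_from_noiseless_data(self):
        rng = np.random.default_rng(11)
        levels = rng.uniform(0, 1, size=(10, 5))
        truth = published_model()
        ages = np.array(
            [predict_age(truth, make_profile(row)) for row in levels]
        )
        fitted = fit_age_model(cohort_from_matrix(levels, ages))
        assert fitted.intercept == pytest.approx(truth.intercept, abs=1e-8)
        for locus in LOCUS_ORDER:
            assert fitted.coefficient(locus) == pytest.approx(
                truth.coefficient(locus), abs=1e-8
            )

    def test_training_residuals_sum_to_zero(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(0, 1, size=(30, 5))
        ages = rng.uniform(23, 70, size=30)
        cohort = cohort_from_matrix(levels, ages)
        fitted = fit_age_model(cohort)
        predictions = predict_cohort(fitted, cohort)
        residuals = predictions["age_years"] - predictions["predicted_age_years"]
        assert abs(residuals.sum()) < 1e-8 * len(cohort)

    def test_six_samples_are_insufficient(self):
        rng = np.random.default_rng(1)
        cohort = cohort_from_matrix(rng.uniform(0, 1, (6, 5)), rng.uniform(23, 70, 6))
        with pytest.raises(InsufficientDataError):
            fit_age_model(cohort)

    def test_duplicated_locus_column_is_singular(self):
        rng = np.random.default_rng(2)
        levels = rng.uniform(0, 1, size=(20, 5))
        levels[:, 1] = levels[:, 0]  # FHL2 duplicates ELOVL2 exactly
        cohort = cohort_from_matrix(levels, rng.uniform(23, 70, 20))
        with pytest.raises(SingularFitError):
            fit_age_model(cohort)

    def test_incomplete_profiles_are_excluded(self):
        rng = np.random.default_rng(4)
        levels = rng.uniform(0, 1, size=(12, 5))
        ages = rng.uniform(23, 70, size=12)
        samples = list(cohort_from_matrix(levels, ages).samples)
        samples[0] = CohortSample(
            "S_incomplete", 40.0, make_profile({"ELOVL2": 0.5}, "S_incomplete")
        )
        fitted = fit_age_model(Cohort(tuple(samples)))
        assert "n=11" in fitted.provenance


class TestSplitCohort:
    @staticmethod
    def _cohort(n):
        rng = np.random.default_rng(9)
        return cohort_from_matrix(rng.uniform(0, 1, (n, 5)), rng.uniform(23, 70, n))

    def test_sixty_samples_split_thirty_thirty(self):
        cohort = self._cohort(60)
        train, test = split_cohort(cohort, 0.5, seed=123)
        assert len(train) == 30 and len(test) == 30
        ids = {s.sample_id for s in train} | {s.sample_id for s in test}
        assert len(ids) == 60  # disjoint and exhaustive

    def test_same_seed_reproduces_the_partition(self):
        cohort = self._cohort(60)
        first = split_cohort(cohort, 0.5, seed=5)
        second = split_cohort(cohort, 0.5, seed=5)
        assert [s.sample_id for s in first[0]] == [s.sample_id for s in second[0]]
        different = split_cohort(cohort, 0.5, seed=6)
        assert [s.sample_id for s in first[0]] != [s.sample_id for s in different[0]]

    def test_odd_cohort_rounds_training_up(self):
        train, test = split_cohort(self._cohort(5), 0.5, seed=0)
        assert (len(train), len(test)) == (3, 2)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(self._cohort(4), 1.0, seed=0)

    def test_stratified_split_balances_ages(self):
        cohort = self._cohort(60)
        train, test = split_cohort(cohort, 0.5, seed=1, stratify_by_age=True)
        assert len(train) == 30 and len(test) == 30
        assert abs(train.ages().mean() - test.ages().mean()) < 5.0


class TestModelSerialization:
    def test_json_round_trip_is_bit_exact(self, tmp_path):
        model = published_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = AgeModel.from_json(path)
        assert loaded == model

    def test_fitted_model_round_trips(self, tmp_path):
        rng = np.random.default_rng(12)
        cohort = cohort_from_matrix(rng.uniform(0, 1, (15, 5)), rng.uniform(23, 70, 15))
        fitted = fit_age_model(cohort)
        loaded = AgeModel.from_json(fitted.to_json())
        assert loaded.intercept == fitted.intercept
        assert dict(loaded.coefficients) == dict(fitted.coefficients)

    def test_coefficients_must_match_locus_order(self):
        with pytest.raises(ValueError):
            AgeModel(intercept=0.0, coefficients={"ELOVL2": 1.0})
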
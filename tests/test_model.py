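"""Exponential reference model: fitting, prediction, splits, CV, oracles."""

import numpy as np
import pytest
from sklearn.base import clone

from lungref import (
    PORCINE_REFERENCE,
    CohortSpec,
    ExponentialIndexRegressor,
    ExponentialModel,
    PigRecord,
    SplitSpec,
    cross_validate,
    evaluate,
    fit_exponential,
    generate_cohort,
    predict_lung_weight,
    predict_lwi,
    split_cohort,
)


def grid_search_fit(bw, lwi, center, half_width=(0.05, 0.005), n_grid=201):
    """Brute-force oracle: minimize squared log10 error on a fine 2-D grid
    of (log10 a, b) around ``center``; independent of the OLS path."""
    log_lwi = np.log10(lwi)
    i0, s0 = center
    intercepts = np.linspace(i0 - half_width[0], i0 + half_width[0], n_grid)
    slopes = np.linspace(s0 - half_width[1], s0 + half_width[1], n_grid)
    best, best_sse = None, np.inf
    for ic in intercepts:
        pred = ic + np.outer(slopes, bw)
        sse = ((log_lwi - pred) ** 2).sum(axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best_sse:
            best_sse, best = sse[j], (ic, slopes[j])
    return best


class TestExponentialModel:
    def test_reference_prediction_at_20_and_40_kg(self, reference_model):
        assert reference_model.predict_lwi(20) == pytest.approx(15.8, abs=0.05)
        assert reference_model.predict_lwi(40) == pytest.approx(9.5, abs=0.05)
        assert predict_lung_weight(reference_model, 20) == pytest.approx(316, abs=1)
        assert predict_lung_weight(reference_model, 40) == pytest.approx(381, abs=1)

    def test_flat_model_weight_is_linear_in_bw(self):
        flat = ExponentialModel(a=12.0, b=0.0)
        for bw in (5.0, 20.0, 37.5):
            assert flat.predict_lung_weight(bw) == pytest.approx(12.0 * bw)

    def test_non_positive_bw_rejected(self, reference_model):
        with pytest.raises(ValueError):
            predict_lwi(reference_model, 0.0)
        with pytest.raises(ValueError):
            reference_model.predict_lung_weight(-3.0)

    def test_non_positive_prefactor_rejected(self):
        with pytest.raises(ValueError):
            ExponentialModel(a=-1.0, b=0.0)

    def test_strictly_decreasing_when_b_negative(self, reference_model):
        grid = np.linspace(16.0, 52.0, 200)
        pred = reference_model.predict_lwi(grid)
        assert np.all(np.diff(pred) < 0)


class TestRegressorFit:
    def test_noiseless_cohort_recovers_generating_parameters(self, noiseless_cohort):
        fit = fit_exponential(noiseless_cohort)
        assert fit.model.a == pytest.approx(26.26, rel=1e-6)
        assert fit.model.b == pytest.approx(-0.011, abs=1e-9)
        assert fit.rmse_log10 == pytest.approx(0.0, abs=1e-12)

    def test_three_points_on_curve_fit_exactly(self, reference_model):
        records = [
            PigRecord(f"p{i}", bw, reference_model.predict_lung_weight(bw))
            for i, bw in enumerate([18.0, 30.0, 45.0])
        ]
        fit = fit_exponential(records)
        assert fit.rmse_log10 == pytest.approx(0.0, abs=1e-10)
        assert fit.mae_log10 == pytest.approx(0.0, abs=1e-10)

    def test_too_few_records_rejected(self, reference_model):
        records = [PigRecord("a", 20.0, 300.0), PigRecord("b", 30.0, 330.0)]
        with pytest.raises(ValueError, match="3"):
            fit_exponential(records)

    def test_identical_body_weights_singular(self):
        records = [PigRecord(str(i), 25.0, 300.0 + i) for i in range(5)]
        with pytest.raises(ValueError, match="singular|identical"):
            fit_exponential(records)

    def test_ci_band_brackets_point_model(self, noisy_cohort):
        fit = fit_exponential(noisy_cohort)
        grid = np.linspace(16.0, 52.0, 100)
        assert np.all(fit.band_upper.predict_lwi(grid) >= fit.model.predict_lwi(grid))
        assert np.all(fit.band_lower.predict_lwi(grid) <= fit.model.predict_lwi(grid))

    def test_scaling_lung_weights_scales_a_only(self, noisy_cohort):
        fit0 = fit_exponential(noisy_cohort)
        scaled = [
            PigRecord(r.animal_id, r.body_weight, 3.0 * r.lung_weight, r.method)
            for r in noisy_cohort
        ]
        fit3 = fit_exponential(scaled)
        assert fit3.model.a == pytest.approx(3.0 * fit0.model.a, rel=1e-9)
        assert fit3.model.b == pytest.approx(fit0.model.b, abs=1e-12)

    def test_matches_grid_search_oracle_on_small_cohorts(self, rng):
        """Closed-form OLS fit agrees with a brute-force grid minimizer of
        the squared log10 error, to grid resolution, on cohorts of n<=25."""
        for seed in (0, 1, 2):
            cohort = generate_cohort(CohortSpec(n=20, seed=seed))
            bw = np.array([r.body_weight for r in cohort])
            lwi = np.array([r.lung_weight_index for r in cohort])
            fit = fit_exponential(cohort)
            center = (np.log10(fit.model.a), fit.model.b)
            gi, gs = grid_search_fit(bw, lwi, center)
            assert gi == pytest.approx(np.log10(fit.model.a), abs=0.05 / 100)
            assert gs == pytest.approx(fit.model.b, abs=0.005 / 100)

    def test_natural_scale_fit_close_to_log_fit_at_low_noise(self):
        cohort = generate_cohort(CohortSpec(n=141, seed=9, noise_sigma_log10=0.02))
        log_fit = fit_exponential(cohort, scale="log10")
        nat_fit = fit_exponential(cohort, scale="natural")
        assert nat_fit.model.a == pytest.approx(log_fit.model.a, rel=0.02)
        assert nat_fit.model.b == pytest.approx(log_fit.model.b, abs=0.001)

    def test_sklearn_protocol(self, noisy_cohort):
        bw = np.array([r.body_weight for r in noisy_cohort])
        lwi = np.array([r.lung_weight_index for r in noisy_cohort])
        reg = ExponentialIndexRegressor()
        assert reg.get_params() == {"scale": "log10", "alpha": 0.05}
        cloned = clone(reg).set_params(alpha=0.1)
        assert cloned.alpha == 0.1
        reg.fit(bw, lwi)
        pred = reg.predict([20.0, 40.0])
        assert pred.shape == (2,)
        assert reg.score(bw, lwi) > 0.3  # R^2 against a real BW trend


class TestSplit:
    def test_study_sized_cohort_splits_141_36(self, noisy_cohort):
        train, valid = split_cohort(noisy_cohort, SplitSpec(0.8, seed=0))
        assert (len(train), len(valid)) == (141, 36)

    def test_90_10_split_is_159_18(self, noisy_cohort):
        train, valid = split_cohort(noisy_cohort, SplitSpec(0.9, seed=0))
        assert (len(train), len(valid)) == (159, 18)

    def test_partition_disjoint_and_exhaustive(self, noisy_cohort):
        train, valid = split_cohort(noisy_cohort, SplitSpec(0.8, seed=5))
        ids = {r.animal_id for r in train} | {r.animal_id for r in valid}
        assert len(ids) == len(noisy_cohort)
        assert not ({r.animal_id for r in train} & {r.animal_id for r in valid})

    def test_same_seed_same_partition(self, noisy_cohort):
        a = split_cohort(noisy_cohort, SplitSpec(0.8, seed=42))
        b = split_cohort(noisy_cohort, SplitSpec(0.8, seed=42))
        assert [r.animal_id for r in a[0]] == [r.animal_id for r in b[0]]

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0, seed=0)
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.0, seed=0)


class TestEvaluate:
    def test_cohort_on_curve_scores_zero(self, noiseless_cohort, reference_model):
        rmse, mae = evaluate(reference_model, noiseless_cohort)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert mae == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_two_point_residuals(self, reference_model):
        # log10 residuals of exactly +0.1 and -0.1
        records = [
            PigRecord("hi", 20.0,
                      reference_model.predict_lung_weight(20.0) * 10**0.1),
            PigRecord("lo", 40.0,
                      reference_model.predict_lung_weight(40.0) * 10**-0.1),
        ]
        rmse, mae = evaluate(reference_model, records)
        assert rmse == pytest.approx(0.1, abs=1e-12)
        assert mae == pytest.approx(0.1, abs=1e-12)

    def test_rmse_estimates_noise_sd_at_large_n(self, reference_model):
        cohort = generate_cohort(
            CohortSpec(n=5000, seed=13, noise_sigma_log10=0.068)
        )
        rmse, mae = evaluate(reference_model, cohort)
        assert rmse == pytest.approx(0.068, abs=0.005)
        assert mae <= rmse

    def test_empty_cohort_rejected(self, reference_model):
        with pytest.raises(ValueError):
            evaluate(reference_model, [])


class TestCrossValidate:
    def test_noiseless_cohort_gives_zero_fold_errors(self, noiseless_cohort):
        cv = cross_validate(noiseless_cohort, k=5, seed=0)
        assert cv["mean_rmse_log10"] == pytest.approx(0.0, abs=1e-10)
        assert all(r == pytest.approx(0.0, abs=1e-10) for r in cv["rmse_log10"])

    def test_leave_one_out_runs_on_small_cohort(self):
        cohort = generate_cohort(CohortSpec(n=20, seed=2))
        cv = cross_validate(cohort, k=20, seed=0)
        assert len(cv["rmse_log10"]) == 20

    def test_cv_error_tracks_training_error(self, noisy_cohort):
        fit = fit_exponential(noisy_cohort)
        cv = cross_validate(noisy_cohort, k=5, seed=3)
        assert cv["mean_rmse_log10"] == pytest.approx(fit.rmse_log10, abs=0.01)

    def test_k_out_of_range_rejected(self, noisy_cohort):
        with pytest.raises(ValueError):
            cross_validate(noisy_cohort, k=1, seed=0)
        with pytest.raises(ValueError):
            cross_validate(noisy_cohort, k=len(noisy_cohort) + 1, seed=0)
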
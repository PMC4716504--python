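"""Weighted binomial GLM fitting and post-fit diagnostics."""

import numpy as np
import pytest
from scipy.special import expit

from gridbias.sdm import (
    DESIGN_COLUMNS,
    FitError,
    FitResult,
    ModelVariant,
    SchemaError,
    VARIANTS,
    design_matrix,
    fit_variant,
    fit_weighted_glm,
    partial_explained_deviance,
    predict_occurrence,
    pseudo_r2,
    standardize_coefficients,
    vif,
    weighted_sd,
)


def simulate_logistic(rng, n=800, beta=(0.2, 1.0, -0.8), k=2):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
    p = expit(X @ np.asarray(beta))
    y = (rng.random(n) < p).astype(float)
    return X, y


class TestModelVariant:
    def test_six_valid_variants(self):
        assert set(VARIANTS) == {"L", "LA", "LL", "LLA", "M", "ML"}

    def test_flags_consistent_with_abbreviation(self):
        assert VARIANTS["LA"].area_weighting and not VARIANTS["LA"].landcover_weighting
        assert VARIANTS["ML"].projection == "equalarea"

    def test_equalarea_area_weighting_invalid(self):
        with pytest.raises(FitError):
            ModelVariant("equalarea", True, False, "MA")

    def test_mismatched_abbreviation(self):
        with pytest.raises(FitError):
            ModelVariant("longlat", False, False, "LA")

    def test_weights_selection(self, longlat_land):
        np.testing.assert_allclose(VARIANTS["L"].weights(longlat_land), 1.0)
        np.testing.assert_allclose(
            VARIANTS["LLA"].weights(longlat_land),
            longlat_land["weight_area"] * longlat_land["weight_land"],
        )


class TestDesignMatrix:
    def test_shape_and_columns(self, longlat_land):
        X, names, warn = design_matrix(longlat_land)
        assert X.shape == (len(longlat_land), 9)
        assert names == DESIGN_COLUMNS
        assert warn == []

    def test_squared_columns(self, longlat_land):
        X, names, _ = design_matrix(longlat_land)
        np.testing.assert_allclose(X[:, 5], X[:, 1] ** 2)

    def test_linear_only_mode(self, longlat_land):
        X, names, _ = design_matrix(longlat_land, quadratic=False)
        assert X.shape[1] == 5

    def test_collinearity_flagged(self, longlat_land):
        table = longlat_land.copy()
        table["diurnal_range"] = table["temperature"]
        _, _, warn = design_matrix(table)
        assert any("rank" in w for w in warn)

    def test_missing_values_rejected(self, longlat_land):
        table = longlat_land.copy()
        table.loc[table.index[0], "temperature"] = np.nan
        with pytest.raises(FitError):
            design_matrix(table)


class TestFitWeightedGlm:
    def test_unit_weights_equal_unweighted(self, rng):
        X, y = simulate_logistic(rng)
        a = fit_weighted_glm(X, y, np.ones(len(y)), columns=["c0", "c1", "c2"])
        b = fit_weighted_glm(X, y, None, columns=["c0", "c1", "c2"])
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_row_duplication_equals_weight_doubling(self, rng):
        X, y = simulate_logistic(rng, n=300)
        w = rng.random(len(y)) + 0.5
        dup = fit_weighted_glm(
            np.vstack([X, X]), np.concatenate([y, y]), np.concatenate([w, w]),
            columns=["c0", "c1", "c2"],
        )
        dbl = fit_weighted_glm(X, y, 2 * w, columns=["c0", "c1", "c2"])
        np.testing.assert_allclose(dup.coefficients, dbl.coefficients, atol=1e-8)

    def test_weight_rescaling_leaves_coefficients(self, rng):
        X, y = simulate_logistic(rng)
        w = rng.random(len(y)) + 0.1
        a = fit_weighted_glm(X, y, w, columns=["c0", "c1", "c2"])
        b = fit_weighted_glm(X, y, 7.3 * w, columns=["c0", "c1", "c2"])
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X, _ = simulate_logistic(rng, n=50)
        with pytest.raises(FitError):
            fit_weighted_glm(X, np.ones(50), columns=["c0", "c1", "c2"])

    def test_negative_weights_rejected(self, rng):
        X, y = simulate_logistic(rng, n=50)
        with pytest.raises(FitError):
            fit_weighted_glm(X, y, -np.ones(50))

    def test_perfect_separation_flagged_not_raised(self):
        x = np.linspace(-2, 2, 60)
        X = np.column_stack([np.ones(60), x])
        y = (x > 0).astype(float)
        fit = fit_weighted_glm(X, y, columns=["c0", "c1"], compute_partials=False)
        assert fit.converged is False

    def test_prevalence_is_weighted(self, rng):
        X, y = simulate_logistic(rng, n=400)
        w = rng.random(400)
        fit = fit_weighted_glm(X, y, w, columns=["c0", "c1", "c2"])
        assert fit.prevalence == pytest.approx(np.sum(w * y) / np.sum(w))

    def test_recovers_truth_small(self, rng):
        # parameter recovery at modest n: within 3 SE for every coefficient
        beta = np.array([0.3, 1.2, -0.7])
        X, y = simulate_logistic(rng, n=4000, beta=beta)
        fit = fit_weighted_glm(X, y, columns=["c0", "c1", "c2"])
        z = np.abs(fit.coefficients - beta) / fit.standard_errors
        assert np.all(z < 3)

    def test_serialization_round_trip(self, rng, tmp_path):
        X, y = simulate_logistic(rng)
        fit = fit_weighted_glm(X, y, columns=["c0", "c1", "c2"])
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        back = FitResult.from_dict(json.loads(path.read_text()))
        np.testing.assert_allclose(back.coefficients, fit.coefficients)
        assert back.converged == fit.converged


class TestStandardization:
    def test_scales_by_column_sd(self):
        X = np.column_stack([np.ones(8), [1, 1, 3, 3, 1, 1, 3, 3]])
        coefs = np.array([0.0, 2.0])
        out = standardize_coefficients(coefs, X)
        assert out[0] == pytest.approx(2.0 * 1.0)  # sd of column is 1

    def test_prestandardized_column_unchanged(self, rng):
        col = rng.normal(size=500)
        col = (col - col.mean()) / col.std()
        X = np.column_stack([np.ones(500), col])
        out = standardize_coefficients(np.array([1.0, 3.3]), X)
        assert out[0] == pytest.approx(3.3, rel=1e-9)

    def test_zero_variance_column_missing(self):
        X = np.column_stack([np.ones(5), np.full(5, 2.0)])
        out = standardize_coefficients(np.array([1.0, 5.0]), X)
        assert np.isnan(out[0])

    def test_weighted_sd(self, rng):
        x = rng.normal(size=100)
        assert weighted_sd(x, np.ones(100)) == pytest.approx(x.std())

    def test_delta_invariant_under_consistent_scaling(self, rng):
        # rescaling a design column scales beta and se together: delta fixed
        beta = np.array([0.0, 1.0, -0.5])
        X, y = simulate_logistic(rng, n=2000, beta=beta)
        fit_raw = fit_weighted_glm(X, y, columns=["c0", "c1", "c2"])
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] / 3.0
        fit_scaled = fit_weighted_glm(X2, y, columns=["c0", "c1", "c2"])
        d_raw = np.abs(fit_raw.coefficients[1] - beta[1]) / fit_raw.standard_errors[1]
        d_scaled = np.abs(fit_scaled.coefficients[1] - 3 * beta[1]) / fit_scaled.standard_errors[1]
        assert d_raw == pytest.approx(d_scaled, rel=1e-4)


class TestPartialDeviance:
    def test_null_predictor_near_zero(self, rng):
        n = 4000
        x1 = rng.normal(size=n)
        x_null = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x_null, x1**2, x_null**2])
        cols = ["intercept", "temperature", "diurnal_range", "temperature_sq", "diurnal_range_sq"]
        y = (rng.random(n) < expit(1.0 * x1 - 0.5 * x1**2)).astype(float)
        fit = fit_weighted_glm(X, y, columns=cols, compute_partials=False)
        w = np.ones(n)
        pd4 = partial_explained_deviance(X, y, w, fit.deviance, fit.null_deviance, cols)
        assert pd4[1] < 0.01  # diurnal_range has no true effect
        assert pd4[0] > 0.05

    def test_sole_predictor_matches_pseudo_r2(self, rng):
        n = 3000
        x1 = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x1**2])
        cols = ["intercept", "temperature", "temperature_sq"]
        y = (rng.random(n) < expit(0.8 * x1 - 0.3 * x1**2)).astype(float)
        fit = fit_weighted_glm(X, y, columns=cols, compute_partials=False)
        pd4 = partial_explained_deviance(X, y, np.ones(n), fit.deviance, fit.null_deviance, cols)
        assert pd4[0] == pytest.approx(fit.pseudo_r2, abs=1e-10)

    def test_non_negative(self, longlat_land):
        fit = fit_variant(longlat_land, "L")
        assert np.all(fit.partial_deviance[~np.isnan(fit.partial_deviance)] >= 0)


class TestPseudoR2:
    def test_null_model_zero(self, rng):
        X, y = simulate_logistic(rng, n=500)
        fit = fit_weighted_glm(X[:, :1], y, columns=["intercept"], compute_partials=False)
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-10)

    def test_nested_model_not_better(self, rng):
        X, y = simulate_logistic(rng, n=1500)
        full = fit_weighted_glm(X, y, columns=["c0", "c1", "c2"], compute_partials=False)
        reduced = fit_weighted_glm(X[:, :2], y, columns=["c0", "c1"], compute_partials=False)
        assert reduced.pseudo_r2 <= full.pseudo_r2 + 1e-12

    def test_strong_signal_approaches_one(self, rng):
        n = 2000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < expit(8 * x)).astype(float)
        fit = fit_weighted_glm(X, y, columns=["c0", "c1"], compute_partials=False)
        assert fit.pseudo_r2 > 0.6

    def test_degenerate_null(self):
        assert pseudo_r2(0.0, 0.0) == 0.0


class TestVif:
    def test_orthogonal_columns(self, rng):
        X = rng.normal(size=(5000, 4))
        np.testing.assert_allclose(vif(X), 1.0, atol=0.01)

    def test_duplicate_column_infinite(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, x, rng.normal(size=200), rng.normal(size=200)])
        v = vif(X)
        assert np.isinf(v[0]) and np.isinf(v[1])

    def test_known_pairwise_correlation(self, rng):
        # closed form for two correlated variables: VIF = 1 / (1 - rho^2)
        n = 200_000
        z = rng.normal(size=n)
        x1 = z
        x2 = 0.7 * z + np.sqrt(1 - 0.49) * rng.normal(size=n)
        X = np.column_stack([x1, x2, rng.normal(size=n), rng.normal(size=n)])
        v = vif(X)
        assert v[0] == pytest.approx(1 / (1 - 0.49), rel=0.02)
        assert v[2] == pytest.approx(1.0, abs=0.01)


class TestPredict:
    def test_zero_coefficients_give_half(self, longlat_land):
        X, names, _ = design_matrix(longlat_land)
        fit = FitResult(
            coefficients=np.zeros(9),
            standard_errors=np.ones(9),
            standardized_coefficients=np.zeros(8),
            partial_deviance=np.zeros(4),
            pseudo_r2=0.0,
            prevalence=0.5,
            n_cells=len(longlat_land),
            converged=True,
            deviance=0.0,
            null_deviance=0.0,
            columns=names,
        )
        np.testing.assert_allclose(predict_occurrence(fit, X), 0.5)

    def test_column_mismatch_rejected(self, longlat_land, rng):
        fit = fit_variant(longlat_land, "L")
        with pytest.raises(SchemaError):
            predict_occurrence(fit, rng.normal(size=(10, 5)))
        X, _, _ = design_matrix(longlat_land)
        with pytest.raises(SchemaError):
            predict_occurrence(fit, X, columns=["wrong"] * 9)

    def test_mean_prediction_matches_weighted_prevalence(self, longlat_land):
        # IRLS score equation for the intercept
        fit = fit_variant(longlat_land, "LLA")
        X, _, _ = design_matrix(longlat_land)
        p = predict_occurrence(fit, X)
        w = VARIANTS["LLA"].weights(longlat_land)
        assert np.sum(w * p) / np.sum(w) == pytest.approx(fit.prevalence, rel=1e-4)

    def test_monotone_in_single_positive_column(self):
        fit = FitResult(
            coefficients=np.array([0.0, 2.0]),
            standard_errors=np.ones(2),
            standardized_coefficients=np.array([2.0]),
            partial_deviance=np.zeros(4),
            pseudo_r2=0.0,
            prevalence=0.5,
            n_cells=10,
            converged=True,
            deviance=0.0,
            null_deviance=0.0,
            columns=("intercept", "x"),
        )
        X = np.column_stack([np.ones(10), np.linspace(-2, 2, 10)])
        p = predict_occurrence(fit, X)
        assert np.all(np.diff(p) > 0)


class TestRegressionDilution:
    def test_measurement_error_attenuates_slopes(self, rng):
        # classical within-cell measurement error: |slope| shrinks as the
        # error (subcell heterogeneity) grows
        n = 6000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 * x)).astype(float)
        mags = []
        for noise_sd in (0.0, 0.7, 1.4):
            x_obs = x + noise_sd * rng.normal(size=n)
            X = np.column_stack([np.ones(n), x_obs])
            fit = fit_weighted_glm(X, y, columns=["c0", "c1"], compute_partials=False)
            mags.append(abs(fit.coefficients[1]))
        assert mags[0] > mags[1] > mags[2]
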
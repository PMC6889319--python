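"""Fold-change conversion, OLS calibration and synthetic expression data."""

import numpy as np
import pandas as pd
import pytest

from acidmac.calibration import (
    DEFAULT_DESIGN,
    ct_to_foldchange,
    default_true_model,
    design_matrix,
    fit_all_traits,
    fit_trait_model,
    generate_synthetic_expression,
    prediction_heatmap,
)
from acidmac.errors import FittingError, ParameterError
from acidmac.macrophage import ANTI_TUMOUR, PhenotypeModel, TraitModel


class TestCtToFoldchange:
    @pytest.mark.parametrize(
        "target,ref,expected", [(25, 25, 1.0), (25, 20, 0.03125), (20, 25, 32.0)]
    )
    def test_two_to_the_minus_delta_ct(self, target, ref, expected):
        assert ct_to_foldchange(target, ref) == pytest.approx(expected, rel=1e-12)

    def test_always_positive(self):
        assert ct_to_foldchange(40.0, 10.0) > 0

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ParameterError):
            ct_to_foldchange(bad, 20.0)


def obs_from_truth(coeffs, design=DEFAULT_DESIGN, trait="t"):
    rows = []
    a, b, c, d = coeffs
    for i, (p, e) in enumerate(design):
        rows.append([trait, p, e, a + b * p + c * e + d * p * e, i])
    return pd.DataFrame(rows, columns=["trait", "pH", "e_code", "value", "replicate"])


class TestFitTraitModel:
    def test_exact_interpolation_on_2x2_design(self):
        truth = (3.0, -0.4, 1.2, 0.08)
        obs = obs_from_truth(truth)
        fit = fit_trait_model(obs)
        np.testing.assert_allclose(fit.coefficients, truth, atol=1e-10)
        assert fit.rss < 1e-20

    def test_single_ph_design_is_singular_and_names_directions(self):
        obs = obs_from_truth((1, 1, 1, 1), design=[(7.4, -1), (7.4, 1),
                                                   (7.4, -1), (7.4, 1)])
        with pytest.raises(FittingError, match="singular design"):
            fit_trait_model(obs)

    def test_too_few_observations_rejected(self):
        obs = obs_from_truth((1, 0, 0, 0))[:3]
        with pytest.raises(FittingError):
            fit_trait_model(obs)

    def test_matches_normal_equations_oracle_on_random_data(self):
        """OLS solution equals the brute-force normal-equations solve
        (X'X)^-1 X'y on 100 random instances."""
        r = np.random.default_rng(7)
        for _ in range(100):
            n = r.integers(6, 40)
            ph = r.uniform(6.0, 7.6, n)
            e = r.uniform(-1, 1, n)
            y = r.normal(0, 3, n)
            obs = pd.DataFrame({
                "trait": "t", "pH": ph, "e_code": e, "value": y,
                "replicate": np.arange(n),
            })
            fit = fit_trait_model(obs)
            X = design_matrix(ph, e)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)

    def test_coefficient_recovery_within_two_standard_errors(self):
        """Monte-Carlo calibration of the OLS estimator: with 200 noisy
        observations (sigma = 10% of the mean) the fitted coefficients land
        within 2 standard errors of the truth at ~95% nominal coverage;
        the pooled success fraction over 100 seeded repetitions stays
        above 93%."""
        truth_model = default_true_model()
        hits = 0
        total = 0
        for rep in range(100):
            obs = generate_synthetic_expression(
                truth_model, replicates=50, noise_sd=0.1, seed=1000 + rep
            )
            fits = fit_all_traits(obs)
            for name, fit in fits.items():
                t = truth_model.traits[name]
                truth = np.array([t.alpha, t.beta, t.gamma, t.delta])
                se = np.array([fit.std_errors[k]
                               for k in ("alpha", "beta", "gamma", "delta")])
                hits += int(np.sum(np.abs(fit.coefficients - truth) <= 2 * se))
                total += 4
        assert hits / total >= 0.93


class TestSyntheticExpression:
    def test_noiseless_roundtrip_recovers_generating_truth(self):
        truth_model = default_true_model()
        obs = generate_synthetic_expression(truth_model, replicates=1,
                                            noise_sd=0.0, seed=0)
        fits = fit_all_traits(obs)
        for name, fit in fits.items():
            t = truth_model.traits[name]
            np.testing.assert_allclose(
                fit.coefficients, [t.alpha, t.beta, t.gamma, t.delta], atol=1e-10
            )

    def test_noiseless_values_equal_predictions(self):
        truth_model = default_true_model()
        obs = generate_synthetic_expression(truth_model, replicates=2,
                                            noise_sd=0.0, seed=5)
        for row in obs.itertuples():
            pred = truth_model.traits[row.trait].predict(row.pH, row.e_code)
            assert row.value == pytest.approx(pred, abs=1e-12)

    def test_same_seed_identical_tables(self):
        truth_model = default_true_model()
        a = generate_synthetic_expression(truth_model, noise_sd=0.2, seed=9)
        b = generate_synthetic_expression(truth_model, noise_sd=0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_values_truncated_at_zero(self):
        truth_model = default_true_model()
        obs = generate_synthetic_expression(truth_model, replicates=200,
                                            noise_sd=2.0, seed=3)
        assert (obs.value >= 0).all()

    def test_acidosis_raises_pro_tumour_marker_in_default_truth(self):
        """Under the default generating coefficients the alternative
        activation marker rises at pH 6.8 versus 7.4 at matched stimulation
        and the inflammatory marker falls."""
        m = default_true_model()
        arg1 = m.traits["Arg1"]
        ccl2 = m.traits["Ccl2"]
        assert arg1.predict(6.8, 1.0) > arg1.predict(7.4, 1.0)
        assert ccl2.predict(6.8, -1.0) < ccl2.predict(7.4, -1.0)


class TestPredictionHeatmap:
    def test_constant_model_gives_constant_matrix(self):
        m = PhenotypeModel([TraitModel("t", ANTI_TUMOUR, 2.5, 0, 0, 0, 0, 1)])
        mat = prediction_heatmap(m, "t", np.linspace(6, 7.6, 5), np.linspace(-1, 1, 7))
        assert np.all(mat == 2.5)

    def test_matrix_entries_match_trait_expression(self):
        m = default_true_model()
        ph_grid = np.linspace(6.0, 7.6, 9)
        e_grid = np.linspace(-1, 1, 11)
        mat = prediction_heatmap(m, "Arg1", ph_grid, e_grid)
        t = m.traits["Arg1"]
        for i in (0, 4, 8):
            for j in (0, 5, 10):
                assert mat[i, j] == pytest.approx(t.predict(ph_grid[i], e_grid[j]))

    def test_no_interaction_rows_share_slope_in_e(self):
        m = PhenotypeModel([TraitModel("t", ANTI_TUMOUR, 1.0, 0.5, 2.0, 0.0, 0, 1)])
        e_grid = np.linspace(-1, 1, 5)
        mat = prediction_heatmap(m, "t", np.array([6.2, 7.0, 7.5]), e_grid)
        de = e_grid[1] - e_grid[0]
        slopes = np.diff(mat, axis=1) / de
        np.testing.assert_allclose(slopes, 2.0, atol=1e-12)

    def test_design_corner_consistency_after_exact_fit(self):
        obs = obs_from_truth((2.0, 0.3, -1.0, 0.2))
        fit = fit_trait_model(obs)
        m = PhenotypeModel([TraitModel("t", ANTI_TUMOUR, fit.alpha, fit.beta,
                                       fit.gamma, fit.delta, 0, 1)])
        mat = prediction_heatmap(m, "t", np.array([7.4, 6.8]), np.array([-1.0, 1.0]))
        for (p, e), v in zip(DEFAULT_DESIGN, obs.value):
            i = 0 if p == 7.4 else 1
            j = 0 if e == -1 else 1
            assert mat[i, j] == pytest.approx(v, abs=1e-10)
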
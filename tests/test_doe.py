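import numpy as np
import pytest

from ramanscreen.doe import (
    DesirabilitySpec,
    build_design,
    compare_individual_vs_overall,
    desirability,
    fit_metric_model,
    main_effect_terms,
    optimize_combination,
    two_factor_terms,
)
from ramanscreen.filters import FilterCombination, all_combinations
from ramanscreen.simulate import planted_screen
from ramanscreen.workflow import fit_metric_models, optimize_screen

CELLS = all_combinations()


class TestFactorCoding:
    def test_main_effect_design_has_16_columns(self):
        X, slices = build_design(CELLS, main_effect_terms())
        assert X.shape == (480, 16)  # intercept + 5 + 4 + 3 + 3

    def test_contrast_columns_sum_to_zero_over_balanced_grid(self):
        X, _ = build_design(CELLS, main_effect_terms() + two_factor_terms())
        np.testing.assert_allclose(X[:, 1:].sum(axis=0), 0.0, atol=1e-9)

    def test_full_model_design_has_full_column_rank(self):
        X, _ = build_design(CELLS, main_effect_terms() + two_factor_terms())
        assert X.shape[1] == 99
        assert np.linalg.matrix_rank(X) == 99


class TestMetricModel:
    def test_zero_noise_coefficients_recovered_exactly(self):
        terms = main_effect_terms() + two_factor_terms()
        X, slices = build_design(CELLS, terms)
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.2, 1.0, X.shape[1])
        y = X @ beta
        m = fit_metric_model(CELLS, y, transform="none")
        assert set(m.terms) == set(terms)
        np.testing.assert_allclose(m.coef, beta, atol=1e-8)

    def test_predictions_reproduce_cell_means_of_unreduced_fit(self):
        # OLS projection: with one observation per cell and the full
        # main+2FI model, predictions are the model's cell means
        terms = main_effect_terms() + two_factor_terms()
        X, _ = build_design(CELLS, terms)
        rng = np.random.default_rng(1)
        y = X @ rng.uniform(0.1, 0.5, X.shape[1])
        m = fit_metric_model(CELLS, y, transform="none")
        np.testing.assert_allclose(m.predict(CELLS), y, atol=1e-8)

    def test_pure_factor_effect_keeps_only_that_factor(self):
        rng = np.random.default_rng(2)
        effects = dict(zip(("SG", "EWMA", "WDS", "MW", "AsLS", "none"),
                           (0.0, 0.4, 0.8, 0.3, 0.6, 0.2)))
        y = 1.0 + np.array([effects[c.smoothing] for c in CELLS]) \
            + 0.05 * rng.standard_normal(480)
        m = fit_metric_model(CELLS, y, transform="none")
        assert set(m.terms) == {("smoothing",)}


class TestDesirability:
    def test_importance_weighted_geometric_mean(self):
        specs = {"MAE": DesirabilitySpec("MAE", 0.0, 1.0, importance=5),
                 "SD": DesirabilitySpec("SD", 0.0, 1.0, importance=4)}
        ds, D = desirability({"MAE": 0.0, "SD": 0.5}, specs)
        assert ds["MAE"] == 1.0 and ds["SD"] == 0.5
        assert D == pytest.approx((1.0**5 * 0.5**4) ** (1.0 / 9.0))

    def test_boundary_values(self):
        specs = {"a": DesirabilitySpec("a", 1.0, 2.0, importance=3),
                 "b": DesirabilitySpec("b", 0.0, 4.0, importance=2)}
        _, D = desirability({"a": 1.0, "b": 0.0}, specs)
        assert D == 1.0
        _, D0 = desirability({"a": 2.5, "b": 0.0}, specs)
        assert D0 == 0.0

    def test_affine_rescaling_invariance(self):
        spec1 = {"m": DesirabilitySpec("m", 2.0, 8.0)}
        spec2 = {"m": DesirabilitySpec("m", 2.0 * 10 + 1, 8.0 * 10 + 1)}
        _, d1 = desirability({"m": 5.0}, spec1)
        _, d2 = desirability({"m": 5.0 * 10 + 1}, spec2)
        assert d1 == pytest.approx(d2)


class TestOptimizer:
    def test_argmax_matches_direct_single_response_comparison(self):
        screen = planted_screen(FilterCombination("MW", "offset", "none",
                                                  "none"),
                                seed=5, parameters=["Gluc"])
        models, specs = fit_metric_models(screen, ["Gluc"])
        key = "Gluc:MAE"
        res = optimize_combination({key: models[key]}, {key: specs[key]})
        preds = models[key].predict(CELLS)
        assert res.best == CELLS[int(np.argmin(preds))]

    def test_reported_D_consistent_with_recomputation(self):
        screen = planted_screen(FilterCombination("SG", "linear", "snv",
                                                  "msc"),
                                seed=6, parameters=["Gluc", "Lac"])
        bundle = optimize_screen(screen, compare=False)
        _, D = desirability(bundle.overall.predictions, bundle.specs)
        assert bundle.overall.D == pytest.approx(D)

    def test_comparison_flags_constructed_shift(self):
        rng = np.random.default_rng(7)
        win = FilterCombination("WDS", "asls", "snv", "d1q")
        screen = planted_screen(win, seed=8, parameters=["Gluc"])
        bundle = optimize_screen(screen)
        # identical combos -> never flagged
        same = bundle.comparison[
            bundle.comparison.individual_combination
            == bundle.comparison.overall_combination]
        assert not same.individual_better.any()
        # a +1 AE shift for the overall cell is flagged at alpha = 0.05
        ind = screen.lookup("Gluc", win.label())
        other = FilterCombination("SG", "offset", "none", "none")
        ovl = screen.lookup("Gluc", other.label())
        ovl.ae = ind.ae + 1.0 + 0.01 * rng.standard_normal(len(ind.ae))
        from ramanscreen.doe import DesirabilityResult
        fake_overall = DesirabilityResult(best=other, D=0.5, predictions={},
                                          per_response_d={},
                                          D_all=np.zeros(480))
        rep = compare_individual_vs_overall(
            {"Gluc": bundle.individual["Gluc"]}, fake_overall, screen)
        if bundle.individual["Gluc"].best == win:
            assert rep.individual_better.iloc[0]
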
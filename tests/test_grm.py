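import numpy as np
import pytest

from shortform.grm import (
    EstimationOptions,
    ItemParameters,
    category_probabilities,
    fit_grm,
    information_criteria,
    loadings_from_slopes,
    make_grid,
    marginal_loglik,
    select_dimension_count,
)
from shortform.instrument import InstrumentSpec, ResponseMatrix
from shortform.rotation import align_columns
from shortform.simulate import (
    SimulationConfig,
    generate_true_parameters,
    simulate_responses,
)


class TestItemParameters:
    def test_increasing_intercepts_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            ItemParameters(np.array([1.0]), np.array([-1.0, 1.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ItemParameters(np.array([np.inf]), np.array([1.0, -1.0]))


class TestCategoryProbabilities:
    def test_sum_to_one_and_nonnegative(self):
        item = ItemParameters(np.array([1.7]), np.array([2.0, 0.5, -1.0, -3.0]))
        for th in (-2.0, 0.0, 1.5):
            p = category_probabilities(item, np.array([th]))
            assert p.shape == (5,)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monotone_expected_score_in_theta(self):
        item = ItemParameters(np.array([1.2]), np.array([1.0, -0.2, -1.5]))
        grid = np.linspace(-3, 3, 21)
        exp_scores = [
            category_probabilities(item, np.array([t])) @ np.arange(4) for t in grid
        ]
        assert (np.diff(exp_scores) > 0).all()

    def test_published_parameter_row(self):
        # a = (2.57, 0.21, 0.84, 0.92), d = (7.54, 5.34, 2.36, -1.24) at theta=0
        item = ItemParameters(
            np.array([2.57, 0.21, 0.84, 0.92]),
            np.array([7.54, 5.34, 2.36, -1.24]),
        )
        p = category_probabilities(item, np.zeros(4))
        expected = [0.000531, 0.004242, 0.081501, 0.689290, 0.224436]
        assert np.allclose(p, expected, atol=1e-6)


class TestQuadrature:
    def test_gh_grid_integrates_gaussian_moments(self):
        for d in (1, 2, 3):
            grid = make_grid(d)
            assert grid.weights.sum() == pytest.approx(1.0)
            mean = grid.weights @ grid.nodes
            var = grid.weights @ grid.nodes**2
            assert np.allclose(mean, 0.0, atol=1e-10)
            assert np.allclose(var, 1.0, atol=1e-8)

    def test_qmc_grid_for_high_dims(self):
        grid = make_grid(4, n_qmc_nodes=512, seed=1)
        assert grid.kind == "qmc-sobol"
        assert grid.nodes.shape == (512, 4)
        var = grid.weights @ grid.nodes**2
        assert np.allclose(var, 1.0, atol=0.1)


class TestMarginalLoglik:
    def test_matches_brute_force_enumeration(self):
        # one item, exact marginal = sum_m w_m P(x|theta_m)
        item = ItemParameters(np.array([1.0]), np.array([0.5, -0.5]))
        grid = make_grid(1, n_quadrature=11)
        data = ResponseMatrix(np.array([[0], [1], [2]]), ["a"], [3])
        ll = marginal_loglik(data, [item], grid)
        brute = 0.0
        for code in (0, 1, 2):
            pm = np.array(
                [category_probabilities(item, th)[code] for th in grid.nodes]
            )
            brute += np.log(grid.weights @ pm)
        assert ll == pytest.approx(brute, abs=1e-10)

    def test_missing_entries_skipped(self):
        item = ItemParameters(np.array([1.0]), np.array([0.0]))
        grid = make_grid(1, n_quadrature=7)
        full = ResponseMatrix(np.array([[0, 1]]), ["a", "b"], [2, 2])
        part = ResponseMatrix(np.array([[0, -1]]), ["a", "b"], [2, 2])
        ll_full = marginal_loglik(full, [item, item], grid)
        ll_part = marginal_loglik(part, [item, item], grid)
        ll_single = marginal_loglik(
            ResponseMatrix(np.array([[0]]), ["a"], [2]), [item], grid
        )
        assert ll_part == pytest.approx(ll_single, abs=1e-10)
        assert ll_full < ll_part


class TestInformationCriteria:
    def test_formulas(self):
        ll, q, n = -123.4, 7, 200
        ics = information_criteria(ll, q, n)
        assert ics["AIC"] == pytest.approx(-2 * ll + 2 * q)
        assert ics["BIC"] == pytest.approx(-2 * ll + q * np.log(n))
        assert ics["AICc"] == pytest.approx(ics["AIC"] + 2 * q * (q + 1) / (n - q - 1))
        assert ics["SABIC"] == pytest.approx(-2 * ll + q * np.log((n + 2) / 24))

    def test_aicc_undefined_for_tiny_n(self):
        assert np.isnan(information_criteria(-1.0, 5, 6)["AICc"])


class TestFitGRM:
    def test_unidimensional_recovery(self, moderate_config):
        ids = tuple(f"I{j}" for j in range(10))
        inst = InstrumentSpec(ids, {i: "A" for i in ids}, {i: 5 for i in ids})
        params = generate_true_parameters(inst, config=moderate_config, seed=1)
        data = simulate_responses(params, 1500, seed=2)
        fit = fit_grm(data.responses, 1, seed=0)
        assert fit.converged
        a_err = np.abs(fit.slope_matrix.ravel() - params.slopes.ravel())
        d_err = np.abs(
            np.vstack([p.intercepts for p in fit.params]) - params.intercepts
        )
        assert np.sqrt((a_err**2).mean()) < 0.25
        assert np.sqrt((d_err**2).mean()) < 0.2

    def test_loglik_history_nondecreasing(self, small_dataset):
        _, data = small_dataset
        fit = fit_grm(
            data.responses, 1, options=EstimationOptions(tol=1e-3, max_cycles=60)
        )
        hist = np.array(fit.loglik_history)
        assert (np.diff(hist) > -1e-6).all()

    def test_two_dim_rotated_recovery(self, small_instrument, moderate_config):
        params = generate_true_parameters(small_instrument, config=moderate_config, seed=5)
        data = simulate_responses(params, 1000, seed=6)
        fit = fit_grm(data.responses, 2, seed=5)
        aligned, _, _ = align_columns(fit.rotated_slopes, params.slopes)
        rmse = np.sqrt(np.mean((aligned - params.slopes) ** 2))
        assert rmse < 0.3
        phi_est = fit.trait_correlations[0, 1]
        assert abs(phi_est - params.trait_correlations[0, 1]) < 0.15

    def test_loadings_are_bounded(self, small_dataset):
        _, data = small_dataset
        fit = fit_grm(
            data.responses, 1, options=EstimationOptions(tol=1e-3, max_cycles=60)
        )
        assert (np.abs(fit.loadings) <= 1.0).all()
        assert (fit.communalities >= 0).all() and (fit.communalities <= 1).all()

    def test_degenerate_item_excluded(self, small_dataset):
        _, data = small_dataset
        codes = data.responses.codes.copy()
        codes[:, 3] = 2  # constant column
        rm = ResponseMatrix(codes, data.responses.item_ids, data.responses.n_categories)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_grm(rm, 1, options=EstimationOptions(tol=1e-2, max_cycles=20))
        assert fit.excluded_items == ["I03"]
        assert len(fit.item_ids) == 11

    def test_too_few_respondents_rejected(self):
        rm = ResponseMatrix(np.zeros((10, 2), dtype=int), ["a", "b"], [2, 2])
        with pytest.raises(ValueError, match="respondents"):
            fit_grm(rm, 1)

    def test_seed_determinism(self, small_dataset):
        _, data = small_dataset
        opts = EstimationOptions(tol=1e-3, max_cycles=40)
        f1 = fit_grm(data.responses, 2, options=opts, seed=3)
        f2 = fit_grm(data.responses, 2, options=opts, seed=3)
        assert np.array_equal(f1.slope_matrix, f2.slope_matrix)
        assert f1.loglik == f2.loglik


class TestSelectDimensionCount:
    def test_empty_candidates_rejected(self, small_dataset):
        _, data = small_dataset
        with pytest.raises(ValueError):
            select_dimension_count(data.responses, [])

    def test_table_contains_all_criteria(self, small_dataset):
        _, data = small_dataset
        opts = EstimationOptions(tol=1e-2, max_cycles=25, n_quadrature=11)
        chosen, table, fits = select_dimension_count(
            data.responses, [1, 2], options=opts, seed=0
        )
        assert set(table.columns) >= {"AIC", "BIC", "AICc", "SABIC", "loglik"}
        assert chosen in (1, 2)
        assert chosen == int(table["BIC"].idxmin())
        assert set(fits) == {1, 2}


def test_loadings_from_slopes_normal_ogive():
    slopes = np.array([[1.702, 0.0]])
    lam = loadings_from_slopes(slopes)
    assert lam[0, 0] == pytest.approx(1 / np.sqrt(2))
    assert lam[0, 1] == 0.0
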
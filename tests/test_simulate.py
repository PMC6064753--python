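import numpy as np
import pytest

from shortform.simulate import (
    SimulationConfig,
    TrueParameters,
    generate_true_parameters,
    inject_missing,
    plant_misfit_items,
    simulate_criterion_scores,
    simulate_responses,
)


class TestGenerateTrueParameters:
    def test_ranges_and_structure(self, instrument):
        cfg = SimulationConfig()
        params = generate_true_parameters(instrument, config=cfg, seed=0)
        assert params.slopes.shape == (40, 4)
        assert params.intercepts.shape == (40, 4)
        # dominant slope in range, cross slopes small
        subs = instrument.subscales
        for j, item in enumerate(instrument.item_ids):
            dom = subs.index(instrument.subscale_of[item])
            a = params.slopes[j]
            assert cfg.slope_range[0] <= a[dom] <= cfg.slope_range[1]
            off = np.delete(a, dom)
            assert (off >= 0).all() and (off <= cfg.cross_slope_max).all()
        # intercept rows strictly decreasing within the configured span
        assert (np.diff(params.intercepts, axis=1) < 0).all()
        assert params.intercepts[:, 0].max() <= cfg.intercept_top_range[1]
        assert params.intercepts[:, -1].min() >= cfg.intercept_bottom_range[0]
        # trait correlations in the published band, PD with unit diagonal
        r = params.trait_correlations
        iu = np.triu_indices(4, k=1)
        assert (r[iu] >= cfg.trait_correlation_range[0] - 1e-9).all()
        assert (r[iu] <= cfg.trait_correlation_range[1] + 1e-9).all()
        assert np.allclose(np.diag(r), 1.0)
        assert np.linalg.eigvalsh(r).min() > 0

    def test_seed_determinism(self, instrument):
        a = generate_true_parameters(instrument, seed=7)
        b = generate_true_parameters(instrument, seed=7)
        c = generate_true_parameters(instrument, seed=8)
        assert np.array_equal(a.slopes, b.slopes)
        assert np.array_equal(a.intercepts, b.intercepts)
        assert not np.array_equal(a.slopes, c.slopes)

    def test_increasing_intercepts_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            TrueParameters(
                slopes=np.ones((1, 1)),
                intercepts=np.array([[-1.0, 1.0]]),
                trait_correlations=np.eye(1),
            )

    def test_bad_correlation_rejected(self):
        with pytest.raises(ValueError, match="unit diagonal"):
            TrueParameters(
                slopes=np.ones((1, 2)),
                intercepts=np.array([[1.0, -1.0]]),
                trait_correlations=np.array([[2.0, 0.0], [0.0, 1.0]]),
            )


class TestSimulateResponses:
    def test_shapes_and_codes(self, small_instrument, small_dataset):
        params, data = small_dataset
        rm = data.responses
        assert rm.n == 400 and rm.p == 12
        assert rm.codes.min() >= 0 and rm.codes.max() <= 4
        assert data.true_traits.shape == (400, 2)

    def test_slope_direction_monotonicity(self, small_dataset):
        # higher trait -> higher expected response on its dominant item
        params, data = small_dataset
        theta = data.true_traits[:, 0]
        top = theta > np.quantile(theta, 0.8)
        bot = theta < np.quantile(theta, 0.2)
        vals = data.responses.values[:, 0]
        assert vals[top].mean() > vals[bot].mean() + 0.5

    def test_trait_correlation_recovered_empirically(self, small_instrument):
        params = generate_true_parameters(small_instrument, seed=3)
        data = simulate_responses(params, 20_000, seed=4)
        emp = np.corrcoef(data.true_traits.T)[0, 1]
        assert abs(emp - params.trait_correlations[0, 1]) < 0.03

    def test_determinism(self, small_instrument):
        params = generate_true_parameters(small_instrument, seed=0)
        a = simulate_responses(params, 50, seed=9)
        b = simulate_responses(params, 50, seed=9)
        assert np.array_equal(a.responses.codes, b.responses.codes)
        assert np.array_equal(a.criterion_pos, b.criterion_pos)


class TestInjectMissing:
    def test_rate_and_complete_copy(self, small_dataset):
        _, data = small_dataset
        out = inject_missing(data, 0.04, seed=5)
        frac = out.responses.missing_mask.mean()
        assert 0.02 < frac < 0.06
        # ground truth retained for imputation scoring
        assert not out.complete.missing_mask.any()
        kept = ~out.responses.missing_mask
        assert np.array_equal(out.responses.codes[kept], out.complete.codes[kept])

    def test_zero_rate_identity(self, small_dataset):
        _, data = small_dataset
        assert inject_missing(data, 0.0) is data

    def test_bad_rate(self, small_dataset):
        _, data = small_dataset
        with pytest.raises(ValueError):
            inject_missing(data, 1.0)


class TestCriterionScores:
    def test_noiseless_positive_is_exact(self, rng):
        traits = rng.normal(size=(200, 3))
        neg, pos = simulate_criterion_scores(traits, np.ones(3), 0.0, seed=0)
        total = traits.sum(axis=1)
        assert np.corrcoef(pos, total)[0, 1] == pytest.approx(1.0)
        assert np.corrcoef(neg, total)[0, 1] == pytest.approx(-1.0)

    def test_default_signs_at_n500(self, small_instrument):
        params = generate_true_parameters(small_instrument, seed=0)
        data = simulate_responses(params, 500, seed=1)
        total = data.true_traits.sum(axis=1)
        assert np.corrcoef(data.criterion_neg, total)[0, 1] < 0
        assert np.corrcoef(data.criterion_pos, total)[0, 1] > 0

    def test_zero_weights_null_correlation(self, rng):
        traits = rng.normal(size=(10_000, 2))
        neg, pos = simulate_criterion_scores(traits, np.zeros(2), 1.0, seed=1)
        total = traits.sum(axis=1)
        assert abs(np.corrcoef(pos, total)[0, 1]) < 0.1
        assert abs(np.corrcoef(neg, total)[0, 1]) < 0.1

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_criterion_scores(rng.normal(size=(10, 1)), np.ones(1), -1.0)


class TestPlantMisfit:
    def test_unknown_mode_and_items(self, small_dataset):
        _, data = small_dataset
        with pytest.raises(ValueError, match="unknown misfit mode"):
            plant_misfit_items(data, ["I00"], mode="bogus")
        with pytest.raises(ValueError, match="not in instrument"):
            plant_misfit_items(data, ["nope"])
        with pytest.raises(ValueError, match="nonempty"):
            plant_misfit_items(data, [])

    def test_shuffle_preserves_marginal_kills_association(self, small_dataset):
        _, data = small_dataset
        out = plant_misfit_items(data, ["I00"], mode="shuffle", seed=1)
        before = np.bincount(data.responses.codes[:, 0], minlength=5)
        after = np.bincount(out.responses.codes[:, 0], minlength=5)
        assert np.array_equal(before, after)
        r = np.corrcoef(out.responses.codes[:, 0], out.true_traits[:, 0])[0, 1]
        assert abs(r) < 0.15
        assert out.planted_items == ["I00"]

    def test_category_swap_breaks_ordering(self, small_instrument, moderate_config):
        params = generate_true_parameters(small_instrument, config=moderate_config, seed=2)
        data = simulate_responses(params, 4000, seed=3)
        out = plant_misfit_items(data, ["I01"], mode="category_swap", seed=4)
        theta = out.true_traits[:, 0]
        codes = out.responses.codes[:, 1]
        # mean trait is no longer monotone over ordered categories
        means = [theta[codes == k].mean() for k in range(5)]
        assert (np.diff(means) < 0).any()

    def test_untouched_items_unchanged(self, small_dataset):
        _, data = small_dataset
        out = plant_misfit_items(data, ["I03"], mode="shuffle", seed=0)
        keep = [j for j in range(12) if j != 3]
        assert np.array_equal(out.responses.codes[:, keep], data.responses.codes[:, keep])
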
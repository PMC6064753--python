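import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from shortform.grm import EstimationOptions, ItemParameters, fit_grm, make_grid
from shortform.instrument import InstrumentSpec
from shortform.itemfit import (
    ItemFitOptions,
    fit_from_parameters,
    hochberg_adjust,
    s_chi2_all,
    s_chi2_item_fit,
    stepwise_abbreviate,
    summed_score_distribution,
)
from shortform.simulate import (
    SimulationConfig,
    generate_true_parameters,
    plant_misfit_items,
    simulate_responses,
)


class TestHochberg:
    def test_worked_example(self):
        adj = hochberg_adjust(np.array([0.01, 0.04, 0.30]))
        assert np.allclose(adj, [0.03, 0.08, 0.30], atol=1e-12)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = hochberg_adjust(p)
            _, ref, _, _ = multipletests(p, method="simes-hochberg")
            assert np.allclose(ours, ref, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
        st.data(),
    )
    def test_monotone_and_idempotent(self, ps, data):
        p = np.array(ps)
        adj = hochberg_adjust(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        # ordering of adjusted values follows ordering of raw values
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        # raising one raw p never lowers any adjusted p
        i = data.draw(st.integers(min_value=0, max_value=p.size - 1))
        bumped = p.copy()
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 1.0)))
        assert (hochberg_adjust(bumped) >= adj - 1e-9).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hochberg_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            hochberg_adjust(np.array([[0.5]]))


class TestSummedScoreDistribution:
    def test_matches_exhaustive_enumeration(self):
        items = [
            ItemParameters(np.array([1.2]), np.array([1.0, -0.5])),
            ItemParameters(np.array([0.8]), np.array([0.5, -1.0])),
            ItemParameters(np.array([1.5]), np.array([2.0, 0.0])),
        ]
        theta = np.array([0.3])
        dist = summed_score_distribution(items, theta)
        from shortform.grm import category_probabilities

        ps = [category_probabilities(it, theta) for it in items]
        brute = np.zeros(7)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    brute[i + j + k] += ps[0][i] * ps[1][j] * ps[2][k]
        assert np.abs(dist - brute).max() < 1e-10
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_item_equals_category_probs(self):
        from shortform.grm import category_probabilities

        item = ItemParameters(np.array([1.0]), np.array([0.7, -0.7]))
        theta = np.array([-0.4])
        assert np.allclose(
            summed_score_distribution([item], theta),
            category_probabilities(item, theta),
            atol=1e-12,
        )


@pytest.fixture(scope="module")
def onedim_setup():
    ids = tuple(f"I{j:02d}" for j in range(10))
    inst = InstrumentSpec(ids, {i: "A" for i in ids}, {i: 5 for i in ids})
    cfg = SimulationConfig(
        intercept_top_range=(1.0, 2.5), intercept_bottom_range=(-2.5, -1.0)
    )
    params = generate_true_parameters(inst, config=cfg, seed=0)
    data = simulate_responses(params, 800, seed=1)
    return inst, params, data


class TestSChi2:
    def test_records_against_true_model(self, onedim_setup):
        inst, params, data = onedim_setup
        fit = fit_from_parameters(
            [ItemParameters(a, d) for a, d in zip(params.slopes, params.intercepts)],
            list(inst.item_ids),
        )
        records = s_chi2_all(
            data.responses, fit, options=ItemFitOptions(adjust_df_for_item_params=False)
        )
        assert len(records) == 10
        for r in records:
            assert r.testable
            assert r.df > 0
            assert r.s_chi2 >= 0
            assert 0.0 <= r.p_raw <= 1.0
        # under the true model most items should not be flagged
        flagged = sum(r.p_raw < 0.05 for r in records)
        assert flagged <= 3

    def test_single_item_matches_batch(self, onedim_setup):
        inst, params, data = onedim_setup
        fit = fit_grm(
            data.responses, 1, options=EstimationOptions(tol=1e-3, max_cycles=80)
        )
        batch = s_chi2_all(data.responses, fit)
        single = s_chi2_item_fit(data.responses, fit, "I04")
        ref = next(r for r in batch if r.item_id == "I04")
        assert single.s_chi2 == pytest.approx(ref.s_chi2)
        assert single.df == ref.df

    def test_misfitting_item_gets_larger_statistic(self, onedim_setup):
        inst, params, data = onedim_setup
        planted = plant_misfit_items(data, ["I05"], mode="category_swap", seed=9)
        fit = fit_grm(
            planted.responses, 1, options=EstimationOptions(tol=1e-3, max_cycles=80)
        )
        records = s_chi2_all(planted.responses, fit)
        by_id = {r.item_id: r for r in records}
        others = [r.s_chi2 / max(r.df, 1) for r in records if r.item_id != "I05"]
        assert by_id["I05"].s_chi2 / max(by_id["I05"].df, 1) > max(others)


class TestStepwise:
    def test_clean_data_keeps_everything(self, onedim_setup):
        inst, params, data = onedim_setup
        trace = stepwise_abbreviate(
            data.responses,
            1,
            estimation=EstimationOptions(tol=1e-3, max_cycles=80, n_quadrature=15),
            seed=0,
        )
        assert trace.stopped_because == "no_significant_misfit"
        assert len(trace.final_items) >= 9  # at most one type-I removal

    def test_planted_item_removed_first(self, onedim_setup):
        inst, params, data = onedim_setup
        planted = plant_misfit_items(data, ["I02"], mode="category_swap", seed=3)
        trace = stepwise_abbreviate(
            planted.responses,
            1,
            estimation=EstimationOptions(tol=1e-3, max_cycles=80, n_quadrature=15),
            seed=0,
        )
        removed = [s.removed_item for s in trace.steps]
        assert "I02" in removed
        assert removed[0] == "I02"
        frame = trace.to_frame()
        assert list(frame["removed_item"]) == removed
        assert (frame["remaining_count"].to_numpy() == 10 - frame["step"].to_numpy()).all()

    def test_subscale_floor_stops(self, onedim_setup):
        inst, params, data = onedim_setup
        # one-item subscale: its removal must be blocked.  I03 carries a
        # strong slope, so the planted category swap is reliably flagged.
        sub = dict(inst.subscale_of)
        sub["I03"] = "lonely"
        inst2 = InstrumentSpec(inst.item_ids, sub, dict(inst.n_categories))
        planted = plant_misfit_items(data, ["I03"], mode="category_swap", seed=4)
        with pytest.warns(UserWarning, match="empty"):
            trace = stepwise_abbreviate(
                planted.responses,
                1,
                estimation=EstimationOptions(tol=1e-3, max_cycles=60, n_quadrature=15),
                seed=0,
                instrument=inst2,
            )
        assert trace.stopped_because == "floor_reached"
        assert "I03" in trace.final_items

    def test_invalid_alpha(self, onedim_setup):
        _, _, data = onedim_setup
        with pytest.raises(ValueError):
            stepwise_abbreviate(data.responses, 1, alpha=0.0)
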
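"""Post-fit inference: prediction, partial regression, surfaces, scenarios."""

import numpy as np
import pandas as pd
import pytest

from reefbleach.model import INTERCEPT, build_design
from reefbleach.scenarios import (
    interaction_surface,
    management_scenario,
    model_drivers,
    partial_regression,
    perturb_model,
    predict_bleached,
    reduced_terms,
)

from conftest import exact_model


@pytest.fixture()
def driver_data(rng):
    n = 120
    data = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["acute_dhw", "bs_score", "par", "urban_runoff"]
    )
    data = (data - data.mean()) / data.std(ddof=1)  # standardized like the pipeline
    data["weight"] = rng.uniform(0.3, 1.0, n)
    data["cluster_id"] = np.arange(n)
    data["depth_bin"] = "shallow"
    return data


class TestPredict:
    def test_intercept_only_closed_form(self, driver_data):
        model = exact_model({INTERCEPT: 4.0}, driver_data)
        np.testing.assert_allclose(
            predict_bleached(model, driver_data), 16.0, atol=1e-9
        )

    def test_negative_sqrt_clips_to_zero(self, driver_data):
        model = exact_model({INTERCEPT: -2.0}, driver_data)
        np.testing.assert_allclose(predict_bleached(model, driver_data), 0.0)

    def test_upper_clip_at_100(self, driver_data):
        model = exact_model({INTERCEPT: 12.0}, driver_data)
        np.testing.assert_allclose(predict_bleached(model, driver_data), 100.0)

    def test_matches_dot_product_oracle(self, rng, driver_data):
        beta = {INTERCEPT: 3.0, "acute_dhw": 0.8, "bs_score": -0.4,
                "acute_dhw:bs_score": 0.3}
        model = exact_model(beta, driver_data)
        rows = driver_data.sample(10, random_state=1)
        X = build_design(rows, list(beta))
        expected = np.clip(
            np.clip(X.to_numpy() @ np.array(list(beta.values())), 0, None) ** 2, 0, 100
        )
        np.testing.assert_allclose(predict_bleached(model, rows), expected, atol=1e-9)

    def test_unknown_term_rejected(self, driver_data):
        model = exact_model({INTERCEPT: 3.0, "acute_dhw": 1.0}, driver_data)
        with pytest.raises(KeyError, match="lack"):
            predict_bleached(model, pd.DataFrame({"par": [0.0]}))


class TestPartialRegression:
    def test_zero_coefficient_gives_flat_curve(self, driver_data):
        # par enters the model with coefficient ~0 via a tiny epsilon response
        beta = {INTERCEPT: 4.0, "acute_dhw": 1.0, "par": 0.0}
        model = exact_model(beta, driver_data)
        pr = partial_regression(model, driver_data.assign(
            sqrt_pct_bleached=model.fitted), "par")
        assert np.ptp(pr.curve) == pytest.approx(0.0, abs=1e-9)

    def test_single_predictor_closed_form(self, driver_data):
        """Curve equals (b0 + b1 x)^2 minus the reduced intercept squared."""
        beta = {INTERCEPT: 4.0, "acute_dhw": 1.0}
        model = exact_model(beta, driver_data)
        data = driver_data.assign(sqrt_pct_bleached=model.fitted)
        pr = partial_regression(model, data, "acute_dhw")
        from reefbleach.model import fit_terms

        red = fit_terms(data, [INTERCEPT], "sqrt_pct_bleached")
        expected = np.clip(4.0 + 1.0 * pr.grid, 0, None) ** 2 - red.params[INTERCEPT] ** 2
        np.testing.assert_allclose(pr.curve, expected, atol=1e-9)

    def test_reduced_model_drops_driver_and_interactions(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 1.0, "bs_score": 0.5,
                "acute_dhw:bs_score": 0.2}
        model = exact_model(beta, driver_data)
        assert reduced_terms(model, "acute_dhw") == [INTERCEPT, "bs_score"]
        assert len(reduced_terms(model, "bs_score")) == len(model.terms) - 2

    def test_driver_not_in_model_rejected(self, driver_data):
        model = exact_model({INTERCEPT: 4.0, "acute_dhw": 1.0}, driver_data)
        data = driver_data.assign(sqrt_pct_bleached=model.fitted)
        with pytest.raises(ValueError, match="not a term"):
            partial_regression(model, data, "par")


class TestInteractionSurface:
    def test_zero_interaction_is_additive_on_sqrt_scale(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.5, "bs_score": 0.5,
                "acute_dhw:bs_score": 0.0}
        model = exact_model(beta, driver_data)
        surf = interaction_surface(model, driver_data, "acute_dhw", "bs_score", grid_n=5)
        s = np.sqrt(surf.surface)
        mixed = s[1:, 1:] - s[:-1, 1:] - s[1:, :-1] + s[:-1, :-1]
        np.testing.assert_allclose(mixed, 0.0, atol=1e-9)

    def test_mixed_difference_closed_form(self, driver_data):
        """Corner contrast on the sqrt scale equals 4 * beta_ab for a 2-unit box."""
        beta = {INTERCEPT: 3.0, "acute_dhw": 1.0, "bs_score": 1.0,
                "acute_dhw:bs_score": 1.0}
        model = exact_model(beta, driver_data)
        rows = pd.DataFrame(
            {"acute_dhw": [0.0, 2.0, 0.0, 2.0], "bs_score": [0.0, 0.0, 2.0, 2.0]}
        )
        sqrt_pred = model.predict_sqrt(rows)
        mixed = sqrt_pred[3] - sqrt_pred[1] - sqrt_pred[2] + sqrt_pred[0]
        assert mixed == pytest.approx(4.0 * beta["acute_dhw:bs_score"], abs=1e-9)

    def test_symmetric_under_swap(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.5, "bs_score": 0.3,
                "acute_dhw:bs_score": 0.2}
        model = exact_model(beta, driver_data)
        a = interaction_surface(model, driver_data, "acute_dhw", "bs_score", grid_n=7)
        b = interaction_surface(model, driver_data, "bs_score", "acute_dhw", grid_n=7)
        np.testing.assert_allclose(a.surface, b.surface.T, atol=1e-9)

    def test_absent_interaction_rejected(self, driver_data):
        model = exact_model({INTERCEPT: 4.0, "acute_dhw": 1.0, "par": 0.5}, driver_data)
        with pytest.raises(ValueError, match="interaction"):
            interaction_surface(model, driver_data, "acute_dhw", "par")


class TestPerturbation:
    def test_baseline_is_squared_intercept(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.7, "bs_score": -0.2,
                "acute_dhw:bs_score": 0.9}
        model = exact_model(beta, driver_data)
        table = perturb_model(model)
        np.testing.assert_allclose(table["baseline_pct_bleached"], 16.0, atol=1e-9)

    def test_single_driver_closed_form(self, driver_data):
        """(4 ± 1)^2: +1 SD gives 25.0, -1 SD gives 9.0."""
        model = exact_model({INTERCEPT: 4.0, "acute_dhw": 1.0}, driver_data)
        table = perturb_model(model).set_index(["driver", "direction"])
        assert table.loc[("acute_dhw", "+1sd"), "predicted_pct_bleached"] == pytest.approx(25.0, abs=1e-9)
        assert table.loc[("acute_dhw", "-1sd"), "predicted_pct_bleached"] == pytest.approx(9.0, abs=1e-9)

    def test_absent_driver_perturbation_is_baseline(self, driver_data):
        model = exact_model({INTERCEPT: 4.0, "acute_dhw": 1.0}, driver_data)
        table = perturb_model(model, drivers=["acute_dhw", "par"]).set_index(
            ["driver", "direction"]
        )
        assert table.loc[("par", "+1sd"), "predicted_pct_bleached"] == pytest.approx(16.0, abs=1e-9)

    def test_no_interaction_deltas_equal_beta_on_sqrt_scale(self, driver_data):
        beta = {INTERCEPT: 5.0, "acute_dhw": 0.8, "par": -0.3}
        model = exact_model(beta, driver_data)
        table = perturb_model(model).set_index(["driver", "direction"])
        for d in ("acute_dhw", "par"):
            up = np.sqrt(table.loc[(d, "+1sd"), "predicted_pct_bleached"])
            assert up - 5.0 == pytest.approx(beta[d], abs=1e-9)


class TestManagementScenario:
    def test_dominant_driver_always_chosen(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.5, "urban_runoff": 0.8}
        model = exact_model(beta, driver_data)
        out = management_scenario(model, driver_data,
                                  manageable=("urban_runoff", "par", "bs_score"))
        assert (out["best_action"] == "urban_runoff").all()

    def test_matches_exhaustive_oracle(self, driver_data):
        """Per-cell best action agrees with brute-force evaluation of actions."""
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.6, "bs_score": 0.5, "par": 0.3,
                "urban_runoff": 0.4, "acute_dhw:bs_score": 0.7,
                "acute_dhw:urban_runoff": -0.5}
        model = exact_model(beta, driver_data)
        manageable = ("bs_score", "par", "urban_runoff")
        out = management_scenario(model, driver_data, manageable=manageable)
        dhw_fixed = out["dhw_fixed"].iloc[0]
        for i in range(len(driver_data)):
            preds = {}
            for action in manageable:
                row = driver_data.iloc[[i]][model_drivers(model)].copy()
                row["acute_dhw"] = dhw_fixed
                row[action] = row[action] - 1.0
                preds[action] = float(predict_bleached(model, row)[0])
            best = min(sorted(preds), key=lambda a: preds[a])
            assert out["best_action"].iloc[i] == best

    def test_quantile_matching_cell_keeps_ordinary_prediction(self, driver_data):
        beta = {INTERCEPT: 4.0, "acute_dhw": 0.5, "par": 0.2}
        model = exact_model(beta, driver_data)
        out = management_scenario(model, driver_data, manageable=("par",))
        dhw_fixed = out["dhw_fixed"].iloc[0]
        # the cell whose observed DHW equals the fixed quantile is unchanged
        idx = (driver_data["acute_dhw"] - dhw_fixed).abs().idxmin()
        ordinary = predict_bleached(
            model, driver_data.loc[[idx], model_drivers(model)].assign(acute_dhw=dhw_fixed)
        )[0]
        assert out.loc[idx, "baseline_pct_bleached"] == pytest.approx(ordinary, abs=1e-9)

    def test_empty_manageable_list_rejected(self, driver_data):
        model = exact_model({INTERCEPT: 4.0, "acute_dhw": 0.5}, driver_data)
        with pytest.raises(ValueError, match="empty"):
            management_scenario(model, driver_data, manageable=())

    def test_alphabetical_tie_break(self, driver_data):
        # two manageable drivers with identical coefficients tie everywhere
        beta = {INTERCEPT: 4.0, "bs_score": 0.5, "par": 0.5}
        model = exact_model(beta, driver_data)
        out = management_scenario(model, driver_data, manageable=("par", "bs_score"))
        assert (out["best_action"] == "bs_score").all()
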
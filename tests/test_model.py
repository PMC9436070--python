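"""Weighted least squares, backward-BIC selection, weighted ANOVA and LMM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from reefbleach.model import (
    INTERCEPT,
    ModelSpec,
    build_design,
    candidate_terms,
    fit_terms,
    fit_weighted_lmm,
    lmm_lrt_table,
    retain_shared_strata,
    stepwise_bic,
    term_parents,
    weighted_anova_oneway,
    weighted_anova_twoway,
    wls_fit,
)


def toy_system(rng, n=6, k=2):
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    X.insert(0, INTERCEPT, 1.0)
    beta = rng.normal(size=k + 1)
    y = X.to_numpy() @ beta + rng.normal(scale=0.1, size=n)
    w = rng.uniform(0.2, 1.0, size=n)
    return X, y, w


class TestWls:
    def test_equal_weights_match_ols(self, rng):
        X, y, _ = toy_system(rng, n=30)
        w = np.full(30, 0.37)
        fit = wls_fit(X, y, w)
        ols = sm.OLS(y, X.to_numpy()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """beta equals (X'WX)^-1 X'Wy computed directly."""
        for _ in range(20):
            X, y, w = toy_system(rng)
            Xm = X.to_numpy()
            W = np.diag(w)
            beta = np.linalg.solve(Xm.T @ W @ Xm, Xm.T @ W @ y)
            fit = wls_fit(X, y, w)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_row_splitting_weight_additivity(self, rng):
        """A row duplicated at half weight is equivalent to the single row."""
        X, y, w = toy_system(rng, n=8)
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        y2 = np.append(y, y[0])
        w2 = np.append(w.copy(), w[0] / 2)
        w2[0] = w[0] / 2
        a = wls_fit(X, y, w)
        b = wls_fit(X2, y2, w2)
        np.testing.assert_allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-10)

    def test_rank_deficiency_names_aliased_term(self, rng):
        X, y, w = toy_system(rng, n=20)
        X["x_dup"] = X["x0"]
        with pytest.raises(ValueError, match="aliased"):
            wls_fit(X, y, w)

    def test_nonpositive_weights_rejected(self, rng):
        X, y, w = toy_system(rng)
        w[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            wls_fit(X, y, w)

    def test_predict_reproduces_fitted_values(self, rng):
        n = 50
        data = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "weight": rng.uniform(0.2, 1, n),
        })
        data["sqrt_pct_bleached"] = 1 + data["x1"] - data["x2"] + rng.normal(size=n)
        fit = fit_terms(data, [INTERCEPT, "x1", "x2", "x1:x2"], "sqrt_pct_bleached")
        np.testing.assert_allclose(fit.predict_sqrt(data), fit.fitted, atol=1e-9)
        assert fit.adj_r2 <= 1.0


class TestCandidateTerms:
    def test_interaction_structure(self):
        terms = candidate_terms(["acute_dhw", "bs_score", "par"])
        assert "acute_dhw:par" in terms
        assert "bs_score:par" in terms
        assert "acute_dhw:bs_score" in terms
        assert term_parents("acute_dhw:par") == ("acute_dhw", "par")

    def test_marginality_of_design_builder(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        design = build_design(data, [INTERCEPT, "a", "b", "a:b"])
        np.testing.assert_allclose(design["a:b"], data["a"] * data["b"])


def _noise_data(rng, n, k):
    data = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    data["sqrt_pct_bleached"] = rng.normal(size=n)
    data["weight"] = 1.0
    return data


class TestStepwise:
    def test_marginality_never_violated_and_locally_optimal(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 150
            data = pd.DataFrame(r.normal(size=(n, 3)), columns=["a", "b", "c"])
            data["sqrt_pct_bleached"] = (
                data["a"] - data["b"] + 0.8 * data["a"] * data["b"] + r.normal(0, 0.5, n)
            )
            data["weight"] = 1.0
            spec = ModelSpec(drivers=["a", "b", "c"], anchors=("a", "b"))
            fit = stepwise_bic(spec, data)
            for t in fit.terms:
                for parent in term_parents(t):
                    assert parent in fit.terms
            # no single eligible removal lowers BIC
            from reefbleach.model import _eligible_for_removal

            for t in _eligible_for_removal(fit.terms):
                trial = fit_terms(data, [x for x in fit.terms if x != t],
                                  "sqrt_pct_bleached")
                assert trial.bic >= fit.bic - 1e-9

    def test_bic_of_selected_never_exceeds_full(self, rng):
        data = _noise_data(rng, 200, 4)
        spec = ModelSpec(drivers=["x0", "x1", "x2", "x3"], anchors=("x0",))
        full = fit_terms(data, spec.terms(), "sqrt_pct_bleached")
        fit = stepwise_bic(spec, data)
        assert fit.bic <= full.bic + 1e-12

    def test_pure_noise_mostly_selects_intercept_only(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = _noise_data(rng, 300, 4)
            spec = ModelSpec(drivers=["x0", "x1", "x2", "x3"], anchors=())
            fit = stepwise_bic(spec, data)
            hits += fit.terms == [INTERCEPT]
        assert hits >= int(0.7 * n_seeds)

    def test_recovers_true_interaction_support(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 300
            data = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x1", "x2"])
            data["sqrt_pct_bleached"] = (
                data["x1"] + data["x2"] + data["x1"] * data["x2"]
                + rng.normal(0, 0.5, n)
            )
            data["weight"] = 1.0
            spec = ModelSpec(drivers=["x1", "x2"], anchors=("x1",))
            fit = stepwise_bic(spec, data)
            hits += sorted(fit.terms) == [INTERCEPT, "x1", "x1:x2", "x2"]
        assert hits >= int(0.9 * n_seeds)


class TestWeightedAnova:
    def test_identical_groups_give_null_f(self, rng):
        y = np.tile(rng.normal(size=10), 2)
        groups = np.repeat(["a", "b"], 10)
        res = weighted_anova_oneway(y, np.ones(20), groups)
        assert res.f == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_equal_weights_match_textbook_anova(self):
        """Hand-computed 3-group one-way ANOVA table."""
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        groups = np.repeat(["g1", "g2", "g3"], 3)
        res = weighted_anova_oneway(y, np.ones(9), groups)
        f_scipy, p_scipy = stats.f_oneway(y[:3], y[3:6], y[6:])
        assert res.f == pytest.approx(f_scipy, rel=1e-10)
        assert res.p == pytest.approx(p_scipy, rel=1e-8)

    def test_tukey_table_symmetric_in_group_order(self, rng):
        y = rng.normal(size=30)
        w = rng.uniform(0.3, 1.0, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = weighted_anova_oneway(y, w, groups)
        tab = res.tukey.set_index(["group_a", "group_b"])
        # all unordered pairs present exactly once, p-values in [0,1]
        assert len(tab) == 3
        assert ((res.tukey["p"] >= 0) & (res.tukey["p"] <= 1)).all()

    def test_singleton_group_dropped(self, rng):
        y = rng.normal(size=21)
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
        res = weighted_anova_oneway(y, np.ones(21), groups)
        assert {"a", "b"} == set(res.tukey[["group_a", "group_b"]].values.ravel())


def _temporal_cells(rng, n_zone=4, n_per=6, year_effect=0.0):
    rows = []
    for year in (2015, 2019):
        for z in range(n_zone):
            island = f"isl{z % 2}"
            for i in range(n_per):
                rows.append({
                    "year": year, "zone": f"z{z}", "island": island,
                    "depth_bin": "shallow",
                    "sqrt_pct_bleached": 3.0 + 0.3 * z
                    + (year_effect if year == 2019 else 0.0)
                    + rng.normal(0, 0.3),
                    "weight": rng.uniform(0.4, 1.0),
                })
    return pd.DataFrame(rows)


class TestTemporal:
    def test_identical_years_give_zero_year_chi2(self, rng):
        cells = _temporal_cells(rng)
        dup = cells[cells["year"] == 2015].copy()
        dup["year"] = 2019
        data = pd.concat([cells[cells["year"] == 2015], dup], ignore_index=True)
        table = lmm_lrt_table(data).set_index("effect")
        assert table.loc["year", "chi2"] == pytest.approx(0.0, abs=1e-4)
        assert (table["chi2"] >= 0).all()

    def test_zero_random_variance_reduces_to_wls(self, rng):
        """With no island-level variance the LMM fixed effects match WLS."""
        n = 80
        X = pd.DataFrame({INTERCEPT: 1.0, "x": rng.normal(size=n)})
        groups = np.repeat(["a", "b", "c", "d"], n // 4)
        noise = rng.normal(0, 0.4, n)
        # remove all between-group signal so the variance estimate hits 0
        noise -= pd.Series(noise).groupby(pd.Series(groups)).transform("mean").to_numpy()
        y = 2.0 + 0.5 * X["x"].to_numpy() + noise
        w = rng.uniform(0.3, 1.0, n)
        lmm = fit_weighted_lmm(y, X, groups, w)
        wls = sm.WLS(y, X.to_numpy(), weights=w).fit()
        np.testing.assert_allclose(lmm.params.to_numpy(), wls.params, atol=1e-4)

    def test_lrt_detects_injected_year_effect(self, rng):
        cells = _temporal_cells(rng, year_effect=1.0)
        table = lmm_lrt_table(cells).set_index("effect")
        assert table.loc["year", "chi2"] > 10
        assert table.loc["year", "p"] < 0.001

    def test_shared_strata_filter(self):
        cells = pd.DataFrame({
            "year": [2015, 2015, 2019],
            "zone": ["z1", "z2", "z1"],
            "depth_bin": ["shallow"] * 3,
        })
        kept = retain_shared_strata(cells)
        assert set(kept["zone"]) == {"z1"}

    def test_two_way_anova_matches_statsmodels(self, rng):
        cells = _temporal_cells(rng, year_effect=0.5).rename(columns={"zone": "island2"})
        cells["island"] = cells["island2"]
        table = weighted_anova_twoway(cells, factor_a="year", factor_b="island")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.wls("sqrt_pct_bleached ~ C(year) * C(island)", data=cells,
                      weights=cells["weight"]).fit()
        ref = anova_lm(fit, typ=2)
        got = table.set_index("effect")
        assert got.loc["year", "F"] == pytest.approx(ref.loc["C(year)", "F"], rel=1e-6)
        assert got.loc["island", "F"] == pytest.approx(ref.loc["C(island)", "F"], rel=1e-6)
        assert got.loc["year:island", "F"] == pytest.approx(
            ref.loc["C(year):C(island)", "F"], rel=1e-6
        )
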
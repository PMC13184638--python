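"""First-stage NB-GAM: design construction, fitting, knot selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from droughtmeta.stage1 import (CountyEstimate, CountyNBGAM, build_design,
                                fit_nb_gam, national_modal_knots, select_knots,
                                spline_basis)

from conftest import make_county_frame
from oracles import grid_search_mle


class TestSplineBasis:
    @pytest.mark.parametrize("df", [1, 2, 3, 4, 5, 6])
    def test_column_count_equals_df(self, df):
        x = np.linspace(0, 1, 50)
        assert spline_basis(x, df).shape == (50, df)

    def test_constant_input_collapses(self):
        assert spline_basis(np.full(30, 5.0), 4).shape == (30, 0)


class TestBuildDesign:
    def test_column_count_formula(self):
        labels = np.array((["NONE"] * 40 + ["M2SD_WRS"] * 4 + ["S2ED_WRS"] * 4 +
                           ["S2ED_IMP"] * 4 + ["M2SD_IMP"] * 4 + ["WET"] * 8) * 4,
                          dtype=object)
        panel = make_county_frame(len(labels), labels=labels)
        d = build_design(panel, temp_knots=4, time_knots=4)
        # intercept + 5 exposure dummies + 3 seasons + 4 temp + 4 time
        assert d.X.shape[1] == 1 + 5 + 3 + 4 + 4
        assert d.excluded_categories == []

    def test_absent_level_recorded(self):
        panel = make_county_frame(60)  # all NONE
        d = build_design(panel, 3, 3)
        assert set(d.excluded_categories) == {"M2SD_WRS", "S2ED_WRS",
                                              "S2ED_IMP", "M2SD_IMP", "WET"}
        assert d.exposure_cols == {}

    def test_constant_temperature_collapses_and_flags(self):
        panel = make_county_frame(60)
        panel["temperature"] = 10.0
        d = build_design(panel, 4, 3)
        assert "s(temperature)" in d.dropped_collinear
        assert not any(c.startswith("s(temperature).") for c in d.colnames)

    def test_positive_population_required(self):
        panel = make_county_frame(24)
        panel.loc[0, "population"] = 0
        with pytest.raises(ValueError):
            build_design(panel, 3, 3)


class TestFitNBGAM:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        n, pop = 120, 40_000.0
        y = rng.poisson(3.0, n)
        X = np.ones((n, 1))
        offset = np.full(n, np.log(pop))
        fit = fit_nb_gam(X, y, offset)
        # equal offsets: the rate MLE is the total-deaths / total-person-time ratio
        assert fit.params[0] == pytest.approx(np.log(y.sum() / (n * pop)), abs=1e-5)

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        panel = make_county_frame(228, seed=1)
        X = np.column_stack([np.ones(228), (panel["month_index"] - 114) / 100])
        offset = np.log(panel["population"].to_numpy())
        mu = np.exp(X @ np.array([-9.0, 0.3]) + offset)
        y = rng.poisson(mu)
        fit = fit_nb_gam(X, y, offset)
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        # the profile is flat near the boundary, so alpha lands somewhere
        # small; coefficients are then indistinguishable from Poisson
        assert fit.alpha < 0.02
        np.testing.assert_allclose(fit.params, pois.params, atol=5e-3)

    def test_matches_grid_search_oracle(self):
        """Tiny instance: MLE agrees with brute-force likelihood maximisation."""
        rng = np.random.default_rng(2)
        n = 18
        x = np.linspace(-1, 1, n)
        X = np.column_stack([np.ones(n), x])
        offset = np.log(np.full(n, 1000.0))
        mu = np.exp(X @ np.array([-3.0, 0.8]) + offset)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        fit = fit_nb_gam(X, y, offset)
        alpha_grid = np.geomspace(0.05, 2.0, 25)
        beta_g, alpha_g, ll_g = grid_search_mle(y, X, offset, -6, 3, alpha_grid)
        np.testing.assert_allclose(fit.params, beta_g, atol=0.01)
        assert fit.llf >= ll_g - 1e-3  # true MLE cannot be beaten by the grid

    def test_offset_contract(self):
        rng = np.random.default_rng(3)
        labels = np.array((["NONE"] * 10 + ["M2SD_WRS"] * 2) * 19, dtype=object)
        panel = make_county_frame(228, labels=labels, seed=3)
        d = build_design(panel, 3, 3)
        mu = np.exp(-9.0 + 0.2 * (panel["exposure_label"] == "M2SD_WRS")) * \
            panel["population"].to_numpy()
        y = rng.negative_binomial(5.0, 5.0 / (5.0 + mu))
        f1 = fit_nb_gam(d.X, y, d.offset)
        f2 = fit_nb_gam(d.X, y, d.offset + np.log(7.0))
        assert f2.params[0] == pytest.approx(f1.params[0] - np.log(7.0), abs=1e-4)
        np.testing.assert_allclose(f2.params[1:], f1.params[1:], atol=1e-4)

    def test_added_columns_never_reduce_loglik(self):
        rng = np.random.default_rng(4)
        panel = make_county_frame(120, seed=4)
        d = build_design(panel, 2, 3)
        y = rng.poisson(2.0, 120)
        base = fit_nb_gam(d.X, y, d.offset)
        extra = np.column_stack([d.X, rng.normal(size=120)])
        bigger = fit_nb_gam(extra, y, d.offset)
        assert bigger.llf >= base.llf - 1e-6

    def test_all_zero_counts_flagged(self):
        fit = fit_nb_gam(np.ones((24, 1)), np.zeros(24, dtype=int), np.zeros(24))
        assert not fit.converged

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_gam(np.ones((5, 1)), np.array([1.5, 0, 0, 1, 2]), np.zeros(5))


class TestKnotSelection:
    def test_sixteen_fits_attempted(self, small_panel):
        county = small_panel[small_panel["county_id"] ==
                             small_panel["county_id"].iloc[0]]
        est = select_knots(county, "deaths_firearm", county_id="c")
        assert est.n_fits == 16
        assert est.converged
        assert est.chosen_knots in est.aic_table
        assert est.aic == pytest.approx(min(est.aic_table.values()))

    def test_tie_breaks_prefer_parsimony(self):
        """Constant temperature makes every k_temp give the same design, so
        AIC ties exactly and the smallest k_temp must win."""
        rng = np.random.default_rng(5)
        panel = make_county_frame(120, seed=5)
        panel["temperature"] = 15.0
        panel["deaths"] = rng.poisson(2.0, len(panel))
        est = select_knots(panel, "deaths", county_id="c")
        assert est.chosen_knots[0] == 2

    def test_curved_temperature_effect_prefers_more_knots(self):
        """A cubic temperature-rate curve should push k_temp above 2."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            panel = make_county_frame(228, population=200_000.0, seed=seed)
            t = (panel["temperature"].to_numpy() - 12) / 10
            mu = np.exp(-8.5 + 1.2 * t**3 - 0.8 * t) * panel["population"].to_numpy()
            panel["deaths"] = rng.poisson(mu)
            est = select_knots(panel, "deaths", county_id="c")
            hits += est.chosen_knots[0] >= 3
        assert hits >= 3

    def test_modal_knots(self):
        def est(pair):
            return CountyEstimate(county_id="x", outcome="o", stratum="s",
                                  estimates={}, aic=1.0, chosen_knots=pair,
                                  converged=True)
        modal, tab = national_modal_knots([est((4, 4)), est((4, 4)), est((2, 3))])
        assert modal == [(4, 4)]
        assert tab["n_counties"].sum() == 3
        modal, _ = national_modal_knots([est((4, 4)), est((2, 3))])
        assert modal == [(2, 3), (4, 4)]  # tie reports all pairs
        modal, _ = national_modal_knots([est((5, 6))])
        assert modal == [(5, 6)]
        with pytest.raises(ValueError):
            national_modal_knots([CountyEstimate(county_id="x", outcome="o",
                                                 stratum="s", estimates={},
                                                 aic=np.nan, chosen_knots=(np.nan,) * 2,
                                                 converged=False)])


class TestCountyNBGAMEstimator:
    def test_fit_and_predict(self, small_panel):
        county = small_panel[small_panel["county_id"] ==
                             small_panel["county_id"].iloc[0]]
        m = CountyNBGAM(count_col="deaths_firearm", temp_grid=(3,), time_grid=(4,))
        m.fit(county)
        assert m.converged_
        irr = m.predict(county)
        assert np.all(irr > 0)
        assert np.allclose(irr[county["exposure_label"].to_numpy() == "NONE"], 1.0)

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="missing required columns"):
            CountyNBGAM().fit(pd.DataFrame({"deaths_firearm": [1, 2]}))

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        m = CountyNBGAM(temp_grid=(2,), time_grid=(3,))
        params = m.get_params()
        assert params["temp_grid"] == (2,)
        m2 = clone(m).set_params(count_col="deaths_nonfirearm")
        assert m2.get_params()["count_col"] == "deaths_nonfirearm"
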
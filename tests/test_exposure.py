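"""Logistic-exposure model tests: interval construction, closed forms,
grid-search and standard-logistic oracles, and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from steppebird.exposure import (LogisticExposureModel, apparent_success,
                                 build_exposure_intervals,
                                 failure_cause_breakdown, interval_loglik,
                                 model_selection_table, seasonal_survival)
from tests.conftest import make_histories


def _visits(rows):
    return pd.DataFrame(rows, columns=["nest_id", "plot_id", "year",
                                       "species", "visit_day", "stage",
                                       "status", "cause"])


class TestBuildIntervals:
    def test_failure_history_decomposes(self):
        v = _visits([
            ("N1", "P1", 2016, "sp", 0, "egg", "active", ""),
            ("N1", "P1", 2016, "sp", 3, "egg", "active", ""),
            ("N1", "P1", 2016, "sp", 6, "egg", "failed", "predation"),
        ])
        iv = build_exposure_intervals(v)
        assert len(iv) == 2
        assert list(iv["t"]) == [3.0, 3.0]
        assert list(iv["survived"]) == [1, 0]
        assert list(iv["stage"]) == ["egg", "egg"]

    def test_success_terminal(self):
        v = _visits([
            ("N1", "P1", 2016, "sp", 0, "egg", "active", ""),
            ("N1", "P1", 2016, "sp", 4, "nestling", "fledged", ""),
        ])
        iv = build_exposure_intervals(v)
        assert len(iv) == 1
        assert iv["t"].iloc[0] == 4.0 and iv["survived"].iloc[0] == 1

    def test_single_visit_dropped_with_warning(self):
        v = _visits([("N1", "P1", 2016, "sp", 0, "egg", "active", "")])
        with pytest.warns(UserWarning, match="single-visit"):
            iv = build_exposure_intervals(v)
        assert iv.empty

    def test_nonmonotone_dates_name_the_nest(self):
        v = _visits([
            ("BAD", "P1", 2016, "sp", 5, "egg", "active", ""),
            ("BAD", "P1", 2016, "sp", 2, "egg", "failed", ""),
        ])
        with pytest.raises(ValueError, match="BAD"):
            build_exposure_intervals(v)

    def test_midpoint_halves_failed_exposure(self):
        v = _visits([
            ("N1", "P1", 2016, "sp", 0, "egg", "active", ""),
            ("N1", "P1", 2016, "sp", 4, "egg", "failed", ""),
        ])
        assert build_exposure_intervals(v)["t"].iloc[0] == 4.0
        assert build_exposure_intervals(v, midpoint=True)["t"].iloc[0] == 2.0


class TestIntervalLoglik:
    @pytest.mark.parametrize("y,t,theta,expected", [
        (1, 3, 0.9, math.log(0.9 ** 3)),
        (0, 2, 0.5, math.log(0.75)),
        (1, 17, 1.0, 0.0),
    ])
    def test_closed_forms(self, y, t, theta, expected):
        assert interval_loglik(y, t, theta) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            interval_loglik(1, 3, 1.5)
        with pytest.raises(ValueError):
            interval_loglik(1, 0, 0.9)


class TestSeasonalSurvival:
    def test_worked_example(self):
        # DSR 0.81 over a 15-day vesper-sparrow nesting period -> 4.2%
        assert seasonal_survival(0.81, 15) == pytest.approx(0.0424, abs=5e-4)

    def test_certain_survival(self):
        assert seasonal_survival(1.0, 100) == 1.0

    def test_nineteen_day_power(self):
        assert seasonal_survival(0.90, 19) == pytest.approx(0.1351, abs=5e-5)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0),
           st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_dsr_and_period(self, d1, d2, p1, p2):
        lo_d, hi_d = sorted((d1, d2))
        lo_p, hi_p = sorted((p1, p2))
        assert seasonal_survival(lo_d, lo_p) <= seasonal_survival(hi_d, lo_p)
        assert seasonal_survival(hi_d, hi_p) <= seasonal_survival(hi_d, lo_p)


class TestDescriptives:
    def test_apparent_success_counts(self):
        h = make_histories(n_fledged=66, n_failed=46, n_predation=35)
        out = apparent_success(h)
        assert out["n_fledged"] == 66 and out["n_total"] == 112
        assert out["fraction"] == pytest.approx(66 / 112)

    def test_zero_success(self):
        h = make_histories(n_fledged=0, n_failed=5, n_predation=5)
        assert apparent_success(h)["fraction"] == 0.0

    def test_censored_excluded_by_default(self):
        h = make_histories(n_fledged=3, n_failed=1, n_predation=1)
        censored = _visits([
            ("C1", "P1", 2016, "sp", 0, "egg", "active", ""),
            ("C1", "P1", 2016, "sp", 3, "egg", "active", ""),
        ])
        out = apparent_success(pd.concat([h, censored]))
        assert out["n_total"] == 4
        out2 = apparent_success(pd.concat([h, censored]),
                                include_censored=True)
        assert out2["n_total"] == 5

    def test_failure_cause_fractions(self):
        h = make_histories(n_fledged=10, n_failed=46, n_predation=35)
        tab = failure_cause_breakdown(h)
        pred = tab.set_index("cause").loc["predation"]
        assert pred["count"] == 35
        assert pred["fraction"] == pytest.approx(35 / 46)
        assert tab["fraction"].sum() == pytest.approx(1.0)

    def test_unlabelled_failures_bucketed(self):
        v = _visits([
            ("N1", "P1", 2016, "sp", 0, "egg", "active", ""),
            ("N1", "P1", 2016, "sp", 3, "egg", "failed", ""),
        ])
        tab = failure_cause_breakdown(v)
        assert list(tab["cause"]) == ["unknown"]
        assert tab["fraction"].iloc[0] == 1.0


class TestFit:
    def test_binomial_mle_exact(self):
        # 10 one-day intervals, 9 survived: theta-hat = 0.9 exactly
        iv = pd.DataFrame({"survived": [1] * 9 + [0], "t": [1.0] * 10})
        res = LogisticExposureModel(iv, "~ 1").fit()
        assert expit(res.beta[0]) == pytest.approx(0.9, abs=1e-7)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 5, 300).astype(float)
        y = (rng.random(300) < 0.92 ** t).astype(int)
        iv = pd.DataFrame({"survived": y, "t": t})
        res = LogisticExposureModel(iv, "~ 1").fit()
        grid = np.linspace(0.6, 0.999, 8000)
        ll = np.array([
            sum(interval_loglik(yi, ti, th) for yi, ti in zip(y, t))
            for th in grid])
        theta_grid = grid[int(np.argmax(ll))]
        assert expit(res.beta[0]) == pytest.approx(theta_grid, abs=1e-4)

    def test_t_equal_one_reduces_to_logistic_regression(self):
        # with every exposure = 1 day the model is ordinary logistic
        # regression; statsmodels Logit is the independent oracle
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        y = (rng.random(500) < expit(1.0 + 0.7 * x)).astype(int)
        iv = pd.DataFrame({"survived": y, "t": 1.0, "x": x})
        res = LogisticExposureModel(iv, "~ x").fit()
        sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(res.beta, sm_fit.params, atol=1e-6)
        assert res.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_recovers_coefficients_with_plot_effect(self):
        rng = np.random.default_rng(17)
        n_plots, per = 40, 60
        plots = np.repeat([f"P{i}" for i in range(n_plots)], per)
        u = np.repeat(rng.normal(0, 0.4, n_plots), per)
        stage = rng.integers(0, 2, n_plots * per)
        theta = expit(1.5 + 0.8 * stage + u)
        t = np.full(n_plots * per, 3.0)
        y = (rng.random(n_plots * per) < theta ** t).astype(int)
        iv = pd.DataFrame({"survived": y, "t": t, "stage_ind": stage,
                           "plot_id": plots})
        res = LogisticExposureModel(iv, "~ stage_ind",
                                    random_plot=True).fit()
        for est, se, truth in zip(res.beta, res.bse[:2], (1.5, 0.8)):
            assert abs(est - truth) < 3 * se
        assert 0.1 < res.random_sd < 0.8

    def test_zero_plot_variance_estimated_near_zero(self):
        rng = np.random.default_rng(23)
        n = 3000
        plots = np.repeat([f"P{i}" for i in range(30)], n // 30)
        theta = expit(2.0)
        t = np.full(n, 3.0)
        y = (rng.random(n) < theta ** t).astype(int)
        iv = pd.DataFrame({"survived": y, "t": t, "plot_id": plots})
        res = LogisticExposureModel(iv, "~ 1", random_plot=True).fit()
        assert res.random_sd < 0.05

    def test_dsr_predictions_in_unit_interval(self, small_dataset):
        visits = small_dataset["nest_visits"]
        visits = visits[(visits["discovery"] != "none")
                        & (visits["species"] == "vesper_sparrow")]
        iv = build_exposure_intervals(visits)
        res = LogisticExposureModel(iv, "~ stage").fit()
        dsr = res.predict_dsr()
        assert np.all((dsr > 0) & (dsr < 1))
        assert 0.0 <= res.seasonal_survival(15) <= 1.0

    def test_rank_deficiency_reported(self):
        iv = pd.DataFrame({"survived": [1, 0, 1, 1], "t": 1.0,
                           "a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            LogisticExposureModel(iv, "~ a + b")


def test_model_selection_table_weights():
    iv = pd.DataFrame({"survived": [1] * 40 + [0] * 10, "t": 2.0,
                       "x": np.linspace(0, 1, 50)})
    fits = [LogisticExposureModel(iv, f).fit() for f in ("~ 1", "~ x")]
    tab = model_selection_table(fits)
    assert tab["weight"].sum() == pytest.approx(1.0)
    assert (tab["delta_aicc"] >= 0).all()
    # a 2-point AICc gap corresponds to weight ratio e
    gap = tab["delta_aicc"].iloc[1]
    ratio = tab["weight"].iloc[0] / tab["weight"].iloc[1]
    assert ratio == pytest.approx(math.exp(gap / 2), rel=1e-9)
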
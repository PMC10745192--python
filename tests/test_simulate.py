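"""Generator tests: exact contracts, determinism, and Monte-Carlo
agreement with closed-form or quadrature oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from steppebird.config import (ConfigurationError, DetectionConfig,
                               GeometryConfig, SimulationConfig,
                               SpeciesConfig)
from steppebird.simulate import (generate_plots, simulate_dataset,
                                 simulate_ddo_counts,
                                 simulate_nest_histories,
                                 simulate_nest_survey, truth_table)


def _cfg(**kw):
    base = dict(seed=1, n_plots=4, years=[2016],
                species=[SpeciesConfig("sp", nest_density=5.0)])
    base.update(kw)
    return SimulationConfig(**base)


class TestGeneratePlots:
    def test_enrollment_split_half(self):
        plots = generate_plots(_cfg(n_plots=80, prop_enrolled=0.5))
        per_year = plots.groupby("year")["enrollment"]
        assert (per_year.apply(lambda s: (s == "SGI").sum()) == 40).all()
        assert (per_year.apply(lambda s: (s == "non-SGI").sum()) == 40).all()

    def test_zero_enrollment_boundary(self):
        plots = generate_plots(_cfg(n_plots=2, prop_enrolled=0.0))
        assert (plots["enrollment"] == "non-SGI").all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(n_plots=1)
        with pytest.raises(ConfigurationError):
            _cfg(prop_enrolled=1.5)

    def test_shrub_cover_is_a_proportion(self):
        plots = generate_plots(_cfg(n_plots=50))
        assert plots["shrub_cover"].between(0, 1).all()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg_a = _cfg(seed=99)
        cfg_b = _cfg(seed=99)
        da = simulate_dataset(cfg_a)
        db = simulate_dataset(cfg_b)
        for name in da:
            pd.testing.assert_frame_equal(da[name], db[name])

    def test_different_seed_differs(self):
        da = simulate_dataset(_cfg(seed=1, n_plots=10))
        db = simulate_dataset(_cfg(seed=2, n_plots=10))
        assert not da["plots"].equals(db["plots"])


class TestNestSurvey:
    def test_perfect_detection_finds_every_nest(self):
        cfg = _cfg(
            detection=DetectionConfig(nest_key="uniform"),
            geometry=GeometryConfig(strip_half_width=50.0,
                                    rounds_per_season=1))
        plots = generate_plots(cfg)
        det, latent = simulate_nest_survey(plots, cfg)
        assert set(det["nest_id"]) == set(latent["nest_id"])

    def test_zero_density_no_nests(self):
        cfg = _cfg(species=[SpeciesConfig("sp", nest_density=0.0)])
        det, latent = simulate_nest_survey(generate_plots(cfg), cfg)
        assert latent.empty and det.empty

    def test_detection_fraction_matches_quadrature(self):
        # half-normal sigma=6, w=25: P(detect | in strip) should match
        # the numeric integral of g over the strip divided by w
        sigma, w = 6.0, 25.0
        cfg = _cfg(
            n_plots=40, seed=3,
            species=[SpeciesConfig("sp", nest_density=80.0)],
            detection=DetectionConfig(nest_key="half-normal",
                                      nest_scale=sigma),
            geometry=GeometryConfig(strip_half_width=w,
                                    rounds_per_season=1))
        plots = generate_plots(cfg)
        det, latent = simulate_nest_survey(plots, cfg)
        in_strip = latent[latent["distance_m"] <= w]
        n = len(in_strip)
        assert n > 1000
        frac = in_strip["detected"].mean()
        expected, _ = integrate.quad(
            lambda x: np.exp(-x ** 2 / (2 * sigma ** 2)), 0, w)
        expected /= w
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * mc_se


class TestNestHistories:
    def test_certain_survival_always_fledges(self):
        cfg = _cfg(species=[SpeciesConfig("sp", nest_density=10.0,
                                          dsr_egg=1.0, dsr_nestling=1.0)])
        _, latent = simulate_nest_survey(generate_plots(cfg), cfg)
        _, fates = simulate_nest_histories(latent, cfg)
        assert fates["fledged"].all()

    def test_fledging_fraction_matches_power(self):
        # DSR 0.9 over a 19-day period: P(fledge) = 0.9^19
        cfg = _cfg(
            n_plots=60, seed=8,
            species=[SpeciesConfig("sp", nest_density=60.0, dsr_egg=0.9,
                                   dsr_nestling=0.9, nesting_period=19)])
        _, latent = simulate_nest_survey(generate_plots(cfg), cfg)
        _, fates = simulate_nest_histories(latent, cfg)
        n = len(fates)
        assert n > 2000
        expected = 0.9 ** 19
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(fates["fledged"].mean() - expected) < 3 * mc_se

    def test_visit_schedule_covers_period(self):
        # interval 3, period 15: a fledged nest accrues >= 5 visits
        cfg = _cfg(species=[SpeciesConfig("sp", nest_density=10.0,
                                          dsr_egg=1.0, dsr_nestling=1.0,
                                          nesting_period=15)],
                   geometry=GeometryConfig(visit_interval=3))
        _, latent = simulate_nest_survey(generate_plots(cfg), cfg)
        visits, _ = simulate_nest_histories(latent, cfg)
        per_nest = visits.groupby("nest_id").size()
        assert (per_nest >= 5).all()

    def test_stage_never_reverts(self):
        cfg = _cfg(n_plots=10)
        _, latent = simulate_nest_survey(generate_plots(cfg), cfg)
        visits, _ = simulate_nest_histories(latent, cfg)
        order = {"egg": 0, "nestling": 1}
        for _, grp in visits.groupby("nest_id"):
            s = grp.sort_values("visit_day")["stage"].map(order).to_numpy()
            assert (np.diff(s) >= 0).all()


class TestDDOCounts:
    def test_perfect_primary_leaves_nothing(self):
        cfg = _cfg(detection=DetectionConfig(p_observer=1.0))
        counts, _ = simulate_ddo_counts(generate_plots(cfg), cfg)
        assert (counts["x2"] == 0).all()

    def test_zero_abundance_all_zero(self):
        cfg = _cfg(species=[SpeciesConfig("sp", adult_density=0.0)])
        counts, _ = simulate_ddo_counts(generate_plots(cfg), cfg)
        assert (counts[["x1", "x2"]] == 0).all().all()

    def test_thinning_expectations(self):
        # lambda=10, p1=p2=0.5: E[x1]=5, E[x2]=2.5 (Poisson thinning)
        cfg = SimulationConfig(
            seed=12, n_plots=300, years=[2016],
            species=[SpeciesConfig("sp", adult_density=10.0)],
            detection=DetectionConfig(p_observer=0.5),
            geometry=GeometryConfig(adult_visits=4),
            adult_plot_sd=0.0)
        counts, _ = simulate_ddo_counts(generate_plots(cfg), cfg)
        n = len(counts)
        assert n >= 1000
        se1 = np.sqrt(5.0 / n)      # var of Poisson(5) mean
        se2 = np.sqrt(2.5 / n)
        assert abs(counts["x1"].mean() - 5.0) < 3 * se1
        assert abs(counts["x2"].mean() - 2.5) < 3 * se2

    def test_marginal_thinning_independence(self):
        # x1 and x2 are marginally independent Poissons; their sample
        # correlation over many cells should be near zero
        cfg = SimulationConfig(
            seed=13, n_plots=500, years=[2016],
            species=[SpeciesConfig("sp", adult_density=10.0)],
            detection=DetectionConfig(p_observer=0.5),
            adult_plot_sd=0.0)
        counts, _ = simulate_ddo_counts(generate_plots(cfg), cfg)
        r = np.corrcoef(counts["x1"], counts["x2"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(counts))


def test_truth_table_is_complete(small_config, small_dataset):
    truth = small_dataset["truth"]
    expected = (small_config.n_plots * len(small_config.years)
                * len(small_config.species))
    assert len(truth) == expected
    assert not truth.duplicated(["plot_id", "year", "species"]).any()
    # every downstream plot-year-species appears in the truth table
    for name in ("nest_detections", "ddo_counts"):
        keys = small_dataset[name][["plot_id", "year", "species"]]
        merged = keys.drop_duplicates().merge(
            truth, on=["plot_id", "year", "species"], how="left")
        assert merged["true_adult_lambda"].notna().all()
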
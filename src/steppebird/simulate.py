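"""Synthetic survey-data generator with a known truth table.

Emulates the data-generating processes the three estimators assume:

* plots with enrollment flags and biotic/abiotic covariates,
* line-transect nest surveys with distance-dependent detection,
* visit-based nest monitoring with stage-specific daily survival,
* dependent double-observer adult counts (primary tally, secondary-only
  tally) over Poisson plot abundance.

Every generator draws from its own RNG stream spawned from the master
seed, so adding one generator never perturbs another's draws, and the
seed fully determines all output.  Each returns plain DataFrames using
the CSV schemas documented in :mod:`steppebird.validate`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .distance import key_function

__all__ = [
    "generate_plots", "simulate_nest_survey", "simulate_nest_histories",
    "simulate_ddo_counts", "simulate_dataset", "truth_table",
]

# stable stream indices: inserting a new generator appends, never reorders
_STREAMS = {"plots": 0, "nests": 1, "histories": 2, "ddo": 3, "quality": 4}

SEASON_START_DAY = 128          # Julian date of first possible initiation
SEASON_SPAN = 30                # initiation window in days

_FAILURE_CAUSES = ("predation", "abandonment", "other")
_FAILURE_PROBS = (0.78, 0.15, 0.07)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stage]])


def generate_plots(config: SimulationConfig) -> pd.DataFrame:
    """Generate one row per plot-year with enrollment and covariates.

    Exactly ``round(n_plots * prop_enrolled)`` plots are flagged SGI;
    enrollment is a plot property, constant across years.  Covariates are
    drawn identically for both enrollment groups (shrub cover Beta,
    weather Normal), matching the study design in which enrolled and
    unenrolled pastures did not differ in measured covariates.
    """
    rng = _rng(config, "plots")
    n = config.n_plots
    n_enrolled = round(n * config.prop_enrolled)
    plot_ids = [f"P{i:03d}" for i in range(1, n + 1)]
    enrolled = np.array([i < n_enrolled for i in range(n)])

    rows = []
    for year in config.years:
        shrub = rng.beta(config.shrub_alpha, config.shrub_beta, size=n)
        gpp = rng.normal(config.gpp_mean, config.gpp_sd, size=n)
        lai = np.abs(rng.normal(config.lai_mean, config.lai_sd, size=n))
        precip = np.abs(rng.normal(config.precip_mean, config.precip_sd,
                                   size=n))
        tmax = rng.normal(config.tmax_mean, config.tmax_sd, size=n)
        tmin = rng.normal(config.tmin_mean, config.tmin_sd, size=n)
        for i in range(n):
            rows.append({
                "plot_id": plot_ids[i], "year": year,
                "enrollment": "SGI" if enrolled[i] else "non-SGI",
                "shrub_cover": shrub[i], "gpp_mean": gpp[i],
                "lai_mean": lai[i], "precip_mean": precip[i],
                "tmax": tmax[i], "tmin": tmin[i],
            })
    return pd.DataFrame(rows)


def plot_quality(config: SimulationConfig) -> dict[str, float]:
    """Shared log-scale plot-quality effects, keyed by plot id.

    Drawn from Normal(0, plot_density_sd) on a dedicated stream so the
    nest and adult generators see identical habitat quality.  All zero
    when ``plot_density_sd`` is 0 (homogeneous plots).
    """
    ids = [f"P{i:03d}" for i in range(1, config.n_plots + 1)]
    if config.plot_density_sd == 0.0:
        return {pid: 0.0 for pid in ids}
    rng = _rng(config, "quality")
    return dict(zip(ids, rng.normal(0.0, config.plot_density_sd,
                                    config.n_plots)))


def _transect_positions(config: SimulationConfig) -> np.ndarray:
    geo = config.geometry
    extent = (geo.transects_per_plot - 1) * geo.transect_spacing
    start = (geo.plot_side - extent) / 2.0
    return start + geo.transect_spacing * np.arange(geo.transects_per_plot)


def simulate_nest_survey(
    plots: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate latent nests and their transect detections.

    Latent nests are placed uniformly over each 500 x 500 m plot at the
    species' true density (Poisson count per plot-year).  Each survey
    round is an independent pass: a nest within the strip half-width
    ``w`` of its nearest transect is detected on a round with
    probability ``g(x)`` from the configured key function, where ``x``
    is the perpendicular distance.  Detections pool across rounds (a
    nest re-detected on a later round contributes again), matching the
    effort convention of summing line length across rounds.  Nests
    missed on every transect pass may still be found opportunistically
    (no distance recorded), feeding the survival analysis only.

    Returns ``(detections, latent)``; detections carry exact distances.
    """
    rng = _rng(config, "nests")
    geo, det = config.geometry, config.detection
    tx = _transect_positions(config)
    g = key_function(det.nest_key, det.nest_scale, det.nest_shape)

    quality = plot_quality(config)
    plot_years = plots[["plot_id", "year"]].drop_duplicates()
    latent_rows, det_rows = [], []
    nest_counter = 0
    for _, pr in plot_years.iterrows():
        for sp in config.species:
            n_latent = rng.poisson(
                sp.nest_density * np.exp(quality.get(pr.plot_id, 0.0)))
            for _ in range(n_latent):
                nest_counter += 1
                nest_id = f"N{nest_counter:05d}"
                x = rng.uniform(0.0, geo.plot_side)
                y = rng.uniform(0.0, geo.plot_side)
                j = int(np.argmin(np.abs(tx - x)))
                dist = float(abs(tx[j] - x))
                init_day = SEASON_START_DAY + int(
                    rng.integers(0, SEASON_SPAN + 1))
                in_strip = dist <= geo.strip_half_width
                detected = False
                for rnd in range(1, geo.rounds_per_season + 1):
                    if in_strip and rng.random() < g(dist):
                        detected = True
                        det_rows.append({
                            "plot_id": pr.plot_id, "year": pr.year,
                            "species": sp.name, "transect_id": f"T{j + 1}",
                            "nest_id": nest_id, "round": rnd,
                            "distance_m": dist, "opportunistic": False,
                        })
                opportunistic = bool(
                    (not detected)
                    and rng.random() < config.opportunistic_fraction)
                latent_rows.append({
                    "nest_id": nest_id, "plot_id": pr.plot_id,
                    "year": pr.year, "species": sp.name,
                    "x": x, "y": y, "distance_m": dist,
                    "transect_id": f"T{j + 1}",
                    "init_day": init_day, "detected": detected,
                    "opportunistic": opportunistic,
                })
    latent = pd.DataFrame(latent_rows, columns=[
        "nest_id", "plot_id", "year", "species", "x", "y", "distance_m",
        "transect_id", "init_day", "detected", "opportunistic"])
    detections = pd.DataFrame(det_rows, columns=[
        "plot_id", "year", "species", "transect_id", "nest_id", "round",
        "distance_m", "opportunistic"])
    return detections, latent


def survey_effort(plots: pd.DataFrame, config: SimulationConfig
                  ) -> pd.DataFrame:
    """Transect effort table: line length per plot-year-transect."""
    geo = config.geometry
    plot_years = plots[["plot_id", "year"]].drop_duplicates()
    rows = []
    for _, pr in plot_years.iterrows():
        for j in range(geo.transects_per_plot):
            rows.append({
                "plot_id": pr.plot_id, "year": pr.year,
                "transect_id": f"T{j + 1}",
                "length_m": geo.transect_length,
                "rounds": geo.rounds_per_season,
            })
    return pd.DataFrame(rows)


def simulate_nest_histories(
    latent: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily survival and the visit records observers would see.

    Each nest survives each day independently at its stage's daily
    survival rate; the stage switches egg -> nestling at the species'
    hatch day.  A nest alive through the full nesting period fledges.
    Visits run every ``visit_interval`` days from initiation; death is
    only discovered at the first visit after it happens (interval
    censoring), while the exact death day is kept in the fate table for
    oracle tests.

    Returns ``(visits, fates)``.  Visits cover every latent nest;
    downstream analyses subset to nests that were actually found.
    """
    rng = _rng(config, "histories")
    species_cfg = {s.name: s for s in config.species}
    interval = config.geometry.visit_interval

    visit_rows, fate_rows = [], []
    for row in latent.itertuples(index=False):
        sp = species_cfg[row.species]
        period, hatch = sp.nesting_period, sp.hatch_day
        # day-by-day survival: death_day = first day the nest dies, or None
        death_day = None
        for day in range(1, period + 1):
            dsr = sp.dsr_egg if day <= hatch else sp.dsr_nestling
            if rng.random() > dsr:
                death_day = day
                break
        fledged = death_day is None
        cause = ""
        if not fledged:
            cause = str(rng.choice(_FAILURE_CAUSES, p=_FAILURE_PROBS))

        visit_days = list(range(0, period + interval, interval))
        for d in visit_days:
            stage = "egg" if d <= hatch else "nestling"
            if death_day is not None and d >= death_day:
                status, stage_out = "failed", stage
                visit_rows.append(_visit(row, d, stage_out, status, cause))
                break
            if d >= period:
                visit_rows.append(_visit(row, d, "nestling", "fledged", ""))
                break
            visit_rows.append(_visit(row, d, stage, "active", ""))
        fate_rows.append({
            "nest_id": row.nest_id, "plot_id": row.plot_id,
            "year": row.year, "species": row.species,
            "fledged": fledged, "death_day": death_day,
            "cause": cause, "init_day": row.init_day,
        })
    visits = pd.DataFrame(visit_rows, columns=[
        "nest_id", "plot_id", "year", "species", "visit_day", "stage",
        "status", "cause", "init_day", "discovery"])
    fates = pd.DataFrame(fate_rows)
    return visits, fates


def _visit(row, day, stage, status, cause):
    return {
        "nest_id": row.nest_id, "plot_id": row.plot_id, "year": row.year,
        "species": row.species, "visit_day": row.init_day + day,
        "stage": stage, "status": status, "cause": cause,
        "init_day": row.init_day,
        "discovery": ("transect" if row.detected else
                      "opportunistic" if row.opportunistic else "none"),
    }


def simulate_ddo_counts(
    plots: pd.DataFrame, config: SimulationConfig,
    plot_log_sd: float | None = None, n_observers: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dependent double-observer adult counts.

    Each plot carries one site-level effect shared across species and
    years (the structure the hierarchical estimator assumes), giving
    expected abundance ``lambda = adult_density * exp(eps_plot)`` with
    ``eps_plot ~ Normal(0, plot_log_sd)``.  Per visit, the latent count is
    ``N ~ Poisson(lambda)``; the primary observer tallies
    ``x1 ~ Binomial(N, p1)`` and the secondary observer tallies only
    what the primary missed, ``x2 ~ Binomial(N - x1, p2)``.  ``N`` is
    withheld to the truth table.  Observer pairs rotate through roles
    across visits so that per-observer detection is identifiable.

    Returns ``(counts, lambda_truth)``.
    """
    rng = _rng(config, "ddo")
    det = config.detection
    p1, p2 = det.p_observer, det.p_secondary
    if plot_log_sd is None:
        plot_log_sd = config.adult_plot_sd
    plot_years = plots[["plot_id", "year"]].drop_duplicates()
    observers = [f"obs{i + 1}" for i in range(n_observers)]
    quality = plot_quality(config)

    all_plots = sorted(plot_years["plot_id"].unique())
    eps_plot = dict(zip(all_plots,
                        rng.normal(0.0, plot_log_sd, len(all_plots))))

    count_rows, truth_rows = [], []
    for k, pr in enumerate(plot_years.itertuples(index=False)):
        for sp in config.species:
            lam = sp.adult_density * np.exp(
                eps_plot[pr.plot_id] + quality.get(pr.plot_id, 0.0))
            truth_rows.append({
                "plot_id": pr.plot_id, "year": pr.year,
                "species": sp.name, "lambda": lam,
            })
            for v in range(config.geometry.adult_visits):
                primary = observers[(k + v) % n_observers]
                secondary = observers[(k + v + 1) % n_observers]
                n_latent = rng.poisson(lam)
                x1 = rng.binomial(n_latent, p1)
                x2 = rng.binomial(n_latent - x1, p2)
                count_rows.append({
                    "plot_id": pr.plot_id, "year": pr.year,
                    "visit": v + 1, "species": sp.name,
                    "observer_primary": primary,
                    "observer_secondary": secondary,
                    "x1": int(x1), "x2": int(x2),
                })
    counts = pd.DataFrame(count_rows)
    lam_truth = pd.DataFrame(truth_rows)
    return counts, lam_truth


def truth_table(config: SimulationConfig, latent: pd.DataFrame,
                lam_truth: pd.DataFrame) -> pd.DataFrame:
    """One truth row per plot-year-species: densities, DSR, detection."""
    species_cfg = {s.name: s for s in config.species}
    realized = (latent.groupby(["plot_id", "year", "species"])
                .size().rename("n_nests_realized").reset_index())
    out = lam_truth.rename(columns={"lambda": "true_adult_lambda"}).merge(
        realized, on=["plot_id", "year", "species"], how="left")
    out["n_nests_realized"] = out["n_nests_realized"].fillna(0).astype(int)
    quality = plot_quality(config)
    out["true_nest_density"] = [
        species_cfg[s].nest_density * math.exp(quality.get(p, 0.0))
        for s, p in zip(out["species"], out["plot_id"])]
    out["true_dsr_egg"] = [species_cfg[s].dsr_egg for s in out["species"]]
    out["true_dsr_nestling"] = [
        species_cfg[s].dsr_nestling for s in out["species"]]
    out["nest_key"] = config.detection.nest_key
    out["nest_scale"] = config.detection.nest_scale
    out["p_observer"] = config.detection.p_observer
    return out


def simulate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run all generators; returns named DataFrames including the truth."""
    plots = generate_plots(config)
    detections, latent = simulate_nest_survey(plots, config)
    effort = survey_effort(plots, config)
    visits, fates = simulate_nest_histories(latent, config)
    counts, lam_truth = simulate_ddo_counts(plots, config)
    return {
        "plots": plots, "nest_detections": detections, "effort": effort,
        "nest_visits": visits, "nest_fates": fates, "ddo_counts": counts,
        "latent_nests": latent,
        "truth": truth_table(config, latent, lam_truth),
    }
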
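"""End-to-end pipeline: simulate (optional) -> density -> survival ->
abundance -> density-dependence comparison.

Each stage writes plain-CSV artifacts into the output directory and the
whole run is determined by the configuration plus the master seed.  A
stage failure halts the run with the stage name; artifacts written by
earlier stages are preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import density_dependence as dd
from .config import PipelineConfig
from .ddo import DependentDoubleObserverModel
from .distance import DistanceSamplingModel, estimate_density, density_table
from .exposure import (LogisticExposureModel, apparent_success,
                       build_exposure_intervals, failure_cause_breakdown,
                       model_selection_table, seasonal_survival)
from .simulate import simulate_dataset
from .validate import read_csv, validate_dataset, write_csv

log = logging.getLogger("steppebird")

#: default candidate formulas for the survival stage
DEFAULT_SURVIVAL_FORMULAS = (
    "~ 1",
    "~ stage",
    "~ stage + year",
    "~ nest_density",
    "~ enrollment",
    "~ init_day",
    "~ shrub_cover + tmax",
    "~ enrollment + nest_density",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.simulate:
        data = simulate_dataset(config.simulation)
        return data
    tables = {}
    for name, path in (("plots", config.plots_csv),
                       ("nest_detections", config.detections_csv),
                       ("effort", config.effort_csv),
                       ("nest_visits", config.visits_csv),
                       ("ddo_counts", config.counts_csv)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"input file for {name} not found: {p}")
        tables[name] = read_csv(p)
    return tables


def fit_density_stage(tables, config, per_plot: bool = True):
    """Distance-sampling stage: per-species detection function + densities.

    Returns ``(model_tables, strata_estimates, plot_estimates)``.
    Strata follow year x enrollment (the reporting unit); per-plot-year
    estimates (plots with >= 2 detections) feed the survival covariate
    and the density-dependence comparison.
    """
    det = tables["nest_detections"]
    det = det[~det.get("opportunistic", False).astype(bool)]
    plots = tables["plots"]
    det = det.merge(plots[["plot_id", "year", "enrollment"]],
                    on=["plot_id", "year"], how="left")
    effort = tables["effort"].merge(
        plots[["plot_id", "year", "enrollment"]],
        on=["plot_id", "year"], how="left")

    model_rows, strata_rows, plot_rows = [], [], []
    for sp in config.species:
        sub = det[det["species"] == sp]
        if len(sub) < 2:
            log.warning("species %s: < 2 detections, density skipped", sp)
            continue
        model = DistanceSamplingModel(sub, w=config.truncation)
        table, fits = model.fit_all()
        top = fits[table["model"].iloc[0]]
        t = table.copy()
        t.insert(0, "species", sp)
        model_rows.append(t)

        for est in estimate_density(top, sub, effort,
                                    strata=["year", "enrollment"]):
            d = est.as_dict()
            d["species"] = sp
            strata_rows.append(d)
        # pooled across years per enrollment (the bold summary rows)
        for est in estimate_density(top, sub, effort,
                                    strata=["enrollment"]):
            d = est.as_dict()
            d["species"] = sp
            d["stratum"] = f"all-years/{d['stratum']}"
            strata_rows.append(d)
        if per_plot:
            # plot-year estimates where the >= 2-detections rule is met
            counts = sub.groupby(["plot_id", "year"]).size()
            eligible = counts[counts >= 2].index
            for pid, yr in eligible:
                mask = (sub["plot_id"] == pid) & (sub["year"] == yr)
                eff_mask = (effort["plot_id"] == pid) & \
                    (effort["year"] == yr)
                ests = estimate_density(top, sub[mask], effort[eff_mask],
                                        strata=None)
                d = ests[0].as_dict()
                d.update({"species": sp, "plot_id": pid, "year": yr})
                plot_rows.append(d)
    if not model_rows:
        raise ValueError("no species had enough detections")
    return (pd.concat(model_rows, ignore_index=True),
            pd.DataFrame(strata_rows), pd.DataFrame(plot_rows))


def fit_survival_stage(tables, config, plot_density: pd.DataFrame,
                       formulas=DEFAULT_SURVIVAL_FORMULAS):
    """Logistic-exposure stage per species.

    Joins plot covariates and the plot-level species nest density onto
    the exposure intervals, fits the candidate formula suite with a
    plot random effect, and ranks by AICc.
    """
    visits = tables["nest_visits"]
    if "discovery" in visits.columns:
        visits = visits[visits["discovery"] != "none"]
    plots = tables["plots"]

    sel_rows, pred_rows, desc_rows = [], [], []
    for sp in config.species:
        vsub = visits[visits["species"] == sp]
        if vsub.empty:
            continue
        intervals = build_exposure_intervals(vsub)
        intervals = intervals.merge(plots, on=["plot_id", "year"],
                                    how="left")
        if not plot_density.empty:
            pdsub = plot_density[plot_density["species"] == sp]
            intervals = intervals.merge(
                pdsub[["plot_id", "year", "density_per_25ha"]].rename(
                    columns={"density_per_25ha": "nest_density"}),
                on=["plot_id", "year"], how="left")
        if "nest_density" not in intervals.columns:
            intervals["nest_density"] = 0.0
        intervals["nest_density"] = intervals["nest_density"].fillna(0.0)
        intervals["year"] = intervals["year"].astype(str)

        fits = []
        for f in formulas:
            try:
                m = LogisticExposureModel(intervals, formula=f,
                                          random_plot=True)
                fits.append(m.fit())
            except (ValueError, KeyError) as exc:
                log.warning("species %s formula %r skipped: %s", sp, f, exc)
        if not fits:
            raise ValueError(f"no survival model converged for {sp}")
        table = model_selection_table(fits)
        table.insert(0, "species", sp)
        sel_rows.append(table)
        top = next(r for r in fits if r.name == table["model"].iloc[0])

        period = config.nesting_periods.get(sp, 19)
        dsr = top.dsr_at_mean()
        pred_rows.append({
            "species": sp, "top_model": top.name, "dsr_mean": dsr,
            "random_sd": top.random_sd,
            "nesting_period": period,
            "seasonal_survival": seasonal_survival(dsr, period),
        })
        succ = apparent_success(vsub)
        desc = {"species": sp, **succ}
        causes = failure_cause_breakdown(vsub)
        pred = causes[causes["cause"] == "predation"]
        desc["predation_fraction"] = (float(pred["fraction"].iloc[0])
                                      if not pred.empty else 0.0)
        desc_rows.append(desc)
    return (pd.concat(sel_rows, ignore_index=True),
            pd.DataFrame(pred_rows), pd.DataFrame(desc_rows))


def fit_abundance_stage(tables, config):
    model = DependentDoubleObserverModel(tables["ddo_counts"],
                                         plots=tables["plots"])
    res = model.fit(chains=config.mcmc_chains,
                    iterations=config.mcmc_iterations,
                    burn_in=config.mcmc_burn_in, seed=config.seed)
    return res


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns a results bundle and writes CSVs."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "load"
    try:
        tables = _load_inputs(config)
        bundle["tables"] = tables
        if config.simulate:
            for name in ("plots", "nest_detections", "effort",
                         "nest_visits", "ddo_counts", "truth"):
                write_csv(tables[name], out / f"{name}.csv")

        stage = "validate"
        report = validate_dataset(tables)
        bundle["validation"] = report
        if not report.ok:
            log.warning("validation found %d violation(s)",
                        len(report.violations))

        stage = "fit-density"
        model_table, strata_est, plot_est = fit_density_stage(
            tables, config)
        bundle["detection_models"] = model_table
        bundle["density_strata"] = strata_est
        bundle["density_plots"] = plot_est
        write_csv(model_table, out / "detection_model_table.csv")
        write_csv(strata_est, out / "density_estimates.csv")
        write_csv(plot_est, out / "density_plot_estimates.csv")

        stage = "fit-survival"
        sel, preds, desc = fit_survival_stage(tables, config, plot_est)
        bundle["dsr_model_table"] = sel
        bundle["dsr_predictions"] = preds
        bundle["nest_fate_summary"] = desc
        write_csv(sel, out / "dsr_model_table.csv")
        write_csv(preds, out / "dsr_predictions.csv")

        stage = "fit-abundance"
        res = fit_abundance_stage(tables, config)
        bundle["abundance_results"] = res
        pairs = res.pair_density()
        diag = res.diagnostics(include_eps=True)
        bundle["abundance_estimates"] = pairs
        write_csv(pairs, out / "abundance_estimates.csv")
        write_csv(diag, out / "mcmc_diagnostics.csv")

        stage = "compare"
        nest = plot_est.rename(
            columns={"density_per_25ha": "nest_density"})
        comparison = dd.compare(
            nest[["plot_id", "year", "species", "nest_density"]],
            pairs[["plot_id", "year", "species", "pair_density"]],
            by="plot")
        bundle["density_dependence"] = comparison
        write_csv(comparison, out / "density_dependence.csv")

        _write_report(out / "report.txt", config, bundle)
    except Exception as exc:                     # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    return bundle


def _write_report(path: Path, config: PipelineConfig, bundle: dict):
    lines = ["steppebird pipeline report",
             f"seed = {config.seed}", ""]
    lines.append("== detection model selection ==")
    lines.append(bundle["detection_models"].to_string(index=False))
    lines.append("\n== density estimates (per 25 ha) ==")
    lines.append(bundle["density_strata"].to_string(index=False))
    lines.append("\n== nest survival ==")
    lines.append(bundle["dsr_model_table"].to_string(index=False))
    lines.append(bundle["dsr_predictions"].to_string(index=False))
    lines.append(bundle["nest_fate_summary"].to_string(index=False))
    lines.append("\n== adult abundance ==")
    lines.append(bundle["abundance_results"].summary())
    lines.append("\n== density dependence ==")
    lines.append(bundle["density_dependence"].to_string(index=False))
    path.write_text("\n".join(lines))
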
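"""Pipeline stages tying the modules into one run.

Order: generate → preprocess → distances → fit → predict → scenario →
report. Each stage reads the previous stage's CSV artifacts from the
configured output directory and writes its own, so stages can be rerun
individually; ``run_pipeline`` executes them all and writes a run log with
the seed, package version and chosen hyperparameters.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__  # noqa: F401  (run-log provenance)
from . import access as access_mod
from . import io as io_mod
from . import preprocess as prep
from . import scenarios as scen
from . import synthetic
from .config import PipelineConfig
from .errors import InputError, SchemaError
from .model import ModelSpec, fit_model, residual_moran, select_hyperparameters
from .spatial import build_adjacency, convex_hull_mask

logger = logging.getLogger(__name__)

_TRUTH_COLS = ["abortions_true", "true_rate", "true_field"]


def _out(config: PipelineConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def model_spec(config: PipelineConfig) -> ModelSpec:
    return ModelSpec(
        exposure_col=config.exposure_col,
        categories=config.categories,
        lambda_grid=tuple(config.lambda_grid),
        snap_grid=tuple(config.snap_grid),
        max_iter=config.max_iter,
        tol=config.tol,
    )


def stage_generate(config: PipelineConfig) -> dict:
    """Generate the synthetic study population and write its artifacts."""
    data = synthetic.generate_dataset(config.synthetic_config())
    out = _out(config)
    counties = data["counties"]
    public = counties.drop(columns=_TRUTH_COLS + [
        "median_distance", "distance_category", "median_time", "time_category",
    ])
    io_mod.write_table(public, out / "counties.csv")
    io_mod.write_table(
        data["tracts"].drop(columns=["distance", "time_minutes"]), out / "tracts.csv"
    )
    io_mod.write_table(data["facilities"], out / "facilities.csv")
    io_mod.write_table(data["state_totals"], out / "state_totals.csv")
    io_mod.write_adjacency(data["adjacency"], out / "adjacency.csv")
    io_mod.write_table(
        counties[["county_id"] + _TRUTH_COLS], out / "truth.csv"
    )
    config.to_yaml(out / "config.yaml")
    return data


def stage_preprocess(config: PipelineConfig) -> pd.DataFrame:
    """Reconcile counts to state totals, impute suppression, compute rates."""
    out = _out(config)
    counties = io_mod.read_table(out / "counties.csv", "counties")
    totals = io_mod.read_table(out / "state_totals.csv", "state_totals")
    counties = prep.adjust_state_counts(counties, totals, config.adjust_tolerance)
    counties = prep.impute_all_suppressed(counties)
    counties = prep.compute_rates(counties)
    io_mod.write_table(counties, out / "counties_prepared.csv")
    return counties


def stage_distances(config: PipelineConfig) -> pd.DataFrame:
    """Tract-to-facility distances → county median exposure and category.

    If a ``distances.csv`` (tract_id, facility_id, miles[, minutes]) sits in
    the artifact directory — e.g. externally routed road distances — the
    nearest-facility distance is its per-tract minimum; otherwise distances
    are computed from coordinates with the planar metric.
    """
    out = _out(config)
    tracts = io_mod.read_table(out / "tracts.csv", "tracts")
    facilities = io_mod.read_table(out / "facilities.csv", "facilities")
    routed = out / "distances.csv"
    if routed.exists():
        D = pd.read_csv(routed)
        for col, new in (("miles", "distance"), ("minutes", "time_minutes")):
            if col in D.columns:
                per_tract = D.groupby("tract_id")[col].min()
                tracts[new] = tracts["tract_id"].map(per_tract)
        if tracts["distance"].isna().any():
            raise SchemaError(str(routed), ["<distance for every tract>"])
    acc = access_mod.build_county_access(tracts, facilities)
    if config.exposure == "time":
        # travel time from distance at an average road speed of 48 mph;
        # precomputed times may be supplied via a time_minutes tract column
        tracts = tracts.copy()
        if "time_minutes" not in tracts.columns:
            tracts["time_minutes"] = (
                access_mod.nearest_facility_distances(tracts, facilities) / 48.0 * 60.0
            )
        rows = []
        for cid, grp in tracts.groupby("county_id", sort=True):
            grp = grp.rename(columns={"time_minutes": "distance"})
            rows.append(
                {"county_id": cid, "median_time": access_mod.county_median_distance(grp)}
            )
        times = pd.DataFrame(rows)
        times["time_category"] = access_mod.categorize_distance(
            times["median_time"].to_numpy(), config.categories
        ).to_numpy()
        acc = acc.merge(times, on="county_id")
    io_mod.write_table(acc, out / "county_access.csv")
    return acc


def _load_model_inputs(config: PipelineConfig):
    out = _out(config)
    counties = io_mod.read_table(out / "counties_prepared.csv", "counties")
    acc = io_mod.read_table(out / "county_access.csv", "county_access")
    counties = counties.merge(acc, on="county_id")
    graph = io_mod.read_adjacency(out / "adjacency.csv", counties["county_id"].to_numpy())
    return counties, graph


def _adjacency_builder(config: PipelineConfig, counties: pd.DataFrame):
    if config.adjacency_mode == "contiguity":
        graph = build_adjacency(counties, mode="contiguity", contiguity=config.contiguity)
        return lambda snap: graph
    return lambda snap: build_adjacency(counties, mode="distance", snap=snap)


def stage_fit(config: PipelineConfig):
    """State-grouped CV over (λ, snap), then the final fit on all observed data."""
    out = _out(config)
    counties, graph = _load_model_inputs(config)
    spec = model_spec(config)
    if config.adjacency_mode == "contiguity":
        builder = lambda snap: graph  # noqa: E731
    else:
        builder = _adjacency_builder(config, counties)
    lam, snap, cv_table = select_hyperparameters(counties, builder, spec)
    full_graph = builder(snap)
    fit = fit_model(counties, full_graph, spec, lam, snap=snap)
    fit.cv_mse = float(
        cv_table.loc[
            (cv_table["lambda"] == lam)
            & (cv_table["snap"].isna() if snap is None else cv_table["snap"] == snap),
            "cv_mse",
        ].iloc[0]
    )
    fit.residual_moran_i = residual_moran(fit, counties, full_graph)
    io_mod.write_table(cv_table, out / "cv_table.csv")
    io_mod.write_fit(fit, out / "fit.json")
    return fit, cv_table


def stage_predict(config: PipelineConfig) -> pd.DataFrame:
    """Actual-conditions predictions for every county under the hull policy."""
    preds, _ = _scenario_predictions(config, caps=[None])
    out = _out(config)
    io_mod.write_table(preds["actual"], out / "county_predictions.csv")
    return preds["actual"]


def _scenario_predictions(config: PipelineConfig, caps=None):
    out = _out(config)
    counties, graph = _load_model_inputs(config)
    fit = io_mod.read_fit(out / "fit.json")
    spec = model_spec(config)
    observed = counties[counties["abortions"].notna()]
    mask = convex_hull_mask(
        observed[["x", "y"]].to_numpy(), counties[["x", "y"]].to_numpy()
    )
    caps = config.scenario_caps if caps is None else caps
    scenarios = [
        scen.ScenarioSpec(_scenario_name(cap), cap if cap is None else float(cap))
        for cap in caps
    ]
    return scen.run_scenarios(fit, counties, mask, graph, spec, scenarios)


def _scenario_name(cap) -> str:
    if cap is None:
        return "actual"
    return f"under_{_trim(cap)}"


def _trim(x) -> str:
    x = float(x)
    return str(int(x)) if x.is_integer() else str(x)


def stage_scenario(config: PipelineConfig):
    """All configured counterfactual caps → wide per-county prediction table."""
    out = _out(config)
    preds, report = _scenario_predictions(config)
    wide = None
    for name, p in preds.items():
        cols = p[["county_id", "state_id", "pop_f1544", "in_hull"]].copy()
        cols[f"rate_{name}"] = p["predicted_rate"].to_numpy()
        cols[f"count_{name}"] = p["predicted_count"].to_numpy()
        cols[f"category_{name}"] = p["scenario_category"].to_numpy()
        wide = cols if wide is None else wide.merge(
            cols.drop(columns=["state_id", "pop_f1544", "in_hull"]), on="county_id"
        )
    io_mod.write_table(wide, out / "county_predictions.csv")
    io_mod.write_table(report, out / "scenario_report.csv")
    return preds, report


def stage_report(config: PipelineConfig) -> pd.DataFrame:
    """Round and order the scenario report the way the published table reads."""
    out = _out(config)
    path = out / "scenario_report.csv"
    if not path.exists():
        raise SchemaError(str(path), ["<run the scenario stage first>"])
    report = pd.read_csv(path)
    pretty = report.copy()
    pretty["total_abortions"] = pretty["total_abortions_rounded"]
    pretty["median_rate"] = pretty["median_rate"].round(1)
    pretty["mean_rate"] = pretty["mean_rate"].round(1)
    pretty["rate_range"] = (
        pretty["min_rate"].round(1).astype(str) + "-" + pretty["max_rate"].round(1).astype(str)
    )
    cols = [
        "scenario", "state_id", "n_counties", "pop_f1544",
        "total_abortions", "mean_rate", "median_rate", "rate_range",
    ]
    if "pct_change" in pretty.columns:
        pretty["pct_change"] = pretty["pct_change"].round(1)
        cols.append("pct_change")
    io_mod.write_table(pretty[cols], out / "report.csv")
    return pretty[cols]


_STAGES = ["generate", "preprocess", "distances", "fit", "predict", "scenario", "report"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write a run log; returns the artifact dir."""
    out = _out(config)
    chosen = {}
    for name in _STAGES:
        logger.info("stage: %s", name)
        try:
            result = globals()[f"stage_{name}"](config)
        except Exception as exc:
            raise type(exc)(f"stage '{name}' failed: {exc}") from exc
        if name == "fit":
            fit, _ = result
            chosen = {"lambda": fit.lam, "snap": fit.snap, "cv_mse": fit.cv_mse}
    log = {
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": _STAGES,
        "hyperparameters": chosen,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def preflight(config: PipelineConfig, stage: str) -> None:
    """Check a stage's input files exist before any computation."""
    out = Path(config.outdir)
    needs = {
        "preprocess": ["counties.csv", "state_totals.csv"],
        "distances": ["tracts.csv", "facilities.csv"],
        "fit": ["counties_prepared.csv", "county_access.csv", "adjacency.csv"],
        "predict": ["counties_prepared.csv", "county_access.csv", "adjacency.csv", "fit.json"],
        "scenario": ["counties_prepared.csv", "county_access.csv", "adjacency.csv", "fit.json"],
        "report": ["scenario_report.csv"],
    }
    for f in needs.get(stage, []):
        if not (out / f).exists():
            raise InputError(f"stage '{stage}' requires missing file: {out / f}")
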
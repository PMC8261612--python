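"""Counterfactual travel-distance scenarios and report aggregation.

Prediction follows the convex-hull policy: counties inside the hull of the
observed county centroids get the full spatial model (including the MRF
field, harmonically extended to counties absent from the fit); counties
outside get the covariates-only prediction, because extrapolating the
spatial field beyond the observed map produces implausible rates.

Scenarios cap every county's travel distance: a <5-mile cap (simulating
medication abortion by telemedicine) moves every county to the reference
category; a <30-mile cap (a common network-adequacy standard for primary
care) moves counties above the cap to the highest category strictly below
it. Aggregates mirror the study's report tables: state/national totals,
pooled mean rate, population-weighted median county rate and rate range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .access import DistanceCategories, weighted_median
from .errors import ParameterError
from .model import FitResult, ModelSpec, harmonic_extension, predict_fixed_eta
from .spatial import AdjacencyGraph

__all__ = [
    "ScenarioSpec",
    "apply_scenario",
    "predict_counties",
    "aggregate",
    "run_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual travel-distance cap; ``cap=None`` is actual conditions."""

    name: str
    cap: float | None = None


def apply_scenario(
    counties: pd.DataFrame,
    scenario: ScenarioSpec,
    categories: DistanceCategories,
    exposure_col: str = "distance_category",
) -> pd.DataFrame:
    """Recode exposure categories under a distance cap.

    The cap must be one of the category cut points. Categories lying
    entirely at or above the cap are recoded to the highest category
    strictly below it; counties already below the cap are unchanged.
    """
    counties = counties.copy()
    if scenario.cap is None:
        return counties
    cuts = list(categories.cuts)
    if scenario.cap not in cuts:
        raise ParameterError(
            f"scenario cap {scenario.cap} is not a category cut point {cuts}"
        )
    j = cuts.index(scenario.cap)  # labels[j] is the top category below the cap
    labels = categories.labels
    recode = {lab: labels[j] for lab in labels[j + 1 :]}
    cats = counties[exposure_col].astype(str)
    counties[exposure_col] = cats.map(lambda c: recode.get(c, c))
    return counties


def predict_counties(
    fit: FitResult,
    counties: pd.DataFrame,
    hull_mask: np.ndarray,
    graph: AdjacencyGraph,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Predicted counts and rates per county under the hull policy.

    ``hull_mask`` is True for counties inside (or on) the convex hull of
    the observed county centroids. Inside the hull the linear predictor
    includes the MRF effect — the fitted value for fitted counties, the
    penalty-smoothed neighbour value for the rest, zero for counties
    isolated from every fitted county. Outside the hull the field term is
    omitted.
    """
    hull_mask = np.asarray(hull_mask, bool)
    if len(hull_mask) != len(counties):
        raise ParameterError("hull mask must align with counties")
    eta = predict_fixed_eta(fit, counties, spec)
    field = pd.Series(0.0, index=counties["county_id"].to_numpy())
    fitted = pd.Index(fit.county_ids)
    field.loc[fitted.intersection(field.index)] = pd.Series(
        fit.field, index=fit.county_ids
    ).loc[fitted.intersection(field.index)]
    others = field.index.difference(fitted)
    if len(others):
        field.loc[others] = harmonic_extension(
            graph, fit.county_ids, fit.field, others.to_numpy()
        )
    eta_full = eta + np.where(hull_mask, field.to_numpy(), 0.0)
    rate = np.exp(eta_full)
    out = counties[["county_id", "state_id", "pop_f1544"]].copy()
    out["in_hull"] = hull_mask
    out["predicted_rate"] = rate
    out["predicted_count"] = rate * counties["pop_f1544"].to_numpy(float) / 1000.0
    out["scenario_category"] = counties[spec.exposure_col].to_numpy()
    return out


def _round10(x: float) -> int:
    return int(np.round(x / 10.0) * 10)


def _summary(pred: pd.DataFrame) -> dict:
    pop = pred["pop_f1544"].to_numpy(float)
    rate = pred["predicted_rate"].to_numpy(float)
    total = float(pred["predicted_count"].sum())
    return {
        "n_counties": len(pred),
        "pop_f1544": int(pop.sum()),
        "total_abortions": total,
        "total_abortions_rounded": _round10(total),
        "mean_rate": 1000.0 * total / pop.sum(),
        "median_rate": weighted_median(rate, pop),
        "min_rate": float(rate.min()),
        "max_rate": float(rate.max()),
    }


def aggregate(predictions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """State and national report table across scenarios.

    ``predictions`` maps scenario name → per-county prediction frame; the
    scenario named ``actual`` (if present) is the baseline for the percent
    changes. Totals are exact internally; the rounded columns round counts
    to the nearest 10, the granularity of the published tables.
    """
    rows = []
    base = predictions.get("actual")
    for name, pred in predictions.items():
        for state, grp in [("All", pred)] + list(pred.groupby("state_id")):
            s = _summary(grp)
            s["scenario"] = name
            s["state_id"] = state
            if base is not None:
                bgrp = base if state == "All" else base[base["state_id"] == state]
                b = float(bgrp["predicted_count"].sum())
                s["added_abortions"] = s["total_abortions"] - b
                s["pct_change"] = (
                    100.0 * (s["total_abortions"] - b) / b if b > 0 else np.nan
                )
            rows.append(s)
    cols = [
        "scenario",
        "state_id",
        "n_counties",
        "pop_f1544",
        "total_abortions",
        "total_abortions_rounded",
        "mean_rate",
        "median_rate",
        "min_rate",
        "max_rate",
    ]
    if base is not None:
        cols += ["added_abortions", "pct_change"]
    return pd.DataFrame(rows)[cols]


def run_scenarios(
    fit: FitResult,
    counties: pd.DataFrame,
    hull_mask: np.ndarray,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    scenarios: list[ScenarioSpec] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Predict all counties under every scenario and build the report table.

    Counties with missing covariates or exposure cannot be predicted and
    are excluded with a logged count.
    """
    if scenarios is None:
        scenarios = [
            ScenarioSpec("actual", None),
            ScenarioSpec("under_30_miles", 30.0),
            ScenarioSpec("under_5_miles", 5.0),
        ]
    needed = list(spec.covariates) + [spec.exposure_col, spec.grade_col, "pop_f1544"]
    ok = counties[needed].notna().all(axis=1) & (counties["pop_f1544"] > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("excluding %d counties with incomplete covariates", dropped)
    scope = counties[ok]
    mask = np.asarray(hull_mask, bool)[ok.to_numpy()]
    preds = {}
    for sc in scenarios:
        cf = apply_scenario(scope, sc, spec.categories, spec.exposure_col)
        preds[sc.name] = predict_counties(fit, cf, mask, graph, spec)
    return preds, aggregate(preds)
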
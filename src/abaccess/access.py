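"""Spatial-access exposure construction.

Distance from each tract's population-weighted centroid to the nearest
active facility, the population-weighted county median distance, and the
six-level categorical exposure used by the rate model. The distance metric
is pluggable: planar Euclidean for synthetic maps, haversine for lon/lat
coordinates, or a precomputed tract-by-facility matrix for externally
routed (road-network) distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, NoProviderError, ParameterError

__all__ = [
    "DistanceCategories",
    "DISTANCE_CATEGORIES",
    "euclidean_miles",
    "haversine_miles",
    "nearest_facility_distance",
    "nearest_facility_distances",
    "weighted_median",
    "county_median_distance",
    "categorize_distance",
    "describe_access",
    "build_county_access",
]


@dataclass(frozen=True)
class DistanceCategories:
    """Ordered half-open distance bins partitioning [0, ∞).

    Default cut points (5, 15, 30, 60, 120 miles) follow common state
    definitions of health-care network adequacy; a value equal to a cut
    point falls in the upper bin (5.0 → "5-<15").
    """

    cuts: tuple = (5.0, 15.0, 30.0, 60.0, 120.0)
    labels: tuple = ("<5", "5-<15", "15-<30", "30-<60", "60-<120", ">=120")

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ParameterError("cut points must be strictly increasing")
        if len(self.labels) != len(cuts) + 1:
            raise ParameterError("need exactly one more label than cut points")
        object.__setattr__(self, "cuts", cuts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def reference(self) -> str:
        return self.labels[0]


DISTANCE_CATEGORIES = DistanceCategories()

#: Cut points for the travel-time sensitivity exposure, in minutes. The same
#: binning machinery applies; only the column and cuts change.
TIME_CATEGORIES = DistanceCategories(
    cuts=(10.0, 30.0, 60.0, 120.0, 240.0),
    labels=("<10", "10-<30", "30-<60", "60-<120", "120-<240", ">=240"),
)


def euclidean_miles(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pairwise planar distance matrix (coordinates already in miles)."""
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    return np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])


_EARTH_RADIUS_MILES = 3958.8


def haversine_miles(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix for (lon, lat) degree coordinates."""
    a = np.radians(np.asarray(points_a, float))
    b = np.radians(np.asarray(points_b, float))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def nearest_facility_distances(
    tracts: pd.DataFrame,
    facilities: pd.DataFrame,
    metric=euclidean_miles,
) -> pd.Series:
    """Distance from each tract centroid to its nearest active facility.

    ``metric`` maps (tract_xy, facility_xy) to a distance matrix; pass a
    precomputed matrix via ``metric=lambda *_: D``. Ties are broken by the
    lowest facility_id. Raises :class:`NoProviderError` if no facility is
    active.
    """
    if "active" in facilities.columns:
        facilities = facilities[facilities["active"].astype(bool)]
    if len(facilities) == 0:
        raise NoProviderError("no active facilities")
    order = np.argsort(facilities["facility_id"].to_numpy(), kind="stable")
    facilities = facilities.iloc[order]
    D = np.asarray(
        metric(tracts[["x", "y"]].to_numpy(float), facilities[["x", "y"]].to_numpy(float)),
        dtype=float,
    )
    # argmin returns the first minimum; facilities are sorted by id, so ties
    # resolve to the lowest facility_id.
    return pd.Series(D.min(axis=1), index=tracts.index, name="distance")


def nearest_facility_distance(tract_xy, facilities: pd.DataFrame, metric=euclidean_miles) -> float:
    """Single-tract convenience wrapper around :func:`nearest_facility_distances`."""
    tracts = pd.DataFrame({"x": [tract_xy[0]], "y": [tract_xy[1]]})
    return float(nearest_facility_distances(tracts, facilities, metric).iloc[0])


def weighted_median(values, weights) -> float:
    """Population-weighted lower median.

    Smallest value v such that the cumulative weight of items ≤ v reaches
    half the total weight; with equal weights this is the lower median.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if len(v) == 0:
        raise InvalidRecordError("weighted median of an empty set")
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidRecordError("weights must be nonnegative with positive sum")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    k = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(v[order][k])


def county_median_distance(tracts: pd.DataFrame) -> float:
    """Population-weighted median tract distance for one county.

    Excluded tracts (no residents, or institutionalised-male-only) never
    contribute. All tracts excluded → the county is unanalyzable.
    """
    if "excluded" in tracts.columns:
        tracts = tracts[~tracts["excluded"].astype(bool)]
    tracts = tracts[tracts["pop_f1544"] > 0]
    if len(tracts) == 0:
        raise InvalidRecordError("county has no analyzable tracts")
    return weighted_median(tracts["distance"].to_numpy(), tracts["pop_f1544"].to_numpy())


def categorize_distance(d, categories: DistanceCategories = DISTANCE_CATEGORIES):
    """Bin distances into the ordered exposure categories (half-open [lo, hi))."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ParameterError("distances must be finite and nonnegative")
    bins = [0.0, *categories.cuts, np.inf]
    out = pd.cut(np.atleast_1d(arr), bins=bins, labels=categories.labels, right=False)
    if arr.ndim == 0:
        return str(out[0])
    return pd.Series(out.astype(str), name="distance_category")


def describe_access(counties: pd.DataFrame) -> dict:
    """Population-weighted mean and median of the county median distances."""
    d = counties["median_distance"].to_numpy(float)
    p = counties["pop_f1544"].to_numpy(float)
    return {
        "mean": float(np.sum(p * d) / np.sum(p)),
        "median": weighted_median(d, p),
        "min": float(d.min()),
        "max": float(d.max()),
    }


def build_county_access(
    tracts: pd.DataFrame,
    facilities: pd.DataFrame,
    categories: DistanceCategories = DISTANCE_CATEGORIES,
    metric=euclidean_miles,
    distance_col: str = "distance",
) -> pd.DataFrame:
    """Per-county exposure table: median distance and category.

    Computes tract-to-nearest-facility distances (unless ``distance_col``
    already exists on ``tracts``), aggregates them to population-weighted
    county medians and bins the medians into categories.
    """
    tracts = tracts.copy()
    if distance_col not in tracts.columns:
        tracts[distance_col] = nearest_facility_distances(tracts, facilities, metric)
    rows = []
    for county_id, grp in tracts.groupby("county_id", sort=True):
        grp = grp.rename(columns={distance_col: "distance"})
        med = county_median_distance(grp)
        rows.append({"county_id": county_id, "median_distance": med})
    out = pd.DataFrame(rows)
    out["distance_category"] = categorize_distance(
        out["median_distance"].to_numpy(), categories
    ).to_numpy()
    return out
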
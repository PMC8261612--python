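"""Synthetic study-population generator.

Emulates the statistical structure the county-level analysis assumes:
counties laid out on a planar grid and partitioned into contiguous
"states"; census tracts nested in counties with heavy-tailed populations
concentrated around urban centres; sparse facilities located at
high-population tracts; log-linear covariate effects; negative monotone
travel-distance category effects; a spatially autocorrelated county random
field (proper CAR); Poisson counts with a population offset; whole states
that do not report; and small-count suppression with a disclosure limit.

Every stage is driven by an explicit seed, and the same (config, seed)
reproduces the identical dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from . import access
from .errors import ParameterError
from .spatial import AdjacencyGraph, build_adjacency, graph_laplacian

__all__ = [
    "COVARIATE_NAMES",
    "GRADE_LEVELS",
    "SyntheticConfig",
    "TrueParameters",
    "generate_map",
    "place_facilities",
    "simulate_field",
    "simulate_counts",
    "apply_reporting_policy",
    "generate_dataset",
]

#: County covariates: proportions of female residents aged 15-44 (age 25-29,
#: Black, other race/ethnicity, married, high-school degree, foreign-born,
#: below the federal poverty level).
COVARIATE_NAMES = (
    "prop_age2529",
    "prop_black",
    "prop_other_race",
    "prop_married",
    "prop_hs_degree",
    "prop_foreign_born",
    "prop_poverty",
)

#: Typical national means of the covariates, used as generator baselines.
_COVARIATE_MEANS = (0.156, 0.104, 0.034, 0.507, 0.272, 0.045, 0.221)
_COVARIATE_STATE_SD = (0.01, 0.04, 0.015, 0.03, 0.03, 0.02, 0.04)
_COVARIATE_COUNTY_SD = (0.015, 0.05, 0.02, 0.04, 0.05, 0.02, 0.05)

GRADE_LEVELS = ("A", "B", "C", "D", "F")
_GRADE_PROBS = (0.15, 0.20, 0.15, 0.10, 0.40)


@dataclass
class SyntheticConfig:
    """Size and reporting behaviour of the synthetic map.

    Defaults mirror the study scale: 48 contiguous states with ~65 counties
    each (≈3100 counties), of which 27 report county-level counts
    (nonreporting_fraction = 21/48) and 7 reporting states suppress counts
    below a disclosure limit of 10.
    """

    n_states: int = 48
    counties_per_state: tuple = (55, 75)
    tracts_per_county: tuple = (3, 10)
    grid_extent: float = 1500.0
    facility_count: int = 260
    seed: int = 0
    #: state_id → limit, or None for "auto": 7 reporting states, limit 10.
    suppression_limit_by_state: dict | None = None
    nonreporting_fraction: float = 21 / 48
    contiguity: str = "rook"
    n_urban_centers: int = 24
    excluded_tract_fraction: float = 0.01

    def __post_init__(self):
        lo_c, hi_c = self.counties_per_state
        lo_t, hi_t = self.tracts_per_county
        if self.n_states < 1 or lo_c < 1 or lo_t < 1:
            raise ParameterError("counts must be strictly positive")
        if lo_c > hi_c or lo_t > hi_t:
            raise ParameterError("ranges must satisfy lo <= hi")
        if not 0.0 <= self.nonreporting_fraction <= 1.0:
            raise ParameterError("nonreporting_fraction must be in [0, 1]")
        if self.grid_extent <= 0:
            raise ParameterError("grid_extent must be positive")
        if self.facility_count < 1:
            raise ParameterError("facility_count must be strictly positive")


@dataclass
class TrueParameters:
    """Generative parameters of the county rate model.

    The linear predictor of the expected count is
    log μ_i = log(P_i/1000) + intercept + x_iᵀβ + γ[cat_i] + g[grade_i] + f_i,
    so ``intercept`` is a log rate per 1000 female residents aged 15-44 at
    the reference exposure (<5 miles), reference grade (A) and zero
    covariates. ``distance_category_effects`` are the five log-rate
    contrasts of the non-reference distance categories versus <5 miles;
    their defaults are monotone non-increasing, reproducing the
    dose-response decline the model is meant to recover.
    """

    intercept: float = 3.8
    covariate_effects: tuple = (1.0, 0.8, 0.5, -1.5, -0.5, 1.0, -0.8)
    distance_category_effects: tuple = (-0.05, -0.22, -0.34, -0.43, -0.73)
    policy_grade_effects: dict = dc_field(
        default_factory=lambda: {"A": 0.0, "B": -0.08, "C": -0.18, "D": -0.28, "F": -0.40}
    )
    mrf_sd: float = 0.30
    mrf_correlation: float = 0.95

    def __post_init__(self):
        g = np.asarray(self.distance_category_effects, float)
        if len(g) != 5 or not np.all(np.isfinite(g)):
            raise ParameterError("distance_category_effects must be 5 finite values")
        if self.mrf_sd < 0:
            raise ParameterError("mrf_sd must be nonnegative")
        if len(self.covariate_effects) != len(COVARIATE_NAMES):
            raise ParameterError(
                f"covariate_effects must have {len(COVARIATE_NAMES)} entries"
            )


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent generator per pipeline stage, reproducible from one seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def generate_map(config: SyntheticConfig):
    """Lay out counties and tracts on a gridded map of contiguous states.

    Counties occupy cells of a near-square grid enumerated in boustrophedon
    (snake) order; consecutive runs of cells form states, so each state is a
    contiguous, spatially coherent block — which is what makes state-grouped
    cross-validation folds spatially meaningful. Returns
    (counties, tracts, adjacency); the full map graph is connected by
    construction.
    """
    rng = _stage_rng(config.seed, 0)
    lo, hi = config.counties_per_state
    sizes = rng.integers(lo, hi + 1, size=config.n_states)
    total = int(sizes.sum())
    if config.n_states > total:
        raise ParameterError("more states than counties")
    ncols = int(np.ceil(np.sqrt(total)))
    nrows = int(np.ceil(total / ncols))
    cell = config.grid_extent / ncols

    cells = []
    for r in range(nrows):
        cols = range(ncols) if r % 2 == 0 else range(ncols - 1, -1, -1)
        cells.extend((r, c) for c in cols)
    cells = cells[:total]

    state_of = np.repeat(np.arange(config.n_states), sizes)
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    counties = pd.DataFrame(
        {
            "county_id": np.arange(total),
            "state_id": [f"S{int(s):02d}" for s in state_of],
            "row": rows,
            "col": cols,
            "x": (cols + 0.5) * cell,
            "y": (rows + 0.5) * cell,
        }
    )

    # Covariates: a state-level shift plus county noise, clipped to (0, 1).
    for name, m, s_sd, c_sd in zip(
        COVARIATE_NAMES, _COVARIATE_MEANS, _COVARIATE_STATE_SD, _COVARIATE_COUNTY_SD
    ):
        state_shift = rng.normal(0.0, s_sd, size=config.n_states)
        vals = m + state_shift[state_of] + rng.normal(0.0, c_sd, size=total)
        counties[name] = np.clip(vals, 0.002, 0.98)

    grades = rng.choice(GRADE_LEVELS, size=config.n_states, p=_GRADE_PROBS)
    counties["policy_grade"] = [grades[s] for s in state_of]

    # Urban centres concentrate tract population regionally; facilities will
    # follow population, recreating the urban-access gradient.
    centers = rng.uniform(0.0, config.grid_extent, size=(config.n_urban_centers, 2))

    t_lo, t_hi = config.tracts_per_county
    n_tracts = rng.integers(t_lo, t_hi + 1, size=total)
    reps = np.repeat(np.arange(total), n_tracts)
    scatter = rng.normal(0.0, cell / 5.0, size=(len(reps), 2))
    txy = counties[["x", "y"]].to_numpy()[reps] + scatter
    txy = np.clip(txy, 0.0, config.grid_extent)
    d_center = access.euclidean_miles(txy, centers).min(axis=1)
    base_pop = rng.lognormal(mean=np.log(450.0), sigma=1.2, size=len(reps))
    pop = np.maximum(1, np.round(base_pop * (1.0 + 30.0 * np.exp(-d_center / 35.0))))
    excluded = rng.random(len(reps)) < config.excluded_tract_fraction
    first_of_county = np.r_[True, reps[1:] != reps[:-1]]
    excluded &= ~first_of_county  # every county keeps >=1 analyzable tract
    tracts = pd.DataFrame(
        {
            "tract_id": np.arange(len(reps)),
            "county_id": reps,
            "x": txy[:, 0],
            "y": txy[:, 1],
            "pop_f1544": pop.astype(int),
            "excluded": excluded,
        }
    )
    county_pop = (
        tracts[~tracts["excluded"]].groupby("county_id")["pop_f1544"].sum()
    )
    counties["pop_f1544"] = counties["county_id"].map(county_pop).astype(int)

    adjacency = build_adjacency(counties, mode="contiguity", contiguity=config.contiguity)
    return counties, tracts, adjacency


def place_facilities(tracts: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Locate facilities at high-population tracts (probability ∝ pop^1.5)."""
    rng = _stage_rng(config.seed, 1)
    eligible = tracts[~tracts["excluded"].astype(bool)]
    m = min(config.facility_count, len(eligible))
    w = eligible["pop_f1544"].to_numpy(float) ** 1.5
    idx = rng.choice(len(eligible), size=m, replace=False, p=w / w.sum())
    chosen = eligible.iloc[np.sort(idx)]
    return pd.DataFrame(
        {
            "facility_id": np.arange(m),
            "x": chosen["x"].to_numpy(),
            "y": chosen["y"].to_numpy(),
            "active": True,
        }
    )


def simulate_field(adjacency: AdjacencyGraph, params: TrueParameters, seed: int) -> np.ndarray:
    """Draw the latent spatial effect from a proper CAR distribution.

    Precision ∝ D − ρA with ρ = ``mrf_correlation`` in (0, 1); the intrinsic
    MRF (ρ = 1) is improper and cannot be sampled directly, so a proper CAR
    with ρ close to 1 stands in. The draw is centred to mean zero within
    each connected component and rescaled so its empirical standard
    deviation equals ``mrf_sd``. Isolated nodes get unit precision.
    """
    rho = params.mrf_correlation
    if not 0.0 < rho < 1.0:
        raise ParameterError("mrf_correlation must lie strictly in (0, 1)")
    n = adjacency.n_nodes
    if params.mrf_sd == 0.0:
        return np.zeros(n)
    A = adjacency.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    prec = (sp.diags(np.where(deg > 0, deg, 1.0)) - rho * A).toarray()
    L = sla.cholesky(prec, lower=False)  # prec = Lᵀ L with L upper
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x = sla.solve_triangular(L, z, lower=False)
    comp = adjacency.components
    for c in np.unique(comp):
        x[comp == c] -= x[comp == c].mean()
    sd = x.std()
    if sd == 0.0:
        return np.zeros(n)
    return x * (params.mrf_sd / sd)


def simulate_counts(
    counties: pd.DataFrame,
    field: np.ndarray,
    params: TrueParameters,
    seed: int,
    categories: access.DistanceCategories = access.DISTANCE_CATEGORIES,
    exposure_col: str = "distance_category",
) -> pd.DataFrame:
    """Draw Poisson counts from the generative rate model.

    count_i ~ Poisson(μ_i) with
    log μ_i = log(P_i/1000) + intercept + x_iᵀβ + γ[cat_i] + g[grade_i] + f_i.
    The true rate per 1000 (exp of the linear predictor without the offset)
    and the field are stored alongside for parameter-recovery tests.
    """
    counties = counties.copy()
    if np.any(counties["pop_f1544"].to_numpy() <= 0):
        raise ParameterError("all counties need positive population")
    gamma = dict(zip(categories.labels[1:], params.distance_category_effects))
    gamma[categories.reference] = 0.0
    cat_eff = counties[exposure_col].map(gamma)
    if cat_eff.isna().any():
        raise ParameterError("county with exposure category outside the label set")
    grade_eff = counties["policy_grade"].map(params.policy_grade_effects)
    X = counties[list(COVARIATE_NAMES)].to_numpy(float)
    eta = (
        params.intercept
        + X @ np.asarray(params.covariate_effects, float)
        + cat_eff.to_numpy(float)
        + grade_eff.to_numpy(float)
        + np.asarray(field, float)
    )
    mu = counties["pop_f1544"].to_numpy(float) / 1000.0 * np.exp(eta)
    rng = np.random.default_rng(seed)
    counties["abortions_true"] = rng.poisson(mu)
    counties["true_rate"] = np.exp(eta)
    counties["true_field"] = np.asarray(field, float)
    return counties


def apply_reporting_policy(
    counties: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Impose state-level non-reporting and small-count suppression.

    A random ``nonreporting_fraction`` of states loses every county count;
    in states with a suppression limit L, observed counts below L are
    replaced by a suppression marker carrying L. All other counts pass
    through unchanged into the ``abortions`` column.
    """
    rng = _stage_rng(config.seed, 2)
    counties = counties.copy()
    states = np.array(sorted(counties["state_id"].unique()))
    n_nr = int(round(config.nonreporting_fraction * len(states)))
    nonreporting = set(rng.choice(states, size=n_nr, replace=False)) if n_nr else set()
    reporting_states = [s for s in states if s not in nonreporting]

    limits = config.suppression_limit_by_state
    if limits is None:
        k = min(7, len(reporting_states))
        chosen = rng.choice(reporting_states, size=k, replace=False) if k else []
        limits = {s: 10 for s in chosen}

    counties["reporting"] = ~counties["state_id"].isin(nonreporting)
    y = counties["abortions_true"].to_numpy(float)
    observed = np.where(counties["reporting"], y, np.nan)
    lim = counties["state_id"].map(lambda s: limits.get(s)).to_numpy(object)
    lim = np.array([np.nan if v is None else float(v) for v in lim])
    suppressed = counties["reporting"].to_numpy() & np.isfinite(lim) & (observed < lim)
    counties["abortions"] = np.where(suppressed, np.nan, observed)
    counties["suppressed"] = suppressed
    counties["suppression_limit"] = np.where(suppressed, lim, np.nan)
    return counties


def generate_dataset(
    config: SyntheticConfig, params: TrueParameters | None = None
) -> dict:
    """Run the whole generator: map → facilities → exposure → field → counts
    → reporting policy → state totals.

    Returns a dict with ``counties`` (including exposure, truth and observed
    columns), ``tracts`` (with nearest-facility distance and travel time),
    ``facilities``, ``adjacency`` and ``state_totals``. State reference
    totals are the true totals perturbed by ~5% multiplicative noise,
    emulating the discrepancy between state reports and an independent
    national tally that motivates the count-adjustment rule.
    """
    params = params or TrueParameters()
    counties, tracts, adjacency = generate_map(config)
    facilities = place_facilities(tracts, config)

    rng = _stage_rng(config.seed, 3)
    tracts = tracts.copy()
    tracts["distance"] = access.nearest_facility_distances(tracts, facilities)
    # travel time at ~48 mph with lognormal route noise
    tracts["time_minutes"] = (
        tracts["distance"] / 48.0 * 60.0 * rng.lognormal(0.0, 0.08, size=len(tracts))
    )

    acc = access.build_county_access(tracts, facilities)
    counties = counties.merge(acc, on="county_id")
    time_rows = []
    for cid, grp in tracts.groupby("county_id", sort=True):
        grp = grp.drop(columns=["distance"]).rename(columns={"time_minutes": "distance"})
        time_rows.append(
            {"county_id": cid, "median_time": access.county_median_distance(grp)}
        )
    times = pd.DataFrame(time_rows)
    times["time_category"] = access.categorize_distance(
        times["median_time"].to_numpy(), access.TIME_CATEGORIES
    ).to_numpy()
    counties = counties.merge(times, on="county_id")

    fld = simulate_field(adjacency, params, seed=int(_stage_rng(config.seed, 4).integers(2**31)))
    counties = simulate_counts(
        counties, fld, params, seed=int(_stage_rng(config.seed, 5).integers(2**31))
    )
    counties = apply_reporting_policy(counties, config)

    rng_tot = _stage_rng(config.seed, 6)
    true_totals = counties.groupby("state_id")["abortions_true"].sum()
    noise = rng_tot.lognormal(0.0, 0.05, size=len(true_totals))
    reported = (
        counties[counties["abortions"].notna()].groupby("state_id")["abortions"].sum()
    )
    state_totals = pd.DataFrame(
        {
            "state_id": true_totals.index,
            "reported_total": true_totals.index.map(reported).fillna(0).astype(float),
            "reference_total": np.round(true_totals.to_numpy() * noise).astype(int),
        }
    ).reset_index(drop=True)

    return {
        "counties": counties,
        "tracts": tracts,
        "facilities": facilities,
        "adjacency": adjacency,
        "state_totals": state_totals,
        "params": params,
    }
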
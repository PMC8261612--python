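"""Data-preparation rules for county abortion counts.

Three rules applied before modelling:

1. *State reconciliation* — where a state's summed county counts disagree
   with an independent reference total (e.g. a national surveillance tally)
   by more than a tolerance (default 1%), county counts are scaled
   proportionally and re-integerized by the largest-remainder method so the
   state sum matches the reference exactly.
2. *Suppression imputation* — a count suppressed below a disclosure limit L
   is replaced by the midpoint L/2 unless that would push the county's rate
   above the state mean rate, in which case the count stays missing.
3. *Rate computation* — rate per 1000 = 1000 · count / female population
   aged 15-44.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, ParameterError

__all__ = [
    "largest_remainder",
    "adjust_state_counts",
    "state_mean_rates",
    "impute_suppressed",
    "impute_all_suppressed",
    "compute_rates",
]

logger = logging.getLogger(__name__)


def largest_remainder(values: np.ndarray, target: int) -> np.ndarray:
    """Integerize nonnegative values so they sum to ``target``.

    Scales values proportionally to the target, takes floors, then hands the
    remaining units to the largest fractional remainders (ties to the lowest
    index). Preserves each value's share as closely as integers allow.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ParameterError("values must be nonnegative")
    if target < 0:
        raise ParameterError("target must be nonnegative")
    if len(v) == 0:
        raise ParameterError("cannot distribute a total over zero counties")
    if v.sum() == 0:
        # all-zero counts with a positive target: spread evenly from the front
        base, extra = divmod(int(target), len(v))
        out = np.full(len(v), base, dtype=int)
        out[:extra] += 1
        return out
    scaled = v * (target / v.sum())
    floors = np.floor(scaled).astype(int)
    short = int(round(target - floors.sum()))
    frac = scaled - floors
    order = np.lexsort((np.arange(len(v)), -frac))
    floors[order[:short]] += 1
    return floors


def adjust_state_counts(
    counties: pd.DataFrame, totals: pd.DataFrame, tolerance: float = 0.01
) -> pd.DataFrame:
    """Reconcile county counts to state reference totals.

    For each state whose observed county sum disagrees with the reference
    total by more than ``tolerance`` (relative), scale the observed counts
    by reference/reported and re-integerize by largest remainder so the
    state sum equals the reference exactly. Suppressed and missing counts
    are untouched and excluded from the reported sum. A zero reference with
    positive reported counts is flagged and the state left unadjusted.
    Idempotent: a second pass changes nothing.
    """
    counties = counties.copy()
    ref = totals.set_index("state_id")["reference_total"]
    observed = counties["abortions"].notna()
    missing_states = set(counties.loc[observed, "state_id"]) - set(ref.index)
    if missing_states:
        raise ParameterError(
            f"states with observed counts absent from totals: {sorted(missing_states)}"
        )
    for state, grp in counties[observed].groupby("state_id"):
        reference = float(ref[state])
        reported = float(grp["abortions"].sum())
        if reference == 0:
            if reported > 0:
                logger.warning(
                    "state %s: reference total is 0 but %s reported; left unadjusted",
                    state,
                    reported,
                )
            continue
        if abs(reported - reference) / reference <= tolerance:
            continue
        new = largest_remainder(grp["abortions"].to_numpy(), int(round(reference)))
        counties.loc[grp.index, "abortions"] = new.astype(float)
    return counties


def state_mean_rates(counties: pd.DataFrame) -> pd.Series:
    """Pooled state mean rate per 1000: 1000 · Σy / ΣP over observed counties.

    Computed before imputation, so the guard in :func:`impute_suppressed`
    compares against the rate implied by the state's directly observed
    counts only.
    """
    obs = counties[counties["abortions"].notna()]
    grp = obs.groupby("state_id")
    return 1000.0 * grp["abortions"].sum() / grp["pop_f1544"].sum()


def impute_suppressed(
    pop_f1544: float, limit: float, state_mean_rate: float
) -> float:
    """Midpoint imputation for one suppressed county.

    Candidate count = L/2; accepted only if the implied rate per 1000 does
    not exceed the state mean rate, otherwise the count stays missing (NaN).
    """
    if pop_f1544 <= 0:
        raise InvalidRecordError("suppressed county with nonpositive population")
    if limit <= 0:
        raise InvalidRecordError("suppression limit must be positive")
    candidate = limit / 2.0
    if 1000.0 * candidate / pop_f1544 <= state_mean_rate:
        return candidate
    return np.nan


def impute_all_suppressed(counties: pd.DataFrame) -> pd.DataFrame:
    """Apply midpoint imputation to every suppressed county.

    State mean rates are the pooled rates of the observed (unsuppressed)
    counties, frozen before any imputation.
    """
    counties = counties.copy()
    means = state_mean_rates(counties)
    mask = counties.get("suppressed")
    if mask is None:
        return counties
    for idx in counties.index[mask.astype(bool)]:
        row = counties.loc[idx]
        counties.loc[idx, "abortions"] = impute_suppressed(
            float(row["pop_f1544"]),
            float(row["suppression_limit"]),
            float(means.get(row["state_id"], np.inf)),
        )
    return counties


def compute_rates(counties: pd.DataFrame) -> pd.DataFrame:
    """Attach rate per 1000 female residents aged 15-44 where counts exist."""
    counties = counties.copy()
    pop = counties["pop_f1544"].to_numpy(float)
    if np.any(pop <= 0):
        raise InvalidRecordError("county with nonpositive population")
    counties["rate_per_1000"] = 1000.0 * counties["abortions"] / counties["pop_f1544"]
    return counties
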
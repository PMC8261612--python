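"""Published 2015 national reference figures.

National aggregates from the published county-level study of US abortion
rates and travel distance, kept here as plain data. They serve two
purposes: internal arithmetic-consistency checks (differences, percent
changes and pooled mean rates recomputed from the printed totals must
reproduce the printed derived values after rounding) and worked examples
in the documentation. Nothing in the estimation code depends on them.

Counts are printed rounded to the nearest 10; rates are per 1000 female
residents aged 15-44.
"""

#: 27 reporting states, 1948 counties: reported abortions and female
#: residents aged 15-44.
REPORTED_ABORTIONS = 428_720
REPORTED_WOMEN_15_44 = 37.3e6
REPORTED_MEAN_RATE = 11.5

#: 48 contiguous states, 3107 counties: model-based national estimates
#: under actual travel-distance conditions and the two counterfactual caps.
NATIONAL_WOMEN_15_44 = 62_539_010
ESTIMATED_ABORTIONS = {
    "actual": 696_470,
    "under_30": 714_660,
    "under_5": 767_390,
}
ESTIMATED_MEAN_RATE_ACTUAL = 11.1

#: Printed increases versus actual conditions.
PRINTED_INCREASE = {"under_30": 18_190, "under_5": 70_920}
PRINTED_PCT_INCREASE = {"under_30": 2.6, "under_5": 10.2}

#: Adjusted log-rate contrasts of the travel-distance categories versus
#: <5 miles (the published dose-response decline), used as generative truth
#: in parameter-recovery experiments.
ADJUSTED_DISTANCE_CONTRASTS = (-0.05, -0.22, -0.34, -0.43, -0.73)


def derived_national_quantities() -> dict:
    """Recompute the derived national quantities from the printed totals.

    Returns absolute and percent increases for both scenario caps, the
    pooled national mean rate under actual conditions, and the pooled mean
    reported rate in the reporting states — each computed from the raw
    printed totals, not copied from the printed derived values.
    """
    actual = ESTIMATED_ABORTIONS["actual"]
    out = {}
    for cap in ("under_30", "under_5"):
        diff = ESTIMATED_ABORTIONS[cap] - actual
        out[f"increase_{cap}"] = diff
        out[f"pct_increase_{cap}"] = 100.0 * diff / actual
    out["mean_rate_actual"] = 1000.0 * actual / NATIONAL_WOMEN_15_44
    out["reported_mean_rate"] = 1000.0 * REPORTED_ABORTIONS / REPORTED_WOMEN_15_44
    return out
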
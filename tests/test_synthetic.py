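"""Synthetic study-population generator: map layout, CAR field, Poisson
counts, reporting and suppression behaviour."""

import numpy as np
import pandas as pd
import pytest

from abaccess.errors import ParameterError
from abaccess.spatial import morans_i
from abaccess.synthetic import (
    COVARIATE_NAMES,
    SyntheticConfig,
    TrueParameters,
    apply_reporting_policy,
    generate_dataset,
    generate_map,
    simulate_counts,
    simulate_field,
)
from conftest import small_config


def tiny_config(**kw):
    base = dict(
        n_states=2,
        counties_per_state=(2, 2),
        tracts_per_county=(1, 1),
        grid_extent=100.0,
        facility_count=1,
        seed=0,
        nonreporting_fraction=0.0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateMap:
    def test_smallest_config(self):
        counties, tracts, g = generate_map(tiny_config())
        assert len(counties) == 4
        assert len(tracts) == 4
        assert g.n_nodes == 4

    def test_same_seed_reproduces_identical_map(self):
        c1, t1, _ = generate_map(small_config(seed=3))
        c2, t2, _ = generate_map(small_config(seed=3))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_study_scale_map(self):
        cfg = SyntheticConfig(
            n_states=27, counties_per_state=(66, 78), tracts_per_county=(1, 2),
            facility_count=100, seed=1,
        )
        counties, _, g = generate_map(cfg)
        assert 27 * 66 <= len(counties) <= 27 * 78  # ≈1948 counties
        assert g.n_components == 1

    def test_states_are_contiguous_blocks(self):
        counties, _, g = generate_map(small_config(seed=5))
        for _, grp in counties.groupby("state_id"):
            sub = g.subgraph(grp["county_id"].to_numpy())
            assert sub.n_components == 1

    def test_every_county_has_an_analyzable_tract(self):
        counties, tracts, _ = generate_map(small_config(seed=9))
        ok = tracts[~tracts["excluded"]].groupby("county_id").size()
        assert set(counties["county_id"]) == set(ok.index)
        assert (counties["pop_f1544"] > 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            tiny_config(counties_per_state=(3, 2))
        with pytest.raises(ParameterError):
            tiny_config(nonreporting_fraction=1.5)
        with pytest.raises(ParameterError):
            tiny_config(n_states=0)


class TestSimulateField:
    @pytest.fixture(scope="class")
    def graph(self):
        _, _, g = generate_map(small_config(seed=2))
        return g

    def test_zero_sd_gives_zero_field(self, graph):
        f = simulate_field(graph, TrueParameters(mrf_sd=0.0), seed=1)
        assert np.all(f == 0)

    def test_centered_per_component(self, graph):
        f = simulate_field(graph, TrueParameters(), seed=4)
        for c in np.unique(graph.components):
            assert abs(f[graph.components == c].mean()) < 1e-10

    def test_scaled_to_target_sd(self, graph):
        f = simulate_field(graph, TrueParameters(mrf_sd=0.7), seed=4)
        assert f.std() == pytest.approx(0.7)

    def test_positive_spatial_autocorrelation_at_high_rho(self, graph):
        vals = [
            morans_i(simulate_field(graph, TrueParameters(mrf_correlation=0.95), s), graph)
            for s in range(200)
        ]
        assert np.mean(vals) > 0.1

    def test_autocorrelation_increases_with_rho(self, graph):
        means = []
        for rho in (0.3, 0.9, 0.99):
            p = TrueParameters(mrf_correlation=rho)
            means.append(
                np.mean([morans_i(simulate_field(graph, p, s), graph) for s in range(60)])
            )
        assert means[0] < means[1] < means[2]

    def test_invalid_rho_rejected(self, graph):
        for rho in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                simulate_field(graph, TrueParameters(mrf_correlation=rho), seed=0)


class TestSimulateCounts:
    def _counties(self, n=1, pop=1000.0):
        df = pd.DataFrame(
            {
                "county_id": range(n),
                "pop_f1544": [pop] * n,
                "distance_category": ["<5"] * n,
                "policy_grade": ["A"] * n,
            }
        )
        for name in COVARIATE_NAMES:
            df[name] = 0.0
        return df

    def _null_params(self, intercept):
        return TrueParameters(
            intercept=intercept,
            covariate_effects=(0.0,) * 7,
            distance_category_effects=(0.0, 0.0, 0.0, 0.0, 0.0),
            policy_grade_effects={g: 0.0 for g in "ABCDF"},
            mrf_sd=0.0,
        )

    def test_closed_form_expectation(self):
        c = self._counties(n=400, pop=1000.0)
        p = self._null_params(np.log(10.0))
        out = simulate_counts(c, np.zeros(400), p, seed=5)
        assert np.allclose(out["true_rate"], 10.0)
        assert out["abortions_true"].mean() == pytest.approx(10.0, rel=0.05)

    def test_offset_doubles_expected_count_at_fixed_rate(self):
        p = self._null_params(np.log(10.0))
        small = simulate_counts(self._counties(n=500, pop=1000.0), np.zeros(500), p, seed=6)
        big = simulate_counts(self._counties(n=500, pop=2000.0), np.zeros(500), p, seed=6)
        assert np.allclose(big["true_rate"], small["true_rate"])
        ratio = big["abortions_true"].mean() / small["abortions_true"].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_mean_rate_declines_monotonically_across_categories(self):
        """With the published adjusted contrasts as truth, mean simulated
        rates fall monotonically with distance category."""
        labels = ["<5", "5-<15", "15-<30", "30-<60", "60-<120", ">=120"]
        df = self._counties(n=600, pop=5000.0)
        df["distance_category"] = np.repeat(labels, 100)
        p = TrueParameters(
            covariate_effects=(0.0,) * 7,
            policy_grade_effects={g: 0.0 for g in "ABCDF"},
            mrf_sd=0.0,
        )
        rates = np.zeros((100, 6))
        for rep in range(100):
            out = simulate_counts(df, np.zeros(600), p, seed=rep)
            obs_rate = 1000.0 * out["abortions_true"] / out["pop_f1544"]
            rates[rep] = obs_rate.groupby(out["distance_category"]).mean()[labels]
        mean_rates = rates.mean(axis=0)
        assert np.all(np.diff(mean_rates) < 0)


class TestReportingPolicy:
    @pytest.fixture(scope="class")
    def counted(self):
        cfg = small_config(seed=4, nonreporting_fraction=0.0)
        counties, _, g = generate_map(cfg)
        counties["distance_category"] = "<5"
        counties = simulate_counts(counties, np.zeros(len(counties)), TrueParameters(mrf_sd=0), 3)
        return counties

    def test_identity_when_nothing_suppressed(self, counted):
        cfg = small_config(nonreporting_fraction=0.0, suppression_limit_by_state={})
        out = apply_reporting_policy(counted, cfg)
        assert np.array_equal(out["abortions"], out["abortions_true"])
        assert not out["suppressed"].any()

    def test_suppression_rule_forced(self, counted):
        state = counted["state_id"].iloc[0]
        big = counted["abortions_true"].max() + 1
        cfg = small_config(
            nonreporting_fraction=0.0, suppression_limit_by_state={state: int(big)}
        )
        out = apply_reporting_policy(counted, cfg)
        in_state = out["state_id"] == state
        assert out.loc[in_state, "suppressed"].all()
        assert (out.loc[in_state, "suppression_limit"] == big).all()
        assert out.loc[in_state, "abortions"].isna().all()
        assert out.loc[~in_state, "abortions"].notna().all()

    def test_full_nonreporting_blanks_everything(self, counted):
        cfg = small_config(nonreporting_fraction=1.0, suppression_limit_by_state={})
        out = apply_reporting_policy(counted, cfg)
        assert out["abortions"].isna().all()


class TestDataset:
    def test_dataset_is_deterministic(self, small_dataset):
        again = generate_dataset(small_config())
        for key in ("counties", "tracts", "facilities", "state_totals"):
            pd.testing.assert_frame_equal(small_dataset[key], again[key])

    def test_covariate_slopes_recoverable_at_large_population(self):
        """Log empirical rates regress onto covariates with the generative
        slopes when Poisson noise is negligible (huge offsets)."""
        cfg = small_config(seed=8, nonreporting_fraction=0.0, suppression_limit_by_state={})
        counties, _, g = generate_map(cfg)
        counties["pop_f1544"] = 10_000_000
        counties["distance_category"] = "<5"
        params = TrueParameters(
            policy_grade_effects={g: 0.0 for g in "ABCDF"}, mrf_sd=0.0
        )
        out = simulate_counts(counties, np.zeros(len(counties)), params, seed=2)
        lograte = np.log(1000.0 * out["abortions_true"] / out["pop_f1544"])
        X = np.c_[np.ones(len(out)), out[list(COVARIATE_NAMES)].to_numpy()]
        beta = np.linalg.lstsq(X, lograte, rcond=None)[0]
        assert np.allclose(beta[1:], params.covariate_effects, atol=0.05)
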
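"""Penalized IRLS estimator: design construction, oracle equivalences,
field constraints, hyperparameter selection, residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from abaccess.errors import ConstantInputError, ParameterError, SelectionError
from abaccess.model import (
    Design,
    ModelSpec,
    build_design,
    fit_model,
    fit_penalized_gaussian,
    fit_penalized_poisson,
    harmonic_extension,
    predict_fixed_eta,
    residual_moran,
    select_hyperparameters,
)
from abaccess.spatial import build_adjacency, graph_laplacian
from abaccess.synthetic import COVARIATE_NAMES, TrueParameters, generate_dataset
from conftest import recovery_config, small_config


def random_design(rng, n, p, include_field=False, county_ids=None):
    X = np.c_[np.ones(n), rng.normal(0, 0.5, size=(n, p - 1))]
    beta = rng.normal(0, 0.4, size=p)
    offset = np.log(rng.uniform(0.5, 20.0, n))
    mu = np.exp(offset + X @ beta)
    y = rng.poisson(mu).astype(float)
    return Design(
        X=X,
        y=y,
        offset=offset,
        colnames=[f"b{j}" for j in range(p)],
        county_ids=np.arange(n) if county_ids is None else county_ids,
        grade_levels_present=("A",),
        include_field=include_field,
    )


def single_county_frame():
    df = pd.DataFrame(
        {
            "county_id": [0],
            "state_id": ["A"],
            "pop_f1544": [1000.0],
            "abortions": [5.0],
            "distance_category": ["<5"],
            "policy_grade": ["A"],
        }
    )
    for c in COVARIATE_NAMES:
        df[c] = 0.0
    return df


class TestBuildDesign:
    def test_single_reference_county_row(self):
        d = build_design(single_county_frame(), ModelSpec())
        # intercept + 7 covariates + 5 category dummies (+0 grade dummies)
        assert d.X.shape == (1, 13)
        assert d.matrix.shape == (1, 14)  # + its own MRF column
        row = d.matrix.toarray()[0]
        # reference category, zero covariates: only intercept and MRF nonzero
        assert row[0] == 1.0 and row[-1] == 1.0 and np.all(row[1:-1] == 0.0)

    def test_exactly_one_category_dummy_set(self, midsize_dataset):
        c = midsize_dataset["counties"]
        d = build_design(c, ModelSpec())
        cat_cols = [i for i, n in enumerate(d.colnames) if n.startswith("cat_")]
        dummies = d.X[:, cat_cols]
        top = c[c["distance_category"] == ">=120"].index[0]
        pos = c.index.get_loc(top)
        assert dummies[pos].sum() == 1.0
        ref = (c["distance_category"] == "<5").to_numpy()
        assert np.all(dummies[ref].sum(axis=1) == 0.0)

    def test_column_count_arithmetic(self, midsize_dataset):
        c = midsize_dataset["counties"]
        d = build_design(c, ModelSpec())
        n_grades = len(d.grade_levels_present)
        assert d.matrix.shape[1] == 1 + 7 + 5 + (n_grades - 1) + d.n

    def test_unknown_category_level_rejected(self):
        df = single_county_frame().assign(distance_category="5-15 miles")
        with pytest.raises(ParameterError):
            build_design(df, ModelSpec())


class TestOracleEquivalence:
    def test_lambda_zero_matches_reference_glm(self, rng):
        """Without the field, the IRLS solver is an ordinary Poisson GLM."""
        import statsmodels.api as sm

        for _ in range(10):
            n, p = int(rng.integers(40, 300)), int(rng.integers(2, 7))
            d = random_design(rng, n, p)
            fit = fit_penalized_poisson(d, None, lam=0.0, tol=1e-12)
            ref = sm.GLM(d.y, d.X, family=sm.families.Poisson(), offset=d.offset).fit()
            assert np.allclose(fit.params, ref.params, rtol=1e-6, atol=1e-8)

    def test_huge_lambda_shrinks_field_to_unpenalized_glm(self, rng):
        import statsmodels.api as sm

        n = 60
        d = random_design(rng, n, 4, include_field=True)
        pts = pd.DataFrame(
            {"county_id": np.arange(n), "x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n)}
        )
        S = graph_laplacian(build_adjacency(pts, mode="distance", snap=2.5))
        fit = fit_penalized_poisson(d, S, lam=1e12, tol=1e-12)
        assert np.max(np.abs(fit.field)) < 1e-6
        ref = sm.GLM(d.y, d.X, family=sm.families.Poisson(), offset=d.offset).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-5)

    def test_gaussian_identity_matches_closed_form_ridge(self, rng):
        """Identity-link least squares equals (AᵀA + λS̃)⁻¹Aᵀy exactly."""
        n = 40
        d = random_design(rng, n, 4, include_field=True)
        d.X = d.X[:, 1:]  # drop the intercept so the penalized system is PD
        d.colnames = d.colnames[1:]
        pts = pd.DataFrame(
            {"county_id": np.arange(n), "x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n)}
        )
        S = graph_laplacian(build_adjacency(pts, mode="distance", snap=3.0))
        lam = 2.5
        theta = fit_penalized_gaussian(d, S, lam)
        A = d.matrix.toarray()
        p = d.X.shape[1]
        Spad = np.zeros((A.shape[1], A.shape[1]))
        Spad[p:, p:] = lam * S.toarray()
        oracle = np.linalg.solve(A.T @ A + Spad, A.T @ (d.y - d.offset))
        assert np.allclose(theta, oracle, atol=1e-8)


class TestIRLSBehaviour:
    @pytest.fixture(scope="class")
    def fitted(self, midsize_dataset):
        d = midsize_dataset
        return fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=10.0)

    def test_converges_with_finite_deviance(self, fitted):
        assert fitted.converged
        assert np.isfinite(fitted.deviance)

    def test_field_sums_to_zero_per_component(self, fitted):
        assert fitted.constraint_residual() < 1e-8

    def test_penalized_deviance_monotone_in_iterations(self, midsize_dataset):
        d = midsize_dataset
        devs = []
        for k in range(1, 8):
            f = fit_model(d["counties"], d["adjacency"], ModelSpec(max_iter=k), lam=10.0)
            devs.append(f.penalized_deviance)
        assert all(b <= a + 1e-6 for a, b in zip(devs, devs[1:]))

    def test_training_deviance_nondecreasing_in_lambda(self, midsize_dataset):
        d = midsize_dataset
        devs = [
            fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=lam).deviance
            for lam in (0.1, 10.0, 1000.0, 1e5)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(devs, devs[1:]))

    def test_nonconvergence_is_flagged(self, midsize_dataset):
        d = midsize_dataset
        f = fit_model(d["counties"], d["adjacency"], ModelSpec(max_iter=1, tol=1e-14), lam=10.0)
        assert not f.converged


class TestHarmonicExtension:
    def test_held_out_node_takes_neighbour_mean(self):
        pts = pd.DataFrame(
            {
                "county_id": np.arange(4),
                "row": [0, 0, 1, 1],
                "col": [0, 1, 0, 1],
            }
        )
        g = build_adjacency(pts, mode="contiguity")
        # node 3 neighbours nodes 1 and 2
        f = harmonic_extension(g, np.array([0, 1, 2]), np.array([0.0, 0.4, -0.2]), np.array([3]))
        assert f[0] == pytest.approx((0.4 - 0.2) / 2, abs=1e-6)

    def test_disconnected_target_gets_zero(self):
        pts = pd.DataFrame(
            {"county_id": np.arange(3), "x": [0.0, 1.0, 50.0], "y": [0.0, 0.0, 0.0]}
        )
        g = build_adjacency(pts, mode="distance", snap=2.0)
        f = harmonic_extension(g, np.array([0, 1]), np.array([0.5, -0.5]), np.array([2]))
        assert f[0] == pytest.approx(0.0, abs=1e-6)


class TestHyperparameterSelection:
    def test_single_grid_point_returned_trivially(self, small_dataset):
        d = small_dataset
        spec = ModelSpec(lambda_grid=(10.0,))
        lam, snap, table = select_hyperparameters(d["counties"], lambda s: d["adjacency"], spec)
        assert lam == 10.0 and snap is None
        assert len(table) == 1

    def test_implausible_rates_disqualify_grid_point(self):
        """True rates around 150 per 1000 trip the >100 plausibility screen."""
        cfg = small_config(seed=21, nonreporting_fraction=0.0)
        params = TrueParameters(
            intercept=np.log(150.0),
            covariate_effects=(0.0,) * 7,
            distance_category_effects=(0.0,) * 5,
            policy_grade_effects={g: 0.0 for g in "ABCDF"},
            mrf_sd=0.1,
        )
        d = generate_dataset(cfg, params)
        spec = ModelSpec(lambda_grid=(10.0,))
        with pytest.raises(SelectionError):
            select_hyperparameters(d["counties"], lambda s: d["adjacency"], spec)

    def test_cv_table_records_diagnostics(self, small_dataset):
        d = small_dataset
        spec = ModelSpec(lambda_grid=(1.0, 100.0))
        _, _, table = select_hyperparameters(d["counties"], lambda s: d["adjacency"], spec)
        assert {"lambda", "cv_mse", "moran_i", "max_predicted_rate", "plausible"} <= set(
            table.columns
        )
        assert table["cv_mse"].notna().all()


class TestResidualMoran:
    def test_matches_manual_composition(self, midsize_dataset):
        from abaccess.model import deviance_residuals
        from abaccess.spatial import morans_i

        d = midsize_dataset
        fit = fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=10.0)
        got = residual_moran(fit, d["counties"], d["adjacency"])
        y = (
            d["counties"].set_index("county_id")["abortions"].loc[fit.county_ids].to_numpy()
        )
        manual = morans_i(
            deviance_residuals(y, fit.fitted_mu), d["adjacency"].subgraph(fit.county_ids)
        )
        assert got == pytest.approx(manual)

    def test_perfect_fit_is_degenerate(self):
        """Equal counts and populations fit exactly; zero residuals leave
        Moran's I undefined."""
        df = pd.concat([single_county_frame()] * 4, ignore_index=True)
        df["county_id"] = np.arange(4)
        df["x"], df["y"] = [0.0, 1.0, 0.0, 1.0], [0.0, 0.0, 1.0, 1.0]
        df["row"], df["col"] = [0, 0, 1, 1], [0, 1, 0, 1]
        g = build_adjacency(df, mode="contiguity")
        fit = fit_model(df, g, ModelSpec(), lam=1.0)
        fit.fitted_mu = df["abortions"].to_numpy(float)  # response == fitted
        with pytest.raises(ConstantInputError):
            residual_moran(fit, df, g)

    def test_permuted_residuals_show_no_autocorrelation(self, midsize_dataset, rng):
        from abaccess.model import deviance_residuals
        from abaccess.spatial import morans_i

        d = midsize_dataset
        fit = fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=10.0)
        y = d["counties"].set_index("county_id")["abortions"].loc[fit.county_ids].to_numpy()
        resid = deviance_residuals(y, fit.fitted_mu)
        sub = d["adjacency"].subgraph(fit.county_ids)
        n = len(resid)
        vals = [morans_i(rng.permutation(resid), sub) for _ in range(50)]
        assert abs(np.mean(vals) - (-1 / (n - 1))) < 0.01


class TestPrediction:
    def test_unseen_grade_merges_to_nearest_worse(self, midsize_dataset, caplog):
        d = midsize_dataset
        fit = fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=10.0)
        row = d["counties"].iloc[[0]].copy()
        missing = next(g for g in "ABCDF" if g not in fit.grade_levels_present)
        row["policy_grade"] = missing
        with caplog.at_level("WARNING", logger="abaccess.model"):
            eta = predict_fixed_eta(fit, row, ModelSpec())
        assert np.isfinite(eta).all()
        assert any("merged" in r.message for r in caplog.records)

    def test_unseen_category_is_error(self, midsize_dataset):
        d = midsize_dataset
        fit = fit_model(d["counties"], d["adjacency"], ModelSpec(), lam=10.0)
        row = d["counties"].iloc[[0]].copy()
        row["distance_category"] = "over the rainbow"
        with pytest.raises(ParameterError):
            predict_fixed_eta(fit, row, ModelSpec())
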
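"""Spatial Poisson rate model with an MRF smooth.

The estimator is a Poisson regression of county abortion counts with a
log(population/1000) offset, linear covariates, treatment-coded travel
distance and policy-grade categories, and one random effect per county
(the Markov-random-field smooth). The field f is penalized by the graph
Laplacian quadratic form λ·fᵀSf, which shrinks differences between
neighbouring counties; the penalized likelihood is maximized by iteratively
reweighted least squares (IRLS) with a per-component sum-to-zero projection
of the field each iteration. The smoothing parameter λ (and optionally the
snap tolerance of the adjacency) is chosen by state-grouped
cross-validation: each fold holds out all counties of one state, the
held-out field values are determined by the penalty alone given the fitted
neighbours (a harmonic extension on the graph), and grid points producing
implausible rates (>100 per 1000) are disqualified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.special import xlogy
from scipy.stats import norm

from .access import DISTANCE_CATEGORIES, DistanceCategories
from .errors import ParameterError, SelectionError
from .spatial import AdjacencyGraph, graph_laplacian, morans_i
from .synthetic import COVARIATE_NAMES, GRADE_LEVELS

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "build_design",
    "fit_penalized_poisson",
    "harmonic_extension",
    "predict_fixed_eta",
    "fit_model",
    "select_hyperparameters",
    "residual_moran",
    "analyzable",
]

logger = logging.getLogger(__name__)

#: Rates above this (per 1000) are considered implausible during CV.
PLAUSIBLE_MAX_RATE = 100.0

_DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.linspace(-2, 6, 13))


@dataclass
class ModelSpec:
    """Model structure and tuning grids."""

    covariates: tuple = COVARIATE_NAMES
    exposure_col: str = "distance_category"
    categories: DistanceCategories = dc_field(default_factory=lambda: DISTANCE_CATEGORIES)
    grade_col: str = "policy_grade"
    grade_levels: tuple = GRADE_LEVELS
    lambda_grid: tuple = _DEFAULT_LAMBDA_GRID
    snap_grid: tuple = (None,)
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self):
        if len(self.lambda_grid) == 0 or len(self.snap_grid) == 0:
            raise ParameterError("hyperparameter grids must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ParameterError("lambda values must be nonnegative")


def analyzable(counties: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Counties usable for fitting: observed count, positive population,
    complete covariates, known exposure category and policy grade."""
    ok = (
        counties["abortions"].notna()
        & (counties["pop_f1544"] > 0)
        & counties[list(spec.covariates)].notna().all(axis=1)
        & counties[spec.exposure_col].notna()
        & counties[spec.grade_col].notna()
    )
    return counties[ok]


@dataclass
class Design:
    """Design matrix pieces for the penalized Poisson fit.

    ``X`` is the fixed-effect block (intercept, covariates, exposure and
    grade dummies); the MRF block is an identity over the design counties,
    appended by :attr:`matrix`. The offset log(P/1000) makes the intercept a
    log rate per 1000.
    """

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    colnames: list
    county_ids: np.ndarray
    grade_levels_present: tuple
    include_field: bool = True

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def matrix(self) -> sp.csr_matrix:
        Xs = sp.csr_matrix(self.X)
        if not self.include_field:
            return Xs
        return sp.hstack([Xs, sp.identity(self.n, format="csr")], format="csr")

    @property
    def full_colnames(self) -> list:
        if not self.include_field:
            return list(self.colnames)
        return list(self.colnames) + [f"f_{c}" for c in self.county_ids]


def build_design(
    counties: pd.DataFrame, spec: ModelSpec, include_field: bool = True
) -> Design:
    """Assemble response, offset and fixed-effect design for the fit.

    Treatment coding for the exposure (reference = first category, <5
    miles) and the policy grade (reference = best grade present). An
    exposure level outside the declared label set is an error.
    """
    counties = analyzable(counties, spec)
    if len(counties) == 0:
        raise ParameterError("no analyzable counties")
    y = counties["abortions"].to_numpy(float)
    pop = counties["pop_f1544"].to_numpy(float)
    offset = np.log(pop / 1000.0)

    labels = spec.categories.labels
    cats = counties[spec.exposure_col].astype(str)
    unseen = set(cats) - set(labels)
    if unseen:
        raise ParameterError(f"exposure categories outside the label set: {sorted(unseen)}")
    blocks = [np.ones((len(counties), 1))]
    names = ["intercept"]
    blocks.append(counties[list(spec.covariates)].to_numpy(float))
    names += list(spec.covariates)
    for lab in labels[1:]:
        blocks.append((cats == lab).to_numpy(float)[:, None])
        names.append(f"cat_{lab}")
    grades = counties[spec.grade_col].astype(str)
    present = tuple(g for g in spec.grade_levels if (grades == g).any())
    for g in present[1:]:
        blocks.append((grades == g).to_numpy(float)[:, None])
        names.append(f"grade_{g}")
    X = np.hstack(blocks)
    return Design(
        X=X,
        y=y,
        offset=offset,
        colnames=names,
        county_ids=counties["county_id"].to_numpy(),
        grade_levels_present=present,
        include_field=include_field,
    )


@dataclass
class FitResult:
    """Fitted coefficients, per-county MRF effects and diagnostics."""

    params: np.ndarray
    colnames: list
    field: np.ndarray
    county_ids: np.ndarray
    components: np.ndarray
    grade_levels_present: tuple
    lam: float
    snap: float | None
    deviance: float
    penalized_deviance: float
    converged: bool
    n_iter: int
    cov_fixed: np.ndarray | None = None
    fitted_mu: np.ndarray | None = None
    cv_mse: float | None = None
    residual_moran_i: float | None = None

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.params, index=self.colnames)

    @property
    def intercept(self) -> float:
        return float(self.coef["intercept"])

    def category_contrasts(self) -> pd.Series:
        names = [c for c in self.colnames if c.startswith("cat_")]
        return self.coef[names]

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals from the penalized information matrix."""
        if self.cov_fixed is None:
            raise ParameterError("fit carries no covariance")
        se = np.sqrt(np.diag(self.cov_fixed))
        zq = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "lo": self.params - zq * se,
                "hi": self.params + zq * se,
            },
            index=self.colnames,
        )

    def constraint_residual(self) -> float:
        """Largest |per-component mean| of the field (should be ~0)."""
        if len(self.field) == 0:
            return 0.0
        worst = 0.0
        for c in np.unique(self.components):
            worst = max(worst, abs(self.field[self.components == c].mean()))
        return worst


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def _components_from_laplacian(S: sp.spmatrix) -> np.ndarray:
    A = -sp.tril(S, k=-1) - sp.triu(S, k=1)
    _, labels = connected_components(A, directed=False)
    return labels


def fit_penalized_poisson(
    design: Design,
    S: sp.spmatrix | None,
    lam: float,
    max_iter: int = 100,
    tol: float = 1e-8,
    theta0: np.ndarray | None = None,
    snap: float | None = None,
) -> FitResult:
    """Maximize the Poisson log-likelihood minus (λ/2)·fᵀSf by penalized IRLS.

    Each iteration solves the penalized weighted least-squares system on the
    working response, then projects the field to per-component sum-to-zero
    (folding its global mean into the intercept). Step-halving guards the
    monotone decrease of the penalized deviance; convergence is a relative
    penalized-deviance change below ``tol``. Non-convergence is flagged on
    the result, not silently ignored.
    """
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    y, offset = design.y, design.offset
    n, p = design.n, design.p
    A = design.matrix.tocsr()
    with_field = design.include_field
    if with_field:
        if S is None or S.shape != (n, n):
            raise ParameterError("penalty matrix must align with the MRF block")
        comp = _components_from_laplacian(S)
        Spad = sp.block_diag(
            [sp.csr_matrix((p, p)), (lam * S).tocsr()], format="csr"
        )
    else:
        comp = np.zeros(0, dtype=int)
        Spad = sp.csr_matrix((p, p))
    k = A.shape[1]
    # tiny ridge keeps the system nonsingular: the field/intercept null
    # direction of the penalty, and category dummies empty in a CV fold;
    # the field block scales with lambda so conditioning stays bounded
    diag = np.full(k, 1e-8)
    if with_field:
        diag[p:] = 1e-8 * (1.0 + lam)
    ridge = sp.diags(diag)

    theta = np.zeros(k) if theta0 is None else np.asarray(theta0, float).copy()
    if theta0 is None:
        # start at the constant-rate model
        theta[0] = np.log((y.sum() + 0.5) / np.exp(offset).sum())

    # per-component sum-to-zero constraint rows over the field block,
    # enforced exactly via a KKT system at every IRLS solve
    if with_field:
        comps = np.unique(comp)
        C = sp.lil_matrix((len(comps), k))
        for row, c in enumerate(comps):
            C[row, p + np.flatnonzero(comp == c)] = 1.0
        C = C.tocsr()
        n_con = C.shape[0]
    else:
        C, n_con = None, 0

    def _constrained_solve(M, rhs):
        if not with_field:
            return spla.spsolve(M.tocsc(), rhs)
        K = sp.bmat([[M, C.T], [C, None]], format="csc")
        sol = spla.spsolve(K, np.r_[rhs, np.zeros(n_con)])
        return sol[:k]

    def _project(th):
        # used only to sanitise warm starts from a different subgraph
        if not with_field:
            return th
        th = th.copy()
        f = th[p:].copy()
        th[0] += f.mean()
        for c in np.unique(comp):
            f[comp == c] -= f[comp == c].mean()
        th[p:] = f
        return th

    def _pen_dev(th):
        mu = np.exp(np.clip(offset + A @ th, -30, 30))
        pen = lam * float(th[p:] @ (S @ th[p:])) if with_field else 0.0
        return _poisson_deviance(y, mu) + pen, mu

    theta = _project(theta)
    prev_pd, mu = _pen_dev(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta_lin = A @ theta
        W = np.clip(mu, 1e-10, None)
        z = eta_lin + (y - mu) / W
        AW = A.T.multiply(W)
        M = (AW @ A + Spad + ridge).tocsr()
        rhs = AW @ z
        theta_new = _constrained_solve(M, rhs)
        new_pd, new_mu = _pen_dev(theta_new)
        halvings = 0
        while new_pd > prev_pd + 1e-10 and halvings < 30:
            theta_new = 0.5 * (theta_new + theta)
            new_pd, new_mu = _pen_dev(theta_new)
            halvings += 1
        theta, mu = theta_new, new_mu
        if abs(prev_pd - new_pd) <= tol * (abs(prev_pd) + 0.1):
            prev_pd = new_pd
            converged = True
            break
        prev_pd = new_pd
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", max_iter)

    W = np.clip(mu, 1e-10, None)
    AW = A.T.multiply(W)
    H = (AW @ A + Spad + ridge).tocsc()
    try:
        lu = spla.splu(H)
        eye_p = np.zeros((k, p))
        eye_p[np.arange(p), np.arange(p)] = 1.0
        cov_fixed = lu.solve(eye_p)[:p, :]
        cov_fixed = 0.5 * (cov_fixed + cov_fixed.T)
    except RuntimeError:  # singular information; leave covariance out
        cov_fixed = None

    fld = theta[p:] if with_field else np.zeros(0)
    return FitResult(
        params=theta[:p],
        colnames=list(design.colnames),
        field=fld,
        county_ids=design.county_ids,
        components=comp,
        grade_levels_present=design.grade_levels_present,
        lam=float(lam),
        snap=snap,
        deviance=_poisson_deviance(y, mu),
        penalized_deviance=prev_pd,
        converged=converged,
        n_iter=it,
        cov_fixed=cov_fixed,
        fitted_mu=mu,
    )


def fit_penalized_gaussian(
    design: Design,
    S: sp.spmatrix | None,
    lam: float,
    project: bool = False,
    ridge: float = 0.0,
) -> np.ndarray:
    """Gaussian-identity limit of the penalized fit.

    Replacing the Poisson likelihood by identity-link least squares turns
    the estimator into generalized ridge regression with the padded
    Laplacian penalty: θ̂ = (AᵀA + λS̃)⁻¹Aᵀ(y − offset). Used as a numerical
    cross-check of the IRLS machinery; ``project`` applies the same
    per-component sum-to-zero projection as the Poisson path.
    """
    A = design.matrix.tocsr()
    p = design.p
    if design.include_field:
        Spad = sp.block_diag([sp.csr_matrix((p, p)), (lam * S).tocsr()], format="csr")
        comp = _components_from_laplacian(S)
    else:
        Spad = sp.csr_matrix((p, p))
        comp = np.zeros(0, dtype=int)
    M = (A.T @ A + Spad + ridge * sp.identity(A.shape[1])).tocsc()
    theta = spla.spsolve(M, A.T @ (design.y - design.offset))
    if project and design.include_field:
        f = theta[p:].copy()
        theta[0] += f.mean()
        for c in np.unique(comp):
            f[comp == c] -= f[comp == c].mean()
        theta[p:] = f
    return theta


def harmonic_extension(
    graph: AdjacencyGraph,
    fitted_ids: np.ndarray,
    fitted_field: np.ndarray,
    target_ids: np.ndarray,
) -> np.ndarray:
    """Extend the MRF field to unfitted counties by the penalty alone.

    Minimizes fᵀSf over the target values given the fitted ones, i.e.
    solves S_tt f_t = −S_tf f_f on the full graph (each target county takes
    the penalty-smoothed value of its neighbours). Target components with no
    link to any fitted county — including isolated counties — get 0.
    """
    if len(target_ids) == 0:
        return np.zeros(0)
    S = graph_laplacian(graph)
    ti = graph.index_of(target_ids)
    fi = graph.index_of(fitted_ids)
    S_tt = S[ti][:, ti].tocsc() + 1e-10 * sp.identity(len(ti), format="csc")
    rhs = -S[ti][:, fi] @ np.asarray(fitted_field, float)
    return spla.spsolve(S_tt, rhs)


def predict_fixed_eta(fit: FitResult, counties: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Fixed-effect linear predictor (log rate per 1000, no field, no offset).

    Policy grades unseen at fit time are merged with the nearest worse grade
    that was present (e.g. D→F), with a logged warning; an unseen exposure
    category is an error.
    """
    labels = spec.categories.labels
    cats = counties[spec.exposure_col].astype(str)
    unseen = set(cats) - set(labels)
    if unseen:
        raise ParameterError(f"unseen exposure categories: {sorted(unseen)}")
    coef = fit.coef
    eta = np.full(len(counties), fit.intercept)
    for name in spec.covariates:
        eta += coef[name] * counties[name].to_numpy(float)
    cat_effect = {labels[0]: 0.0}
    for lab in labels[1:]:
        cat_effect[lab] = float(coef.get(f"cat_{lab}", 0.0))
    eta += cats.map(cat_effect).to_numpy(float)

    present = fit.grade_levels_present
    order = list(spec.grade_levels)

    def merge_grade(g: str) -> str:
        if g in present:
            return g
        i = order.index(g)
        for j in list(range(i + 1, len(order))) + list(range(i - 1, -1, -1)):
            if order[j] in present:
                logger.warning("grade %s unseen at fit time; merged with %s", g, order[j])
                return order[j]
        return present[0]

    grade_map = {g: merge_grade(g) for g in counties[spec.grade_col].astype(str).unique()}
    grades = counties[spec.grade_col].astype(str).map(grade_map)
    grade_effect = {present[0]: 0.0}
    for g in present[1:]:
        grade_effect[g] = float(coef.get(f"grade_{g}", 0.0))
    eta += grades.map(grade_effect).to_numpy(float)
    return eta


def fit_model(
    counties: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    lam: float,
    snap: float | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit the penalized model on the analyzable counties.

    The MRF penalty is the Laplacian of the subgraph induced on the design
    counties (edges to unobserved counties carry no information at fit
    time; those counties receive field values by harmonic extension at
    prediction time).
    """
    design = build_design(counties, spec)
    sub = graph.subgraph(design.county_ids)
    S = graph_laplacian(sub)
    return fit_penalized_poisson(
        design, S, lam, max_iter=spec.max_iter, tol=spec.tol, theta0=theta0, snap=snap
    )


def deviance_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    d = 2.0 * (xlogy(y, y / mu) - (y - mu))
    return np.sign(y - mu) * np.sqrt(np.clip(d, 0.0, None))


def residual_moran(fit: FitResult, counties: pd.DataFrame, graph: AdjacencyGraph) -> float:
    """Moran's I of the deviance residuals on the fitted-county subgraph.

    Perfectly fitted data gives all-zero residuals, for which the statistic
    is undefined (raises :class:`ConstantInputError` rather than returning 0).
    """
    if fit.fitted_mu is None:
        raise ParameterError("fit carries no fitted values")
    y = (
        counties.set_index("county_id")["abortions"]
        .loc[fit.county_ids]
        .to_numpy(float)
    )
    resid = deviance_residuals(y, fit.fitted_mu)
    return morans_i(resid, graph.subgraph(fit.county_ids))


def select_hyperparameters(
    counties: pd.DataFrame,
    adjacency_builder,
    spec: ModelSpec,
) -> tuple[float, float | None, pd.DataFrame]:
    """Choose (λ, snap) by state-grouped cross-validation.

    ``adjacency_builder(snap)`` must return the full-county
    :class:`AdjacencyGraph` for a snap value (ignore the argument for
    contiguity graphs). For every grid point each fold holds out one state's
    observed counties; the model is fitted on the rest, the held-out field
    is harmonically extended, and the fold is scored by the mean squared
    error of predicted vs observed rates per 1000. Any held-out predicted
    rate above 100 per 1000 disqualifies the grid point. Returns the argmin
    CV-MSE among qualified points (ties to the smallest λ, then snap order)
    plus the full CV table.
    """
    obs = analyzable(counties, spec)
    states = sorted(obs["state_id"].unique())
    if len(states) < 2:
        raise ParameterError("state-grouped CV needs at least 2 states with data")

    rows = []
    for snap in spec.snap_grid:
        graph = adjacency_builder(snap)
        obs_graph = graph.subgraph(obs["county_id"].to_numpy())
        fold_cache: dict = {}
        warm: dict = {}
        for st in states:
            train = obs[obs["state_id"] != st]
            test = obs[obs["state_id"] == st]
            design = build_design(train, spec)
            sub = graph.subgraph(design.county_ids)
            fold_cache[st] = (design, graph_laplacian(sub), test)
        for lam in sorted(spec.lambda_grid):
            fold_mses = []
            residuals = pd.Series(np.nan, index=obs["county_id"].to_numpy())
            max_rate = 0.0
            converged_all = True
            for st in states:
                design, S_tt, test = fold_cache[st]
                fit = fit_penalized_poisson(
                    design,
                    S_tt,
                    lam,
                    max_iter=spec.max_iter,
                    tol=max(spec.tol, 1e-7),
                    theta0=warm.get(st),
                    snap=snap,
                )
                warm[st] = np.r_[fit.params, fit.field]
                converged_all &= fit.converged
                f_test = harmonic_extension(
                    graph, fit.county_ids, fit.field, test["county_id"].to_numpy()
                )
                rate_pred = np.exp(predict_fixed_eta(fit, test, spec) + f_test)
                rate_obs = 1000.0 * test["abortions"].to_numpy(float) / test[
                    "pop_f1544"
                ].to_numpy(float)
                err = rate_pred - rate_obs
                fold_mses.append(float(np.mean(err**2)))
                residuals.loc[test["county_id"].to_numpy()] = err
                max_rate = max(max_rate, float(rate_pred.max()))
            cv_mse = float(np.mean(fold_mses))
            plausible = bool(max_rate <= PLAUSIBLE_MAX_RATE and np.isfinite(cv_mse))
            try:
                mi = morans_i(residuals.to_numpy(), obs_graph)
            except Exception:
                mi = np.nan
            rows.append(
                {
                    "snap": snap,
                    "lambda": lam,
                    "cv_mse": cv_mse,
                    "moran_i": mi,
                    "max_predicted_rate": max_rate,
                    "plausible": plausible,
                    "converged": converged_all,
                }
            )
    table = pd.DataFrame(rows)
    if not table["plausible"].any():
        raise SelectionError(
            "every (lambda, snap) grid point was disqualified by the "
            f"plausibility screen (rate > {PLAUSIBLE_MAX_RATE} per 1000): "
            f"{table[['snap', 'lambda', 'max_predicted_rate']].to_dict('records')}"
        )
    # deterministic tie-break: smallest lambda, then snap grid order
    q = table[table["plausible"]]
    tied = q[q["cv_mse"] == q["cv_mse"].min()].sort_values("lambda", kind="stable")
    lam_best = float(tied.iloc[0]["lambda"])
    snap_best = tied.iloc[0]["snap"]
    if isinstance(snap_best, float) and np.isnan(snap_best):
        snap_best = None
    return lam_best, snap_best, table
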
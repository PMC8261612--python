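"""Delimited-text readers and writers with schema validation.

Every artifact is plain CSV with a header row (or JSON for the fit
summary); rates and coefficients are written at full precision and rounded
only in report tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .model import FitResult
from .spatial import AdjacencyGraph

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_adjacency",
    "read_adjacency",
    "write_fit",
    "read_fit",
]

#: Required columns per table kind; extra columns always pass through.
SCHEMAS = {
    "counties": ["county_id", "state_id", "pop_f1544", "x", "y"],
    "tracts": ["tract_id", "county_id", "x", "y", "pop_f1544"],
    "facilities": ["facility_id", "x", "y"],
    "state_totals": ["state_id", "reported_total", "reference_total"],
    "adjacency": ["county_a", "county_b"],
    "county_access": ["county_id", "median_distance", "distance_category"],
    "truth": ["county_id", "abortions_true", "true_rate", "true_field"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a CSV artifact and validate its required columns."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(str(path), ["<file not found>"])
    df = pd.read_csv(path)
    required = SCHEMAS.get(kind, [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(str(path), missing)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> Path:
    return write_table(graph.edge_list(), path)


def read_adjacency(path: str | Path, node_ids) -> AdjacencyGraph:
    edges = read_table(path, "adjacency")
    return AdjacencyGraph.from_edge_list(edges, node_ids)


def write_fit(fit: FitResult, path: str | Path) -> Path:
    """Serialise a fit: coefficients, hyperparameters, diagnostics, field."""
    payload = {
        "coefficients": {k: float(v) for k, v in fit.coef.items()},
        "lambda": fit.lam,
        "snap": fit.snap,
        "deviance": fit.deviance,
        "penalized_deviance": fit.penalized_deviance,
        "converged": bool(fit.converged),
        "n_iter": fit.n_iter,
        "cv_mse": fit.cv_mse,
        "residual_moran_i": fit.residual_moran_i,
        "constraint_residual": fit.constraint_residual(),
        "grade_levels_present": list(fit.grade_levels_present),
        "field": {str(c): float(f) for c, f in zip(fit.county_ids, fit.field)},
        "components": [int(c) for c in fit.components],
        "cov_fixed": None
        if fit.cov_fixed is None
        else [[float(v) for v in row] for row in fit.cov_fixed],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_fit(path: str | Path) -> FitResult:
    d = json.loads(Path(path).read_text())
    coefs = d["coefficients"]
    county_ids = np.array([_maybe_int(c) for c in d["field"]])
    return FitResult(
        params=np.array(list(coefs.values()), float),
        colnames=list(coefs.keys()),
        field=np.array(list(d["field"].values()), float),
        county_ids=county_ids,
        components=np.array(d["components"], int),
        grade_levels_present=tuple(d["grade_levels_present"]),
        lam=d["lambda"],
        snap=d["snap"],
        deviance=d["deviance"],
        penalized_deviance=d["penalized_deviance"],
        converged=d["converged"],
        n_iter=d["n_iter"],
        cov_fixed=None if d["cov_fixed"] is None else np.array(d["cov_fixed"], float),
        cv_mse=d["cv_mse"],
        residual_moran_i=d["residual_moran_i"],
    )


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s
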
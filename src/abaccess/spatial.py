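"""Graph and geometry utilities for areal (county-level) analysis.

Provides the county adjacency structure, the graph-Laplacian penalty used by
the Markov-random-field smooth, Moran's I spatial autocorrelation, and the
convex-hull membership mask that governs the prediction policy (full spatial
model inside the hull of observed counties, covariates-only outside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from .errors import ConstantInputError, DegenerateHullError, ParameterError

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "graph_laplacian",
    "morans_i",
    "convex_hull_mask",
]


@dataclass
class AdjacencyGraph:
    """Undirected, binary county neighbour structure.

    Parameters
    ----------
    node_ids
        County identifiers, one per node, in matrix order.
    adjacency
        Symmetric sparse 0/1 matrix with an empty diagonal.
    """

    node_ids: np.ndarray
    adjacency: sp.csr_matrix
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids)
        A = sp.csr_matrix(self.adjacency)
        if (A != A.T).nnz:
            raise ParameterError("adjacency matrix must be symmetric")
        if A.diagonal().any():
            raise ParameterError("adjacency matrix must have an empty diagonal")
        self.adjacency = A
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def components(self) -> np.ndarray:
        """Connected-component label per node."""
        _, labels = connected_components(self.adjacency, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        n, _ = connected_components(self.adjacency, directed=False)
        return n

    def index_of(self, node_ids) -> np.ndarray:
        """Matrix positions of the given county ids."""
        return np.array([self._index[n] for n in np.asarray(node_ids)], dtype=int)

    def subgraph(self, node_ids) -> "AdjacencyGraph":
        """Induced subgraph on the given county ids (in the given order)."""
        idx = self.index_of(node_ids)
        A = self.adjacency[idx][:, idx]
        return AdjacencyGraph(np.asarray(node_ids), A.tocsr())

    def edge_list(self) -> pd.DataFrame:
        """Two-column edge list (each undirected edge once, i < j)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame(
            {"county_a": self.node_ids[coo.row], "county_b": self.node_ids[coo.col]}
        )

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame, node_ids) -> "AdjacencyGraph":
        node_ids = np.asarray(node_ids)
        index = {nid: i for i, nid in enumerate(node_ids)}
        i = np.array([index[v] for v in edges.iloc[:, 0]], dtype=int)
        j = np.array([index[v] for v in edges.iloc[:, 1]], dtype=int)
        n = len(node_ids)
        data = np.ones(len(i) * 2)
        A = sp.coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
        A.data[:] = 1.0  # collapse duplicate entries to binary weights
        return cls(node_ids, A)


def build_adjacency(
    counties: pd.DataFrame,
    mode: str = "contiguity",
    snap: float | None = None,
    contiguity: str = "rook",
) -> AdjacencyGraph:
    """Build the county neighbourhood graph.

    ``mode="distance"`` links counties whose centroids lie within ``snap``
    miles of each other; the snap tolerance is a tunable hyperparameter of
    the spatial smooth. ``mode="contiguity"`` uses the rook (edge-sharing)
    or queen (edge- or corner-sharing) neighbours of a gridded map and
    requires integer ``row``/``col`` columns.
    """
    ids = counties["county_id"].to_numpy()
    n = len(ids)
    if mode == "distance":
        if snap is None or snap <= 0:
            raise ParameterError("distance mode requires snap > 0")
        xy = counties[["x", "y"]].to_numpy(float)
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=float(snap), output_type="ndarray")
        if len(pairs) == 0:
            A = sp.csr_matrix((n, n))
        else:
            i, j = pairs[:, 0], pairs[:, 1]
            data = np.ones(len(i) * 2)
            A = sp.coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
        return AdjacencyGraph(ids, A)
    if mode == "contiguity":
        if not {"row", "col"}.issubset(counties.columns):
            raise ParameterError("contiguity mode requires 'row' and 'col' columns")
        if contiguity == "rook":
            offsets = [(0, 1), (1, 0)]
        elif contiguity == "queen":
            offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        else:
            raise ParameterError(f"unknown contiguity: {contiguity!r}")
        cells = {
            (int(r), int(c)): k
            for k, (r, c) in enumerate(zip(counties["row"], counties["col"]))
        }
        ii, jj = [], []
        for (r, c), k in cells.items():
            for dr, dc in offsets:
                other = cells.get((r + dr, c + dc))
                if other is not None:
                    ii += [k, other]
                    jj += [other, k]
        if ii:
            A = sp.coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n)).tocsr()
        else:
            A = sp.csr_matrix((n, n))
        return AdjacencyGraph(ids, A)
    raise ParameterError(f"unknown adjacency mode: {mode!r}")


def graph_laplacian(g: AdjacencyGraph) -> sp.csr_matrix:
    """Graph-Laplacian penalty matrix S = D − A.

    The quadratic form fᵀSf equals the sum of squared differences of f across
    edges, which is the roughness penalty of the MRF smooth. S is positive
    semidefinite with one zero eigenvalue per connected component.
    """
    A = g.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()


def morans_i(values, g: AdjacencyGraph, row_standardize: bool = False) -> float:
    """Global Moran's I of ``values`` on the graph ``g``.

    I = (n/W) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² with z the centred values. Binary
    weights by default (W = total weight); ``row_standardize=True`` divides
    each row of the weight matrix by its degree. Under no spatial
    correlation E[I] = −1/(n−1); positive values mean neighbours are alike.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or len(z) != g.n_nodes:
        raise ParameterError("values must be a vector aligned with the graph nodes")
    if g.n_nodes < 2:
        raise ParameterError("Moran's I requires at least 2 nodes")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ConstantInputError("Moran's I is undefined for constant input")
    W_mat = g.adjacency.astype(float)
    if row_standardize:
        deg = np.asarray(W_mat.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        W_mat = sp.diags(inv) @ W_mat
    W = W_mat.sum()
    if W == 0:
        raise ParameterError("graph has no edges; Moran's I is undefined")
    num = float(z @ (W_mat @ z))
    n = g.n_nodes
    return (n / W) * num / denom


def convex_hull_mask(observed_points, query_points, tol: float = 1e-9) -> np.ndarray:
    """True for each query point inside or on the hull of the observed points.

    Points on the hull boundary count as inside, so every observed county is
    inside its own hull. Fewer than three non-collinear observed points leave
    the hull degenerate and raise :class:`DegenerateHullError`.
    """
    obs = np.asarray(observed_points, dtype=float)
    qry = np.atleast_2d(np.asarray(query_points, dtype=float))
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ParameterError("observed_points must be an (n, 2) array")
    if obs.shape[0] < 3:
        raise DegenerateHullError("need at least 3 observed points")
    try:
        hull = ConvexHull(obs)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate hull: {exc}") from exc
    # hull.equations rows are [a, b, c] with a·x + b·y + c <= 0 inside
    scale = max(1.0, float(np.abs(obs).max()))
    aug = np.c_[qry, np.ones(len(qry))]
    return (aug @ hull.equations.T).max(axis=1) <= tol * scale
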
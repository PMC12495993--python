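"""Spatial-information metrics: k-NN graphs, Moran's I, neighbor correlation.

Spatially informative genes show locally coherent expression. Two summaries
are computed per gene over a k-nearest-neighbor graph of the cell
coordinates: global Moran's I (positive = spatially clustered, ~0 = random,
negative = dispersed) and the Pearson correlation between each cell's
expression and the mean expression of its spatial neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .core_data import DataValidationError, ExpressionDataset, GenePanel


@dataclass
class SpatialGraph:
    """k-NN adjacency with per-edge weights.

    ``neighbors[i]`` lists the ``k`` neighbor indices of unit ``i``;
    ``weights[i]`` the matching edge weights. With ``row_standardized`` each
    unit's outgoing weights sum to 1.
    """

    neighbors: np.ndarray  # (n, k) int
    weights: np.ndarray  # (n, k) float
    k: int
    row_standardized: bool

    @property
    def n_units(self) -> int:
        return self.neighbors.shape[0]

    def to_sparse(self) -> sparse.csr_matrix:
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        return sparse.csr_matrix(
            (self.weights.ravel(), (rows, self.neighbors.ravel())), shape=(n, n)
        )


@dataclass
class SpatialResult:
    """Per-gene spatial summaries; degenerate genes carry no scores."""

    morans_i: dict[str, float]
    nn_correlation: dict[str, float]
    degenerate_genes: list[str] = field(default_factory=list)


def build_knn_graph(
    coords: np.ndarray, k: int = 6, row_standardize: bool = True
) -> SpatialGraph:
    """Exact k nearest neighbors under Euclidean distance.

    Ties are broken toward the lower cell index, making the graph
    deterministic even with duplicate coordinates. Weights are binary, then
    optionally row-standardized (the convention used for Moran's I here).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise DataValidationError("coordinates must be finite")
    if k < 1 or k >= n:
        raise DataValidationError(f"k must satisfy 1 <= k < n_cells ({n})")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)  # no self-edges
    # stable sort on distance keeps lower indices first among ties
    order = np.argsort(d, axis=1, kind="stable")
    neighbors = order[:, :k]
    weights = np.full((n, k), 1.0 / k if row_standardize else 1.0)
    return SpatialGraph(neighbors, weights, k, row_standardize)


def _moran_from_sparse(values: np.ndarray, w: sparse.spmatrix) -> tuple[float, bool]:
    """Moran's I for an arbitrary sparse weight matrix.

    Returns ``(I, degenerate)``; zero-variance input is degenerate with
    I defined as 0.
    """
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return 0.0, True
    w = w.tocoo()
    num = float(np.sum(w.data * z[w.row] * z[w.col]))
    w_sum = float(w.data.sum())
    return len(x) / w_sum * num / denom, False


def morans_i(values: np.ndarray, graph: SpatialGraph) -> float:
    """Global Moran's I of ``values`` over the graph.

    I = (N / W) * sum_ij w_ij (x_i - mean)(x_j - mean) / sum_i (x_i - mean)^2.
    Zero-variance input returns 0 (degenerate).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != graph.n_units:
        raise DataValidationError("values length must match graph size")
    i, _ = _moran_from_sparse(values, graph.to_sparse())
    return i


def grid_rook_weights(n_rows: int, n_cols: int) -> sparse.csr_matrix:
    """Binary rook (4-neighbor) adjacency for an n_rows × n_cols grid."""
    rows, cols, data = [], [], []
    idx = lambda r, c: r * n_cols + c
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    rows.append(idx(r, c))
                    cols.append(idx(rr, cc))
                    data.append(1.0)
    n = n_rows * n_cols
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def grid_morans_i(matrix: np.ndarray) -> tuple[float, bool]:
    """Moran's I treating each matrix entry as a unit with rook adjacency.

    Used by the panel entropy score on the clustered specificity heatmap.
    Returns ``(I, degenerate)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    w = grid_rook_weights(*matrix.shape)
    return _moran_from_sparse(matrix.ravel(), w)


def nearest_neighbor_correlation(
    ds: ExpressionDataset, panel: GenePanel, graph: SpatialGraph
) -> SpatialResult:
    """Per-gene Pearson correlation with the k-neighbor mean expression.

    For gene g the statistic is corr(x_i, mean_{j in N(i)} x_j) over cells i,
    computed on the log-normalized layer. Genes with zero variance in either
    vector are reported as degenerate and carry no score.
    """
    lognorm = ds.require_lognorm()
    if graph.n_units != ds.n_cells:
        raise DataValidationError("graph size must match n_cells")
    panel, _ = panel.intersect(ds)
    gidx = ds.gene_indices(list(panel.genes))
    sub = lognorm[:, gidx]
    neigh_mean = sub[graph.neighbors].mean(axis=1)  # (n_cells, n_genes)
    res = SpatialResult(morans_i={}, nn_correlation={})
    for j, g in enumerate(panel.genes):
        x, m = sub[:, j], neigh_mean[:, j]
        if x.std() == 0 or m.std() == 0:
            res.degenerate_genes.append(g)
            continue
        res.nn_correlation[g] = float(np.corrcoef(x, m)[0, 1])
    return res


def spatial_panel_result(
    ds: ExpressionDataset, panel: GenePanel, graph: SpatialGraph
) -> SpatialResult:
    """Moran's I and NN correlation for every usable panel gene."""
    lognorm = ds.require_lognorm()
    if graph.n_units != ds.n_cells:
        raise DataValidationError("graph size must match n_cells")
    panel, _ = panel.intersect(ds)
    gidx = ds.gene_indices(list(panel.genes))
    sub = lognorm[:, gidx]
    w = graph.to_sparse()
    neigh_mean = sub[graph.neighbors].mean(axis=1)
    res = SpatialResult(morans_i={}, nn_correlation={})
    for j, g in enumerate(panel.genes):
        x = sub[:, j]
        i_val, degenerate = _moran_from_sparse(x, w)
        if degenerate:
            res.degenerate_genes.append(g)
            continue
        res.morans_i[g] = i_val
        m = neigh_mean[:, j]
        if m.std() > 0:
            res.nn_correlation[g] = float(np.corrcoef(x, m)[0, 1])
    return res


def panel_spatial_score(result: SpatialResult) -> float:
    """Panel-level spatial score: mean Moran's I mapped to [0, 1] via (I+1)/2."""
    if not result.morans_i:
        raise DataValidationError("no non-degenerate genes with Moran's I")
    vals = np.array(list(result.morans_i.values()))
    return float(np.mean((vals + 1.0) / 2.0))
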
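"""Feature-specificity metrics.

Four views on how well a panel separates the annotated cell types:

* **gene specificity score (gsc)** — per gene × type log2 ratio of detection
  rates (fraction of cells with a nonzero count) between the target type and
  all other types; positive values mean the gene is preferentially detected
  in that type.
* **panel entropy score** — a panel-level non-specificity summary in [0, 1].
  The gsc matrix is hierarchically clustered on both axes; a specific panel
  produces a blocky heatmap whose grid autocorrelation (Moran's I with rook
  adjacency over the reordered entries) is high. The score mixes the
  autocorrelation term with the fraction of low-specificity genes (those
  with no positive gsc in any type), equally weighted; lower is better.
* **variation recovery (NMI)** — normalized mutual information between the
  annotated labels and a k-means clustering of the panel-gene expression
  (top principal components), arithmetic-mean normalization.
* **classification performance** — stratified cross-validated random forest
  on the panel genes, summarized as balanced accuracy (unweighted mean of
  per-type recall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import normalized_mutual_info_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .core_data import DataValidationError, ExpressionDataset, GenePanel
from .spatial import grid_morans_i


@dataclass
class SpecificityMatrix:
    """Panel genes × cell types matrix of gsc values (log2 units)."""

    values: np.ndarray
    genes: list[str]
    cell_types: list[str]
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cell_types)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class EntropyResult:
    """Panel entropy score and its two components."""

    entropy: float
    grid_moran: float
    nonspecific_fraction: float
    row_order: np.ndarray
    col_order: np.ndarray
    degenerate: bool = False


@dataclass
class ClassificationResult:
    balanced_accuracy: float
    per_type_accuracy: dict[str, float]
    fold_scores: list[float]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "per_type_accuracy": self.per_type_accuracy,
            "fold_scores": self.fold_scores,
            "seed": self.seed,
        }


def gene_specificity_matrix(
    ds: ExpressionDataset, panel: GenePanel, epsilon: float = 0.01
) -> SpecificityMatrix:
    """gsc(g, t) = log2((p_in + eps) / (p_out + eps)).

    ``p_in`` is the detection rate of gene g among cells of type t (fraction
    with a nonzero raw count), ``p_out`` the detection rate among all other
    cells. The pseudocount keeps the ratio finite for all-zero groups.
    """
    if epsilon <= 0:
        raise DataValidationError("epsilon must be positive")
    types = ds.type_labels
    if len(types) < 2:
        raise DataValidationError("gsc requires at least 2 cell types")
    panel, _ = panel.intersect(ds)
    gidx = ds.gene_indices(list(panel.genes))
    detected = ds.counts[:, gidx] > 0  # cells × panel genes
    values = np.empty((len(panel.genes), len(types)))
    for t_i, t in enumerate(types):
        mask = ds.cell_types == t
        p_in = detected[mask].mean(axis=0)
        p_out = detected[~mask].mean(axis=0)
        values[:, t_i] = np.log2((p_in + epsilon) / (p_out + epsilon))
    return SpecificityMatrix(values, list(panel.genes), [str(t) for t in types], epsilon)


def _leaf_order(matrix: np.ndarray) -> np.ndarray:
    """Average-linkage / Euclidean leaf order; ties resolved by input index."""
    if matrix.shape[0] < 2:
        return np.arange(matrix.shape[0])
    return leaves_list(linkage(matrix, method="average", metric="euclidean"))


def panel_entropy_score(sm: SpecificityMatrix) -> EntropyResult:
    """Panel entropy in [0, 1]; lower means a more type-specific panel.

    Steps: cluster rows and columns of the gsc matrix (average linkage,
    Euclidean), reorder by leaf order, compute Moran's I over the reordered
    grid with binary rook adjacency, take p0 = fraction of low-specificity
    genes (no cell type with gsc > 0), and combine as
    ``0.5 * (1 - (I + 1) / 2) + 0.5 * p0``. A zero-variance gsc matrix is
    degenerate: its Moran term is defined as 0.

    The per-gene reading of p0 matters: a perfectly specific gene still has
    negative gsc in every *other* type, so counting non-positive entries
    would penalize specificity instead of rewarding it.
    """
    v = sm.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise DataValidationError("entropy requires >= 2 genes and >= 2 cell types")
    row_order = _leaf_order(v)
    col_order = _leaf_order(v.T)
    reordered = v[np.ix_(row_order, col_order)]
    moran, degenerate = grid_morans_i(reordered)
    p0 = float(np.mean(v.max(axis=1) <= 0))
    entropy = 0.5 * (1.0 - (moran + 1.0) / 2.0) + 0.5 * p0
    return EntropyResult(entropy, moran, p0, row_order, col_order, degenerate)


def variation_recovery_nmi(
    ds: ExpressionDataset,
    panel: GenePanel,
    k: int | None = None,
    seed: int = 0,
    reference: str = "labels",
) -> float:
    """NMI between annotated labels and a panel-based k-means partition.

    The panel-gene lognorm submatrix is reduced to its top
    ``min(20, n_panel_genes - 1)`` principal components and clustered with
    k-means (k = number of cell types unless overridden; 10 restarts,
    seeded). NMI uses arithmetic-mean normalization,
    ``2 I(U;V) / (H(U) + H(V))``. With ``reference="kmeans"`` the reference
    partition is a seeded k-means on all genes instead of the labels.
    """
    lognorm = ds.require_lognorm()
    panel, _ = panel.intersect(ds)
    if len(panel) < 2:
        raise DataValidationError("NMI requires >= 2 usable panel genes")
    labels = pd.factorize(ds.cell_types)[0]
    if k is None:
        k = len(ds.type_labels)
    if k < 2:
        raise DataValidationError("k must be >= 2")

    def _partition(matrix: np.ndarray, rs: int) -> np.ndarray:
        n_comp = min(20, matrix.shape[1] - 1, matrix.shape[0] - 1)
        if n_comp >= 1:
            matrix = PCA(n_components=n_comp, random_state=rs).fit_transform(matrix)
        return KMeans(n_clusters=k, n_init=10, random_state=rs).fit_predict(matrix)

    sub = lognorm[:, ds.gene_indices(list(panel.genes))]
    panel_part = _partition(sub, seed)
    if reference == "kmeans":
        ref_part = _partition(lognorm, seed + 1)
    else:
        ref_part = labels
    return float(
        normalized_mutual_info_score(ref_part, panel_part, average_method="arithmetic")
    )


def nmi_arithmetic(u, v) -> float:
    """Arithmetic-mean-normalized mutual information between two labelings."""
    return float(normalized_mutual_info_score(u, v, average_method="arithmetic"))


def classification_performance(
    ds: ExpressionDataset,
    panel: GenePanel,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    classifier=None,
) -> ClassificationResult:
    """Stratified cross-validated random forest on the panel genes.

    Balanced accuracy is the unweighted mean of per-type recall pooled over
    folds; per-fold balanced accuracies are also recorded. Any estimator
    with fit/predict may be substituted via ``classifier``.
    """
    lognorm = ds.require_lognorm()
    panel, _ = panel.intersect(ds)
    y = ds.cell_types.astype(str)
    types, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise DataValidationError(
            f"cell type {types[counts.argmin()]!r} has fewer than {n_folds} cells; "
            "lower n_folds or filter the dataset"
        )
    x = lognorm[:, ds.gene_indices(list(panel.genes))]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled_pred = np.empty(len(y), dtype=object)
    fold_scores = []
    for train, test in skf.split(x, y):
        clf = classifier or RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        )
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        pooled_pred[test] = pred
        recalls = recall_score(y[test], pred, labels=types, average=None, zero_division=0)
        fold_scores.append(float(np.mean(recalls)))
    per_type = recall_score(
        y, pooled_pred.astype(str), labels=types, average=None, zero_division=0
    )
    return ClassificationResult(
        balanced_accuracy=float(np.mean(per_type)),
        per_type_accuracy={t: float(r) for t, r in zip(types, per_type)},
        fold_scores=fold_scores,
        seed=seed,
    )
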
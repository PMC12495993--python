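"""Core data model: expression datasets, gene panels, filtering and normalization.

The central container is :class:`ExpressionDataset`, a cells × genes count
matrix with gene/cell identifiers, one cell-type label per cell, optional
planar spatial coordinates, and an optional log-normalized expression layer.
Every characterization metric in the package is computed against one of
these objects.

On disk, counts live either in MatrixMarket triplet form (stored genes ×
cells, the 10x convention, with sidecar gene/cell identifier lists) or in a
dense CSV whose header row names the genes and whose first column holds the
cell identifiers. Labels and coordinates are plain CSV tables keyed by
``cell_id``. Gene panels are one symbol per line, ``#`` comments allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class DataValidationError(ValueError):
    """Raised when an input violates the data-model invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Cells × genes counts with identifiers, labels and optional extras.

    Parameters
    ----------
    counts
        Dense ``(n_cells, n_genes)`` array of non-negative integers.
    gene_ids, cell_ids
        Unique identifier lists matching the matrix dimensions.
    cell_types
        One label per cell, aligned with ``cell_ids``.
    coords
        Optional ``(n_cells, 2)`` planar coordinates.
    lognorm
        Optional log-normalized layer with the same shape as ``counts``;
        populated by :func:`normalize`.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: np.ndarray
    coords: np.ndarray | None = None
    lognorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DataValidationError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise DataValidationError(
                f"cell_ids length {len(self.cell_ids)} != n_cells {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DataValidationError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise DataValidationError("duplicate cell identifiers")
        if self.cell_types.shape[0] != n_cells:
            raise DataValidationError("cell_types length must equal n_cells")
        if np.any(self.counts < 0):
            raise DataValidationError("negative counts")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n_cells, 2):
                raise DataValidationError("coords must be (n_cells, 2)")
        if self.lognorm is not None:
            self.lognorm = np.asarray(self.lognorm, dtype=float)
            if self.lognorm.shape != self.counts.shape:
                raise DataValidationError("lognorm shape must match counts")
            if np.any(self.lognorm < 0):
                raise DataValidationError("lognorm must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def type_labels(self) -> list[str]:
        """Distinct cell-type labels in order of first appearance."""
        return list(pd.unique(self.cell_types))

    def gene_indices(self, genes: list[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([idx[g] for g in genes], dtype=int)

    def require_lognorm(self) -> np.ndarray:
        if self.lognorm is None:
            raise DataValidationError(
                "lognorm layer required; call normalize() first"
            )
        return self.lognorm

    def subset(self, cell_mask=None, gene_mask=None) -> "ExpressionDataset":
        """Return a new dataset restricted to the masked cells/genes."""
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        return ExpressionDataset(
            counts=self.counts[np.ix_(cm, gm)],
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            cell_ids=[c for c, k in zip(self.cell_ids, cm) if k],
            cell_types=self.cell_types[cm],
            coords=None if self.coords is None else self.coords[cm],
            lognorm=None if self.lognorm is None else self.lognorm[np.ix_(cm, gm)],
        )


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered, duplicate-free list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if len(genes) == 0:
            raise DataValidationError(f"panel {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise DataValidationError(f"panel {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(
        self, ds: ExpressionDataset, case_insensitive: bool = False
    ) -> tuple["GenePanel", list[str]]:
        """Restrict the panel to genes present in the dataset.

        Returns the restricted panel and the list of dropped symbols.
        Characterization operations call this explicitly so that dropped
        genes are always reported.
        """
        if case_insensitive:
            lookup = {g.upper(): g for g in ds.gene_ids}
            kept, dropped = [], []
            for g in self.genes:
                hit = lookup.get(g.upper())
                (kept.append(hit) if hit is not None else dropped.append(g))
        else:
            present = set(ds.gene_ids)
            kept = [g for g in self.genes if g in present]
            dropped = [g for g in self.genes if g not in present]
        if not kept:
            raise DataValidationError(
                f"panel {self.name!r} shares no genes with the dataset"
            )
        return GenePanel(self.name, tuple(kept)), dropped


@dataclass(frozen=True)
class FilterThresholds:
    """Preprocessing thresholds; totals strictly below a threshold are removed."""

    min_gene_total: int = 10
    min_cell_total: int = 200
    min_cells_per_type: int = 10

    def __post_init__(self) -> None:
        for name in ("min_gene_total", "min_cell_total", "min_cells_per_type"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be >= 0")


@dataclass
class FilterLog:
    """Per-filter removal counts recorded by :func:`filter_dataset`."""

    genes_removed: int = 0
    cells_removed: int = 0
    type_cells_removed: int = 0
    types_removed: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def _read_id_list(path: Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            # features.tsv may carry extra columns (id, name, type); first wins
            out.append(line.split("\t")[0])
    return out


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    coords_path: str | Path | None = None,
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from disk.

    ``matrix_path`` is auto-detected by extension: ``.mtx`` expects a
    MatrixMarket triplet stored genes × cells plus ``genes_path`` and
    ``cells_path`` identifier lists; ``.csv`` expects a dense table with the
    gene symbols as header and the cell identifiers in the first column.
    ``labels_path`` is a required CSV with columns ``cell_id,label``; every
    cell in the matrix must be labeled.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise DataValidationError("MTX input requires genes_path and cells_path")
        mat = spio.mmread(matrix_path)
        counts = np.asarray(
            mat.todense() if sparse.issparse(mat) else mat
        ).T  # genes × cells on disk -> cells × genes in memory
        gene_ids = _read_id_list(Path(genes_path))
        cell_ids = _read_id_list(Path(cells_path))
    elif matrix_path.suffix == ".csv":
        df = pd.read_csv(matrix_path, index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.columns]
        cell_ids = [str(c) for c in df.index]
    else:
        raise DataValidationError(f"unsupported matrix format: {matrix_path.suffix}")

    if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
        raise DataValidationError("counts must be non-negative integers")
    counts = np.asarray(np.round(counts), dtype=np.int64)

    if labels_path is None:
        raise DataValidationError("labels_path is required")
    labels = pd.read_csv(labels_path)
    if not {"cell_id", "label"}.issubset(labels.columns):
        raise DataValidationError("labels CSV must have columns cell_id,label")
    labels = labels.astype({"cell_id": str}).set_index("cell_id")
    extra = set(labels.index) - set(cell_ids)
    if extra:
        raise DataValidationError(
            f"labels reference unknown cell_ids: {sorted(extra)[:5]}"
        )
    missing = [c for c in cell_ids if c not in labels.index]
    if missing:
        raise DataValidationError(f"unlabeled cell(s): {missing[:5]}")
    cell_types = labels.loc[cell_ids, "label"].to_numpy(dtype=object)

    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path).astype({"cell_id": str}).set_index("cell_id")
        missing = [c for c in cell_ids if c not in cdf.index]
        if missing:
            raise DataValidationError(f"cells missing coordinates: {missing[:5]}")
        coords = cdf.loc[cell_ids, ["x", "y"]].to_numpy(dtype=float)

    return ExpressionDataset(counts, gene_ids, cell_ids, cell_types, coords)


def save_expression(ds: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as MTX (genes × cells) + sidecar CSV/TSV files.

    Returns the mapping of file kinds to paths; the layout round-trips
    through :func:`load_expression`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "features.tsv",
        "cells": out / "barcodes.tsv",
        "labels": out / "labels.csv",
    }
    spio.mmwrite(paths["matrix"], sparse.coo_matrix(ds.counts.T))
    paths["genes"].write_text("\n".join(ds.gene_ids) + "\n")
    paths["cells"].write_text("\n".join(ds.cell_ids) + "\n")
    pd.DataFrame({"cell_id": ds.cell_ids, "label": ds.cell_types}).to_csv(
        paths["labels"], index=False
    )
    if ds.coords is not None:
        paths["coords"] = out / "coords.csv"
        pd.DataFrame(
            {"cell_id": ds.cell_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
        ).to_csv(paths["coords"], index=False)
    return paths


def load_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a panel from a text file: one symbol per line, ``#`` comments."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GenePanel(name or path.stem, tuple(genes))


def save_panel(panel: GenePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.genes) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_dataset(
    ds: ExpressionDataset, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[ExpressionDataset, FilterLog]:
    """Apply the three preprocessing filters, in order.

    Genes with total counts below ``min_gene_total`` are removed first, then
    cells with totals below ``min_cell_total``, then all cells of any type
    represented by fewer than ``min_cells_per_type`` cells. Totals are
    recomputed after each step. "Below" is strict: totals equal to a
    threshold are kept.
    """
    log = FilterLog()

    gene_mask = ds.counts.sum(axis=0) >= thresholds.min_gene_total
    log.genes_removed = int((~gene_mask).sum())
    ds = ds.subset(gene_mask=gene_mask)
    if ds.n_genes == 0:
        raise DataValidationError("empty dataset after filtering (no genes)")

    cell_mask = ds.counts.sum(axis=1) >= thresholds.min_cell_total
    log.cells_removed = int((~cell_mask).sum())
    ds = ds.subset(cell_mask=cell_mask)
    if ds.n_cells == 0:
        raise DataValidationError("empty dataset after filtering (no cells)")

    types, counts = np.unique(ds.cell_types.astype(str), return_counts=True)
    small = set(types[counts < thresholds.min_cells_per_type])
    type_mask = np.array([t not in small for t in ds.cell_types])
    log.type_cells_removed = int((~type_mask).sum())
    log.types_removed = sorted(small)
    ds = ds.subset(cell_mask=type_mask)
    if ds.n_cells == 0:
        raise DataValidationError("empty dataset after filtering (no cell types)")

    return ds, log


def normalize(ds: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Counts-per-``scale`` log-normalization.

    ``lognorm[i, g] = ln(1 + scale * counts[i, g] / total_i)`` with
    ``total_i`` the cell's total count. Cells with zero total are an error
    (remove them with :func:`filter_dataset` first). Counts are unchanged.
    """
    if scale <= 0:
        raise DataValidationError("scale must be positive")
    totals = ds.counts.sum(axis=1, dtype=float)
    if np.any(totals == 0):
        raise DataValidationError(
            "cell(s) with zero total counts; filter before normalizing"
        )
    lognorm = np.log1p(scale * ds.counts / totals[:, None])
    return replace(ds, lognorm=lognorm)
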
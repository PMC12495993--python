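"""Synthetic single-cell / spatial fixtures with known ground truth.

The generator produces the statistical structure every metric in the
package assumes, so the full pipeline can be exercised without external
data:

* **cell-type markers** — negative-binomial counts whose mean is
  ``marker_fold`` times higher in the gene's own type, giving
  detection-rate differences for specificity metrics and signal for the
  classifier and NMI;
* **a housekeeping block** — genes sharing one positive per-cell latent
  factor, inducing the pairwise correlation that the diversity metric
  penalizes (a stably-expressed-gene-like redundant block);
* **independent noise genes** — no type, spatial, or correlation
  structure;
* **spatial blobs** — each cell type scattered around its own 2D center,
  so marker expression is spatially clustered and noise is not;
* per-cell log-normal library-size multipliers for depth variation.

Gene names encode the ground truth (``M{type}_{i}`` markers, ``HK_{i}``
housekeeping, ``NZ_{i}`` noise), so tests can build marker / housekeeping /
noise panels without bookkeeping tables. Matching pathway and
ligand/receptor annotations are generated alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biology import PathwayDatabase, write_gmt
from .core_data import DataValidationError, ExpressionDataset, GenePanel, save_expression


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give 3 types × 100 cells × 60 genes."""

    n_types: int = 3
    cells_per_type: int = 100
    markers_per_type: int = 5
    n_housekeeping: int = 10
    n_noise: int = 35
    marker_fold: float = 4.0  # marker mean multiplier in the home type
    base_mean: float = 1.0  # baseline NB mean per gene per cell
    dispersion: float = 0.5  # NB dispersion (var = mu + disp * mu^2)
    spatial_blob_sd: float = 1.0  # Gaussian scatter around type centers
    blob_spacing: float = 6.0  # distance scale between type centers
    library_size_cv: float = 0.3  # CV of per-cell depth multipliers
    hk_mean: float = 2.0  # housekeeping baseline mean (well-detected)
    hk_factor_sd: float = 1.2  # sd of the shared log-latent factor
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.cells_per_type, self.markers_per_type) < 1:
            raise DataValidationError("n_types, cells_per_type, markers_per_type >= 1")
        if self.n_housekeeping < 0 or self.n_noise < 0:
            raise DataValidationError("gene-block sizes must be >= 0")
        if self.marker_fold <= 1:
            raise DataValidationError("marker_fold must exceed 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise DataValidationError("base_mean and dispersion must be positive")
        if self.spatial_blob_sd <= 0 or self.library_size_cv < 0:
            raise DataValidationError("invalid spatial/library parameters")

    @property
    def n_genes(self) -> int:
        return self.n_types * self.markers_per_type + self.n_housekeeping + self.n_noise

    @property
    def n_cells(self) -> int:
        return self.n_types * self.cells_per_type

    def gene_names(self) -> list[str]:
        names = [
            f"M{t}_{i}"
            for t in range(self.n_types)
            for i in range(self.markers_per_type)
        ]
        names += [f"HK_{i}" for i in range(self.n_housekeeping)]
        names += [f"NZ_{i}" for i in range(self.n_noise)]
        return names

    def marker_panel(self, name: str = "markers") -> GenePanel:
        return GenePanel(
            name,
            tuple(
                f"M{t}_{i}"
                for t in range(self.n_types)
                for i in range(self.markers_per_type)
            ),
        )

    def housekeeping_panel(self, name: str = "housekeeping") -> GenePanel:
        return GenePanel(name, tuple(f"HK_{i}" for i in range(self.n_housekeeping)))

    def noise_panel(self, size: int | None = None, name: str = "noise") -> GenePanel:
        n = self.n_noise if size is None else size
        return GenePanel(name, tuple(f"NZ_{i}" for i in range(n)))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_dataset(cfg: SimConfig) -> ExpressionDataset:
    """Generate counts, labels and coordinates per the config; seeded."""
    rng = np.random.default_rng(cfg.seed)
    n_cells, n_genes = cfg.n_cells, cfg.n_genes
    genes = cfg.gene_names()
    type_of_cell = np.repeat(np.arange(cfg.n_types), cfg.cells_per_type)

    # per-gene, per-cell NB means
    mu = np.full((n_cells, n_genes), cfg.base_mean)
    for t in range(cfg.n_types):
        cells_t = type_of_cell == t
        for i in range(cfg.markers_per_type):
            mu[cells_t, t * cfg.markers_per_type + i] = cfg.base_mean * cfg.marker_fold

    hk_start = cfg.n_types * cfg.markers_per_type
    if cfg.n_housekeeping:
        factor = np.exp(rng.normal(0.0, cfg.hk_factor_sd, size=n_cells))
        mu[:, hk_start : hk_start + cfg.n_housekeeping] = (
            cfg.hk_mean * factor[:, None]
        )

    if cfg.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.library_size_cv**2))
        lib = np.exp(rng.normal(-(sigma**2) / 2, sigma, size=n_cells))
        mu *= lib[:, None]

    counts = _nb_sample(rng, mu, cfg.dispersion).astype(np.int64)

    # spatial blobs: type centers on a circle, Gaussian scatter
    angles = 2 * np.pi * np.arange(cfg.n_types) / cfg.n_types
    centers = cfg.blob_spacing * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = centers[type_of_cell] + rng.normal(
        0.0, cfg.spatial_blob_sd, size=(n_cells, 2)
    )

    return ExpressionDataset(
        counts=counts,
        gene_ids=genes,
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        cell_types=np.array([f"type{t}" for t in type_of_cell], dtype=object),
        coords=coords,
    )


def simulate_pathway_db(
    cfg: SimConfig, n_extra: int = 5, seed: int | None = None, fillers_per_pathway: int = 2
) -> PathwayDatabase:
    """Gene sets aligned to the simulated ground truth.

    One pathway per cell type holding its markers plus a few sampled noise
    fillers, one housekeeping pathway, and ``n_extra`` random pathways.
    Marker panels are then enriched in their type pathways by construction,
    while noise-only panels have no coherent set to hit.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = np.array(cfg.gene_names())
    pathways: dict[str, set[str]] = {}
    for t in range(cfg.n_types):
        members = {f"M{t}_{i}" for i in range(cfg.markers_per_type)}
        if cfg.n_noise and fillers_per_pathway:
            fill = rng.choice(cfg.n_noise, size=min(fillers_per_pathway, cfg.n_noise),
                              replace=False)
            members |= {f"NZ_{i}" for i in fill}
        pathways[f"type{t}_program"] = members
    if cfg.n_housekeeping:
        pathways["housekeeping"] = {f"HK_{i}" for i in range(cfg.n_housekeeping)}
    for j in range(n_extra):
        size = int(rng.integers(5, max(6, cfg.n_genes // 4)))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        pathways[f"random_set_{j}"] = set(genes[members])
    return PathwayDatabase(pathways, source="synthetic")


def simulate_lr_table(
    cfg: SimConfig, lr_fraction: float = 0.3, seed: int | None = None
) -> pd.DataFrame:
    """Annotate a random ``lr_fraction`` of genes, split evenly ligand/receptor."""
    if not 0 <= lr_fraction <= 1:
        raise DataValidationError("lr_fraction must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = cfg.gene_names()
    n_lr = int(round(lr_fraction * len(genes)))
    chosen = rng.choice(len(genes), size=n_lr, replace=False)
    rows = [
        (genes[g], "ligand" if i < n_lr // 2 else "receptor")
        for i, g in enumerate(chosen)
    ]
    return pd.DataFrame(rows, columns=["gene", "category"])


def write_fixture(
    cfg: SimConfig,
    out_dir: str | Path,
    n_extra_pathways: int = 5,
    lr_fraction: float = 0.3,
) -> dict[str, Path]:
    """Write a complete on-disk fixture readable by the loaders.

    Produces the MTX matrix with identifier sidecars, labels and
    coordinates CSVs, a GMT pathway file, a ligand/receptor CSV, and
    marker/housekeeping/noise panel TXT files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    paths = save_expression(ds, out)
    db = simulate_pathway_db(cfg, n_extra=n_extra_pathways)
    paths["gmt"] = out / "pathways.gmt"
    write_gmt(db, paths["gmt"])
    lr = simulate_lr_table(cfg, lr_fraction=lr_fraction)
    paths["lr"] = out / "lr_table.csv"
    lr.to_csv(paths["lr"], index=False)
    for panel in (cfg.marker_panel(), cfg.housekeeping_panel(), cfg.noise_panel()):
        p = out / f"panel_{panel.name}.txt"
        p.write_text("\n".join(panel.genes) + "\n")
        paths[f"panel_{panel.name}"] = p
    return paths
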
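"""Forward-compatibility scoring behind a pluggable perturbation model.

A perturbation model answers one question: if gene g were perturbed, which
genes respond and how strongly (log-fold-change-like magnitudes)? Any
object with a ``covered_genes`` set and a ``respond(gene)`` method
satisfies the contract — a precomputed response matrix exported from a
trained simulator plugs in unchanged via :class:`MatrixResponseModel`.

A gene's perturbation score combines the number and magnitude of influenced
genes as a thresholded L1 mass: the sum of |effect| over responding genes
whose |effect| clears the threshold delta. Panel scores rank-normalize the
per-gene scores against all covered genes so that panels are comparable
across models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataValidationError, GenePanel


class PerturbationModel(Protocol):
    """Contract: a response source over a fixed set of covered genes."""

    covered_genes: frozenset[str]

    def respond(self, gene: str) -> pd.Series:
        """Per-gene effect magnitudes (indexed by gene symbol) for perturbing ``gene``."""
        ...


class MatrixResponseModel:
    """Perturbation model backed by a dense effect matrix.

    Rows are perturbed genes, columns responding genes. Loadable from CSV
    via :meth:`from_csv`, so externally simulated responses can be scored
    without code changes.
    """

    def __init__(self, effects: pd.DataFrame):
        if not effects.index.equals(effects.columns):
            # allow differing orders but require the same gene set
            if set(effects.index) != set(effects.columns):
                raise DataValidationError(
                    "effect matrix rows and columns must cover the same genes"
                )
            effects = effects.loc[:, effects.index]
        if not np.all(np.isfinite(effects.to_numpy())):
            raise DataValidationError("effect matrix must be finite")
        self.effects = effects
        self.covered_genes = frozenset(effects.index)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MatrixResponseModel":
        return cls(pd.read_csv(path, index_col=0))

    def respond(self, gene: str) -> pd.Series:
        if gene not in self.covered_genes:
            raise DataValidationError(f"gene {gene!r} not covered by the model")
        return self.effects.loc[gene]


def linear_response_model(
    n_genes: int,
    density: float,
    seed: int,
    gene_ids: list[str] | None = None,
    hub_genes: list[str] | None = None,
    hub_factor: float = 10.0,
) -> MatrixResponseModel:
    """Seeded sparse random linear-response model for testing and demos.

    Each covered gene affects a random ``density`` fraction of genes with
    standard-normal magnitudes. Optional ``hub_genes`` affect
    ``hub_factor``-times more targets, emulating broadly connected
    regulators.
    """
    if not 0 < density <= 1:
        raise DataValidationError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else [f"G{i}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise DataValidationError("gene_ids length must equal n_genes")
    hubs = set(hub_genes or [])
    effects = np.zeros((n_genes, n_genes))
    for i, g in enumerate(genes):
        d = min(1.0, density * (hub_factor if g in hubs else 1.0))
        mask = rng.random(n_genes) < d
        mask[i] = False
        effects[i, mask] = rng.standard_normal(int(mask.sum()))
    return MatrixResponseModel(pd.DataFrame(effects, index=genes, columns=genes))


@dataclass
class PerturbationSummary:
    per_gene_score: dict[str, float]  # raw thresholded-L1 scores, panel genes
    per_gene_normalized: dict[str, float]  # rank-normalized to [0, 1]
    panel_score: float
    coverage: float
    delta: float

    def to_json_dict(self) -> dict:
        return {
            "per_gene_score": self.per_gene_score,
            "per_gene_normalized": self.per_gene_normalized,
            "panel_score": self.panel_score,
            "coverage": self.coverage,
            "delta": self.delta,
        }


def perturbation_gene_score(
    model: PerturbationModel, gene: str, delta: float = 0.1
) -> float:
    """Thresholded L1 impact: sum of |effect| >= delta over other genes."""
    if gene not in model.covered_genes:
        raise DataValidationError(f"gene {gene!r} not covered by the model")
    resp = model.respond(gene).drop(labels=[gene], errors="ignore")
    mag = resp.abs().to_numpy(dtype=float)
    return float(mag[mag >= delta].sum())


def panel_perturbation_score(
    model: PerturbationModel, panel: GenePanel, delta: float = 0.1
) -> PerturbationSummary:
    """Mean rank-normalized perturbation score over covered panel genes.

    Scores for *all* covered genes are ranked (average ranks for ties) and
    mapped to [0, 1] via (rank - 1) / (n - 1), so the single highest-impact
    gene scores 1 and fully tied models score 0.5 everywhere. Panel genes
    outside the model's coverage are excluded and reported via ``coverage``.
    """
    covered_panel = [g for g in panel.genes if g in model.covered_genes]
    if not covered_panel:
        raise DataValidationError(
            f"no panel gene covered by the model (coverage 0/{len(panel)})"
        )
    all_genes = sorted(model.covered_genes)
    scores = np.array([perturbation_gene_score(model, g, delta) for g in all_genes])
    if len(all_genes) == 1:
        normalized = np.array([1.0])
    else:
        ranks = stats.rankdata(scores, method="average")
        normalized = (ranks - 1.0) / (len(all_genes) - 1.0)
    norm_map = dict(zip(all_genes, normalized))
    raw_map = dict(zip(all_genes, scores))
    per_norm = {g: float(norm_map[g]) for g in covered_panel}
    return PerturbationSummary(
        per_gene_score={g: float(raw_map[g]) for g in covered_panel},
        per_gene_normalized=per_norm,
        panel_score=float(np.mean(list(per_norm.values()))),
        coverage=len(covered_panel) / len(panel),
        delta=delta,
    )
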
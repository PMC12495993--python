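"""Aggregation of the metric categories into panel and gene-level scores.

Five categories are summarized on a common [0, 1] scale:

* specificity — mean of balanced accuracy, 1 - panel entropy, and NMI;
* diversity — the signed pair score D mapped via (D + 1) / 2;
* biology — mean of the enriched-gene fraction, pathway diversity, and the
  ligand/receptor proportion;
* spatial — mean over panel genes of (Moran's I + 1) / 2 (needs coords);
* forward — the rank-normalized panel perturbation score (needs a model).

The overall panel score is a weighted mean over the categories that could
be computed (weights renormalized over that subset; equal by default).
Per-gene importance scores rate each gene's contribution *within* its
panel: category sub-scores are min-max normalized across the panel genes
and averaged with the same weights.

The genetic-algorithm objective is a cheaper, classifier-free variant:
the equally weighted mean of feature diversity, pathway diversity,
1 - entropy, the spatial term (omitted without coordinates), and NMI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biology, diversity, perturbation, specificity, spatial
from .core_data import DataValidationError, ExpressionDataset, GenePanel

CATEGORIES = ("specificity", "diversity", "biology", "spatial", "forward")


@dataclass
class MetricConfig:
    """Tunable metric parameters with their package-wide defaults."""

    epsilon: float = 0.01  # gsc pseudocount
    tau: float = 0.3  # |Spearman rho| redundancy threshold
    alpha: float = 0.05  # enrichment significance level on q-values
    jaccard_cut: float = 0.7  # pathway-pruning similarity cutoff
    k_neighbors: int = 6  # spatial k-NN graph degree
    delta: float = 0.1  # perturbation effect threshold
    n_folds: int = 5
    n_estimators: int = 500
    seed: int = 0
    weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CATEGORIES}
    )

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "tau": self.tau,
            "alpha": self.alpha,
            "jaccard_cut": self.jaccard_cut,
            "k_neighbors": self.k_neighbors,
            "delta": self.delta,
            "n_folds": self.n_folds,
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "weights": dict(self.weights),
        }


@dataclass
class CategoryScores:
    values: dict[str, float]  # category -> score in [0, 1]
    available: set[str]
    weights: dict[str, float]


@dataclass
class PanelReport:
    panel_name: str
    per_gene_importance: dict[str, float]
    category_scores: CategoryScores
    overall: float
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "panel": self.panel_name,
            "category_scores": self.category_scores.values,
            "available_categories": sorted(self.category_scores.available),
            "weights": self.category_scores.weights,
            "overall": self.overall,
            "per_gene_importance": self.per_gene_importance,
            "provenance": self.provenance,
        }


def category_scores(
    ds: ExpressionDataset,
    panel: GenePanel,
    db: biology.PathwayDatabase | None = None,
    lr_table: pd.DataFrame | None = None,
    graph: spatial.SpatialGraph | None = None,
    pmodel: perturbation.PerturbationModel | None = None,
    config: MetricConfig | None = None,
    categories: set[str] | None = None,
) -> CategoryScores:
    """Compute every category whose inputs are present.

    ``db`` gates the biology category, ``graph`` the spatial category and
    ``pmodel`` the forward category; ``categories`` restricts the set
    further. At least one category must be computable.
    """
    cfg = config or MetricConfig()
    wanted = set(categories) if categories is not None else set(CATEGORIES)
    values: dict[str, float] = {}

    if "specificity" in wanted:
        clf = specificity.classification_performance(
            ds, panel, n_folds=cfg.n_folds, seed=cfg.seed,
            n_estimators=cfg.n_estimators,
        )
        sm = specificity.gene_specificity_matrix(ds, panel, epsilon=cfg.epsilon)
        ent = specificity.panel_entropy_score(sm)
        nmi = specificity.variation_recovery_nmi(ds, panel, seed=cfg.seed)
        values["specificity"] = float(
            np.mean([clf.balanced_accuracy, 1.0 - ent.entropy, nmi])
        )
    if "diversity" in wanted:
        d = diversity.feature_diversity_score(ds, panel, tau=cfg.tau)
        values["diversity"] = (d.score + 1.0) / 2.0
    if "biology" in wanted and db is not None:
        universe = set(ds.gene_ids)
        summary = biology.enrich_pathways(panel, db, universe, alpha=cfg.alpha)
        pdiv = biology.pathway_diversity_score(
            summary, db, universe, jaccard_cut=cfg.jaccard_cut
        )
        lr = biology.ligand_receptor_summary(panel, lr_table)
        values["biology"] = float(
            np.mean([summary.pct_genes_enriched, pdiv, lr.lr_proportion])
        )
    if "spatial" in wanted and graph is not None:
        sres = spatial.spatial_panel_result(ds, panel, graph)
        values["spatial"] = spatial.panel_spatial_score(sres)
    if "forward" in wanted and pmodel is not None:
        values["forward"] = perturbation.panel_perturbation_score(
            pmodel, panel, delta=cfg.delta
        ).panel_score

    if not values:
        raise DataValidationError("no category computable with the given inputs")
    return CategoryScores(values=values, available=set(values), weights=dict(cfg.weights))


def overall_score(cs: CategoryScores) -> float:
    """Weighted mean over available categories, weights renormalized."""
    w = np.array([cs.weights.get(c, 0.0) for c in sorted(cs.available)])
    if np.any(w < 0):
        raise DataValidationError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise DataValidationError("all category weights are zero")
    s = np.array([cs.values[c] for c in sorted(cs.available)])
    return float(np.dot(w / total, s))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def gene_importance_scores(
    ds: ExpressionDataset,
    panel: GenePanel,
    db: biology.PathwayDatabase | None = None,
    lr_table: pd.DataFrame | None = None,
    graph: spatial.SpatialGraph | None = None,
    pmodel: perturbation.PerturbationModel | None = None,
    config: MetricConfig | None = None,
) -> dict[str, float]:
    """Per-gene contribution to the panel, in [0, 1].

    Raw sub-scores per gene: specificity = max over types of gsc;
    diversity = 1 - mean |rho| against the other panel genes; biology =
    0.5 * [in a significant pathway] + 0.5 * [annotated ligand/receptor];
    spatial = Moran's I; forward = rank-normalized perturbation score.
    Each available category's sub-scores are min-max normalized across the
    panel genes, then averaged with the configured category weights. A
    single-gene panel is degenerate: all sub-scores become 0.5.
    """
    cfg = config or MetricConfig()
    panel, _ = panel.intersect(ds)
    genes = list(panel.genes)
    sub: dict[str, np.ndarray] = {}

    sm = specificity.gene_specificity_matrix(ds, panel, epsilon=cfg.epsilon)
    sub["specificity"] = sm.values.max(axis=1)

    if len(genes) >= 2:
        d = diversity.feature_diversity_score(ds, panel, tau=cfg.tau)
        mean_abs = np.zeros(len(genes))
        gpos = {g: i for i, g in enumerate(genes)}
        acc = np.zeros(len(genes))
        for _, row in d.correlations.iterrows():
            a, b, r = gpos[row["gene_a"]], gpos[row["gene_b"]], abs(row["rho"])
            acc[a] += r
            acc[b] += r
        mean_abs = acc / (len(genes) - 1)
        sub["diversity"] = 1.0 - mean_abs

    if db is not None:
        universe = set(ds.gene_ids)
        summary = biology.enrich_pathways(panel, db, universe, alpha=cfg.alpha)
        lig: set[str] = set()
        rec: set[str] = set()
        if lr_table is not None and len(lr_table):
            lig = set(lr_table.loc[lr_table["category"] == "ligand", "gene"])
            rec = set(lr_table.loc[lr_table["category"] == "receptor", "gene"])
        sub["biology"] = np.array(
            [
                0.5 * (g in summary.enriched_genes) + 0.5 * (g in lig or g in rec)
                for g in genes
            ],
            dtype=float,
        )

    if graph is not None:
        sres = spatial.spatial_panel_result(ds, panel, graph)
        sub["spatial"] = np.array([sres.morans_i.get(g, 0.0) for g in genes])

    if pmodel is not None and any(g in pmodel.covered_genes for g in genes):
        psum = perturbation.panel_perturbation_score(pmodel, panel, delta=cfg.delta)
        sub["forward"] = np.array(
            [psum.per_gene_normalized.get(g, 0.0) for g in genes]
        )

    if len(genes) == 1:
        warnings.warn("single-gene panel: importance degenerates to 0.5", stacklevel=2)
        return {genes[0]: 0.5}

    w = np.array([cfg.weights.get(c, 0.0) for c in sub])
    if w.sum() == 0:
        raise DataValidationError("all weights zero for available categories")
    w = w / w.sum()
    normed = np.stack([_minmax(v) for v in sub.values()], axis=1)
    importance = normed @ w
    return {g: float(s) for g, s in zip(genes, importance)}


def characterize_panel(
    ds: ExpressionDataset,
    panel: GenePanel,
    db: biology.PathwayDatabase | None = None,
    lr_table: pd.DataFrame | None = None,
    graph: spatial.SpatialGraph | None = None,
    pmodel: perturbation.PerturbationModel | None = None,
    config: MetricConfig | None = None,
    categories: set[str] | None = None,
) -> PanelReport:
    """Full characterization: category scores, overall score, importances."""
    cfg = config or MetricConfig()
    cs = category_scores(ds, panel, db, lr_table, graph, pmodel, cfg, categories)
    overall = overall_score(cs)
    importance = gene_importance_scores(ds, panel, db, lr_table, graph, pmodel, cfg)
    used, dropped = panel.intersect(ds)
    return PanelReport(
        panel_name=panel.name,
        per_gene_importance=importance,
        category_scores=cs,
        overall=overall,
        provenance={
            "config": cfg.to_dict(),
            "n_cells": ds.n_cells,
            "n_genes": ds.n_genes,
            "panel_size": len(panel),
            "panel_genes_used": len(used),
            "panel_genes_dropped": dropped,
        },
    )


def ga_objective(
    ds: ExpressionDataset,
    panel: GenePanel,
    db: biology.PathwayDatabase | None = None,
    graph: spatial.SpatialGraph | None = None,
    config: MetricConfig | None = None,
    metric_weights: dict[str, float] | None = None,
) -> float:
    """Cheap multi-metric objective for the panel optimizer, in [0, 1].

    Equally weighted mean of feature diversity (D + 1) / 2, pathway
    diversity, 1 - panel entropy, the mean spatial term (Moran's I + 1) / 2
    (omitted when no graph is given), and variation-recovery NMI. The
    classifier and perturbation model are deliberately excluded to keep a
    single evaluation fast; per-metric weights are overridable.
    """
    cfg = config or MetricConfig()
    terms: dict[str, float] = {}

    d = diversity.feature_diversity_score(ds, panel, tau=cfg.tau)
    terms["diversity"] = (d.score + 1.0) / 2.0

    if db is not None:
        universe = set(ds.gene_ids)
        summary = biology.enrich_pathways(panel, db, universe, alpha=cfg.alpha)
        terms["pathway_diversity"] = biology.pathway_diversity_score(
            summary, db, universe, jaccard_cut=cfg.jaccard_cut
        )

    sm = specificity.gene_specificity_matrix(ds, panel, epsilon=cfg.epsilon)
    ent = specificity.panel_entropy_score(sm)
    terms["entropy"] = 1.0 - ent.entropy

    if graph is not None:
        sres = spatial.spatial_panel_result(ds, panel, graph)
        terms["spatial"] = spatial.panel_spatial_score(sres)

    terms["nmi"] = specificity.variation_recovery_nmi(ds, panel, seed=cfg.seed)

    if metric_weights:
        w = np.array([metric_weights.get(t, 0.0) for t in terms])
        if w.sum() == 0:
            raise DataValidationError("all objective weights are zero")
        return float(np.dot(w / w.sum(), np.array(list(terms.values()))))
    return float(np.mean(list(terms.values())))


def multi_panel_score_table(reports: list[PanelReport]) -> pd.DataFrame:
    """Panels × metrics table of standardized (z-scored) category scores.

    Columns with zero variance across panels are left at 0.
    """
    rows = {
        r.panel_name: {**r.category_scores.values, "overall": r.overall}
        for r in reports
    }
    df = pd.DataFrame(rows).T
    std = df.std(axis=0, ddof=0)
    z = (df - df.mean(axis=0)) / std.replace(0.0, np.nan)
    return z.fillna(0.0)
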
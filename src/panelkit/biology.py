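"""Biological-inference metrics: pathway over-representation and LR content.

Over-representation of panel genes in curated gene sets is tested with the
one-sided hypergeometric model (equivalent to one-sided Fisher's exact
test) against a stated gene universe, with Benjamini-Hochberg correction
across pathways. Three panel-level summaries follow:

* counts/fractions of panel genes belonging to at least one significant
  pathway, plus the maximum q-value among significant pathways;
* a *pathway diversity* score in (0, 1]: the fraction of significant
  pathways surviving a greedy pruning of pathways whose member-set Jaccard
  similarity with an already-kept pathway exceeds a cutoff — broad,
  non-overlapping coverage scores 1;
* ligand/receptor composition from a flat gene -> category annotation
  table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import DataValidationError, GenePanel


@dataclass
class PathwayDatabase:
    """Named gene sets, e.g. parsed from a GMT file."""

    pathways: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise DataValidationError(f"pathway {name!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path) -> PathwayDatabase:
    """Parse GMT: tab-separated name, description, then member genes."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataValidationError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = parts
        if name in pathways:
            raise DataValidationError(f"duplicate pathway name {name!r}")
        pathways[name] = {g for g in genes if g}
    return PathwayDatabase(pathways, source=str(path))


def write_gmt(db: PathwayDatabase, path: str | Path) -> None:
    lines = [
        "\t".join([name, db.source or "na", *sorted(genes)])
        for name, genes in db.pathways.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentSummary:
    """Per-pathway hypergeometric results plus panel-level counts."""

    per_pathway: pd.DataFrame  # index: pathway; columns: overlap, p, q, significant
    n_sig_pathways: int
    n_genes_enriched: int
    pct_genes_enriched: float
    max_q: float | None
    alpha: float
    n_panel_in_universe: int
    enriched_genes: set[str] = field(default_factory=set)
    diversity: float | None = None

    def to_tsv(self, path) -> None:
        self.per_pathway.to_csv(path, sep="\t")


@dataclass
class LigandReceptorSummary:
    n_ligand: int
    n_receptor: int
    n_both: int
    n_other: int
    lr_proportion: float


def hypergeom_pvalue(overlap: int, universe: int, pathway: int, panel: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, pathway, panel draws)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, pathway, panel))


def enrich_pathways(
    panel: GenePanel,
    db: PathwayDatabase,
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentSummary:
    """One-sided hypergeometric over-representation with BH correction.

    Pathways are intersected with the universe first; pathways with no
    universe member are skipped with a warning. A pathway is significant
    when its BH q-value is below ``alpha``. ``pct_genes_enriched`` uses the
    panel-in-universe size as denominator.
    """
    if not universe:
        raise DataValidationError("empty universe")
    if not db.pathways:
        raise DataValidationError("empty pathway database")
    panel_genes = [g for g in panel.genes if g in universe]
    skipped = len(panel) - len(panel_genes)
    if skipped:
        warnings.warn(
            f"{skipped} panel gene(s) outside the universe excluded from enrichment",
            stacklevel=2,
        )
    panel_set = set(panel_genes)
    n_univ, n_panel = len(universe), len(panel_set)

    names, overlaps, pvals, members = [], [], [], []
    for name, genes in db.pathways.items():
        in_univ = genes & universe
        if not in_univ:
            warnings.warn(f"pathway {name!r} has no universe genes; skipped",
                          stacklevel=2)
            continue
        ov = panel_set & in_univ
        names.append(name)
        overlaps.append(len(ov))
        members.append(ov)
        pvals.append(hypergeom_pvalue(len(ov), n_univ, len(in_univ), n_panel))

    if not names:
        raise DataValidationError("no pathway overlaps the universe")
    qvals = multipletests(pvals, method="fdr_bh")[1]
    sig = qvals < alpha
    table = pd.DataFrame(
        {"overlap": overlaps, "p": pvals, "q": qvals, "significant": sig},
        index=pd.Index(names, name="pathway"),
    )
    enriched: set[str] = set()
    for ov, is_sig in zip(members, sig):
        if is_sig:
            enriched |= ov
    n_sig = int(sig.sum())
    return EnrichmentSummary(
        per_pathway=table,
        n_sig_pathways=n_sig,
        n_genes_enriched=len(enriched),
        pct_genes_enriched=len(enriched) / n_panel if n_panel else 0.0,
        max_q=float(qvals[sig].max()) if n_sig else None,
        alpha=alpha,
        n_panel_in_universe=n_panel,
        enriched_genes=enriched,
    )


def _jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def pathway_diversity_score(
    summary: EnrichmentSummary,
    db: PathwayDatabase,
    universe: set[str] | None = None,
    jaccard_cut: float = 0.7,
) -> float:
    """Fraction of significant pathways surviving greedy Jaccard pruning.

    Significant pathways are visited by ascending q (ties: descending
    overlap, then name); a pathway is kept iff its Jaccard similarity on
    full member sets (intersected with the universe when given) with every
    kept pathway is <= ``jaccard_cut``. With n significant and n' kept the
    score is n'/n; defined as 1 when n <= 1.
    """
    sig = summary.per_pathway[summary.per_pathway["significant"]]
    n = len(sig)
    if n <= 1:
        return 1.0
    order = sig.assign(_name=sig.index).sort_values(
        ["q", "overlap", "_name"], ascending=[True, False, True]
    ).index
    kept_sets: list[set[str]] = []
    for name in order:
        members = db.pathways[name]
        if universe is not None:
            members = members & universe
        if all(_jaccard(members, ks) <= jaccard_cut for ks in kept_sets):
            kept_sets.append(members)
    return len(kept_sets) / n


def read_lr_table(path: str | Path) -> pd.DataFrame:
    """Read a gene -> category CSV with columns ``gene,category``."""
    df = pd.read_csv(path)
    if not {"gene", "category"}.issubset(df.columns):
        raise DataValidationError("LR table must have columns gene,category")
    bad = set(df["category"].unique()) - {"ligand", "receptor"}
    if bad:
        raise DataValidationError(f"unknown LR categories: {sorted(bad)}")
    return df


def ligand_receptor_summary(
    panel: GenePanel, lr_table: pd.DataFrame | None
) -> LigandReceptorSummary:
    """Classify panel genes as ligand / receptor / both / other.

    A gene annotated as both ligand and receptor counts once, in the
    ``both`` bucket. ``lr_proportion`` is the fraction of panel genes with
    any LR annotation.
    """
    if lr_table is None or len(lr_table) == 0:
        ligands: set[str] = set()
        receptors: set[str] = set()
    else:
        ligands = set(lr_table.loc[lr_table["category"] == "ligand", "gene"])
        receptors = set(lr_table.loc[lr_table["category"] == "receptor", "gene"])
    n_both = sum(1 for g in panel.genes if g in ligands and g in receptors)
    n_lig = sum(1 for g in panel.genes if g in ligands and g not in receptors)
    n_rec = sum(1 for g in panel.genes if g in receptors and g not in ligands)
    n_other = len(panel) - n_both - n_lig - n_rec
    return LigandReceptorSummary(
        n_ligand=n_lig,
        n_receptor=n_rec,
        n_both=n_both,
        n_other=n_other,
        lr_proportion=(n_lig + n_rec + n_both) / len(panel),
    )
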
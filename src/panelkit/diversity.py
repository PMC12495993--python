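"""Feature-diversity metric: signed proportion of orthogonal gene pairs.

A panel wastes probes when its genes co-vary. For every unordered pair of
panel genes the Spearman rank correlation over cells (log-normalized layer)
is computed; a pair is *redundant* when |rho| >= tau and *orthogonal*
otherwise. The score

    D = (n_orthogonal - n_redundant) / n_pairs

lies in [-1, 1]: +1 for a fully decorrelated panel, -1 for a fully
redundant one. Being rank-based, D is invariant to strictly monotone
per-gene transforms of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataValidationError, ExpressionDataset, GenePanel


@dataclass
class DiversityResult:
    score: float
    tau: float
    n_pairs: int
    n_redundant: int
    n_orthogonal: int
    correlations: pd.DataFrame  # columns: gene_a, gene_b, rho, redundant

    def to_tsv(self, path) -> None:
        self.correlations.to_csv(path, sep="\t", index=False)


def feature_diversity_score(
    ds: ExpressionDataset, panel: GenePanel, tau: float = 0.3
) -> DiversityResult:
    """Signed orthogonal-minus-redundant pair proportion under |rho| >= tau.

    Zero-variance genes cannot be ranked; their pairs are assigned rho = 0
    (orthogonal) with a warning.
    """
    if not 0 < tau < 1:
        raise DataValidationError("tau must be in (0, 1)")
    lognorm = ds.require_lognorm()
    panel, _ = panel.intersect(ds)
    if len(panel) < 2:
        raise DataValidationError("diversity requires >= 2 usable panel genes")
    sub = lognorm[:, ds.gene_indices(list(panel.genes))]
    variances = sub.var(axis=0)
    flat = np.flatnonzero(variances == 0)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance gene(s) assigned rho = 0 for all pairs",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(sub).statistic
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for exactly 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    rho[np.isnan(rho)] = 0.0
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0

    genes = list(panel.genes)
    rows = []
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            r = float(rho[a, b])
            rows.append((genes[a], genes[b], r, abs(r) >= tau))
    corr = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "redundant"])
    n_pairs = len(corr)
    n_red = int(corr["redundant"].sum())
    n_orth = n_pairs - n_red
    return DiversityResult(
        score=(n_orth - n_red) / n_pairs,
        tau=tau,
        n_pairs=n_pairs,
        n_redundant=n_red,
        n_orthogonal=n_orth,
        correlations=corr,
    )
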
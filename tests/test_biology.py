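import math

import numpy as np
import pandas as pd
import pytest

import panelkit as pk
from panelkit.biology import (
    EnrichmentSummary,
    PathwayDatabase,
    hypergeom_pvalue,
    read_gmt,
    write_gmt,
)
from panelkit.core_data import DataValidationError, GenePanel

from conftest import make_panel


def tail_sum_pvalue(overlap, universe, pathway, panel):
    """Direct combinatorial hypergeometric tail: P(X >= overlap)."""
    total = 0.0
    for k in range(overlap, min(pathway, panel) + 1):
        total += (
            math.comb(pathway, k)
            * math.comb(universe - pathway, panel - k)
            / math.comb(universe, panel)
        )
    return total


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up q-values, by definition."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return q


class TestHypergeometric:
    def test_panel_equals_pathway_closed_form(self):
        # panel of 10 identical to a 10-gene pathway in a 100-gene universe
        assert hypergeom_pvalue(10, 100, 10, 10) == pytest.approx(
            1.0 / math.comb(100, 10), rel=1e-12
        )

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_pvalue(0, 50, 5, 10) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_tail_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = int(rng.integers(20, 200))
        pathway = int(rng.integers(1, universe // 2))
        panel = int(rng.integers(1, universe // 2))
        overlap = int(rng.integers(0, min(pathway, panel) + 1))
        assert hypergeom_pvalue(overlap, universe, pathway, panel) == pytest.approx(
            tail_sum_pvalue(overlap, universe, pathway, panel), abs=1e-12
        )


class TestEnrichment:
    def _db(self, mapping):
        return PathwayDatabase({k: set(v) for k, v in mapping.items()})

    def test_bh_worked_case_all_q_equal(self):
        """p-values 0.01/0.02/0.03 over 3 tests all step up to q = 0.03."""
        np.testing.assert_allclose(bh_stepup([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        universe = {f"u{i}" for i in range(100)}
        # three disjoint pathways with graded overlap against one panel
        db = self._db(
            {
                "a": {f"u{i}" for i in range(10)},
                "b": {f"u{i}" for i in range(10, 20)},
                "c": {f"u{i}" for i in range(20, 30)},
            }
        )
        panel = make_panel([f"u{i}" for i in range(9)] + ["u10", "u11"])
        res = pk.enrich_pathways(panel, db, universe)
        np.testing.assert_allclose(
            res.per_pathway["q"], bh_stepup(res.per_pathway["p"]), atol=1e-12
        )

    def test_summary_counts_on_known_truth(self, sim_cfg, fixture_ds, pathway_db,
                                           marker_panel):
        universe = set(fixture_ds.gene_ids)
        res = pk.enrich_pathways(marker_panel, pathway_db, universe)
        # every type program is hit by its own five markers
        assert res.n_sig_pathways >= sim_cfg.n_types
        assert res.n_genes_enriched == len(marker_panel)
        assert res.pct_genes_enriched == 1.0
        assert res.max_q is not None and res.max_q < 0.05

    def test_noise_panel_has_no_enrichment(self, sim_cfg, fixture_ds, pathway_db):
        noise = sim_cfg.noise_panel(size=15)
        res = pk.enrich_pathways(noise, pathway_db, set(fixture_ds.gene_ids))
        assert res.n_sig_pathways == 0
        assert res.max_q is None

    def test_dilution_with_pathway_free_genes(self, sim_cfg, fixture_ds, pathway_db,
                                              marker_panel):
        """Adding genes in no pathway never increases the significant count
        and only dilutes the enriched fraction."""
        universe = set(fixture_ds.gene_ids)
        covered = set().union(*pathway_db.pathways.values())
        free = sorted(universe - covered)
        assert len(free) >= 5
        prev_sig, prev_pct = np.inf, np.inf
        for k in range(len(free) + 1):
            panel = GenePanel(f"m+{k}", marker_panel.genes + tuple(free[:k]))
            res = pk.enrich_pathways(panel, pathway_db, universe)
            assert res.n_sig_pathways <= prev_sig
            assert res.pct_genes_enriched <= prev_pct
            prev_sig, prev_pct = res.n_sig_pathways, res.pct_genes_enriched

    def test_empty_universe_rejected(self, pathway_db, marker_panel):
        with pytest.raises(DataValidationError):
            pk.enrich_pathways(marker_panel, pathway_db, set())

    def test_gmt_round_trip(self, tmp_path, pathway_db):
        write_gmt(pathway_db, tmp_path / "db.gmt")
        again = read_gmt(tmp_path / "db.gmt")
        assert again.pathways == pathway_db.pathways


class TestPathwayDiversity:
    def _summary(self, names, qs, overlaps):
        table = pd.DataFrame(
            {
                "overlap": overlaps,
                "p": qs,
                "q": qs,
                "significant": [q < 0.05 for q in qs],
            },
            index=pd.Index(names, name="pathway"),
        )
        return EnrichmentSummary(
            per_pathway=table,
            n_sig_pathways=int(table["significant"].sum()),
            n_genes_enriched=0,
            pct_genes_enriched=0.0,
            max_q=None,
            alpha=0.05,
            n_panel_in_universe=0,
        )

    def test_identical_sets_keep_one_third(self):
        genes = {"a", "b", "c"}
        db = PathwayDatabase({"p1": set(genes), "p2": set(genes), "p3": set(genes)})
        summary = self._summary(["p1", "p2", "p3"], [0.01, 0.02, 0.03], [3, 3, 3])
        assert pk.pathway_diversity_score(summary, db) == pytest.approx(1 / 3)

    def test_disjoint_sets_keep_all(self):
        db = PathwayDatabase({"p1": {"a"}, "p2": {"b"}, "p3": {"c"}})
        summary = self._summary(["p1", "p2", "p3"], [0.01, 0.02, 0.03], [1, 1, 1])
        assert pk.pathway_diversity_score(summary, db) == 1.0

    def test_at_most_one_significant_is_defined_as_one(self):
        db = PathwayDatabase({"p1": {"a"}, "p2": {"b"}})
        summary = self._summary(["p1", "p2"], [0.01, 0.9], [1, 0])
        assert pk.pathway_diversity_score(summary, db) == 1.0
        summary0 = self._summary(["p1", "p2"], [0.9, 0.9], [0, 0])
        assert pk.pathway_diversity_score(summary0, db) == 1.0

    def test_mixed_overlaps_match_greedy_replay(self):
        """Four significant pathways with partial overlaps reproduce an
        explicit greedy trace (visit by q, keep iff Jaccard <= cut with all
        kept so far)."""
        db = PathwayDatabase(
            {
                "w": {"a", "b", "c", "d"},
                "x": {"a", "b", "c", "e"},  # J(w, x) = 3/5 <= 0.7 -> kept
                "y": {"a", "b", "c", "d", "e"},  # J(w, y) = 4/5 > 0.7 -> pruned
                "z": {"f", "g"},  # disjoint -> kept
            }
        )
        qs = [0.01, 0.02, 0.03, 0.04]
        summary = self._summary(["w", "x", "y", "z"], qs, [4, 4, 5, 2])
        # greedy replay by hand
        order = ["w", "x", "y", "z"]
        kept = []
        for name in order:
            s = db.pathways[name]
            if all(
                len(s & k) / len(s | k) <= 0.7 for k in kept
            ):
                kept.append(s)
        assert pk.pathway_diversity_score(summary, db) == pytest.approx(
            len(kept) / 4
        )
        assert len(kept) == 3


class TestLigandReceptor:
    def test_counts_and_proportion(self):
        lr = pd.DataFrame(
            {
                "gene": ["g0", "g1", "g2"],
                "category": ["ligand", "ligand", "receptor"],
            }
        )
        panel = make_panel([f"g{i}" for i in range(10)])
        res = pk.ligand_receptor_summary(panel, lr)
        assert (res.n_ligand, res.n_receptor, res.n_both, res.n_other) == (2, 1, 0, 7)
        assert res.lr_proportion == pytest.approx(0.3)

    def test_empty_table_gives_zero(self):
        panel = make_panel(["a", "b"])
        res = pk.ligand_receptor_summary(panel, None)
        assert res.lr_proportion == 0.0 and res.n_other == 2

    def test_dual_annotation_counts_once(self):
        lr = pd.DataFrame(
            {"gene": ["a", "a"], "category": ["ligand", "receptor"]}
        )
        res = pk.ligand_receptor_summary(make_panel(["a", "b"]), lr)
        assert res.n_both == 1 and res.n_ligand == 0 and res.n_receptor == 0
        assert res.lr_proportion == pytest.approx(0.5)

    def test_fixture_counts_sum_to_panel_size(self, lr_table, marker_panel):
        res = pk.ligand_receptor_summary(marker_panel, lr_table)
        total = res.n_ligand + res.n_receptor + res.n_both + res.n_other
        assert total == len(marker_panel)
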
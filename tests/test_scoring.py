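import numpy as np
import pytest

import panelkit as pk
from panelkit.core_data import DataValidationError
from panelkit.scoring import CategoryScores, MetricConfig, overall_score

from conftest import make_panel


@pytest.fixture(scope="module")
def full_inputs(fixture_ds, pathway_db, lr_table, knn_graph):
    pmodel = pk.linear_response_model(
        60, density=0.2, seed=5, gene_ids=fixture_ds.gene_ids
    )
    return dict(db=pathway_db, lr_table=lr_table, graph=knn_graph, pmodel=pmodel)


def make_cs(values, weights=None):
    return CategoryScores(
        values=values,
        available=set(values),
        weights=weights or {c: 1.0 for c in values},
    )


class TestOverallScore:
    def test_all_ones_equal_weights(self):
        cs = make_cs({c: 1.0 for c in pk.scoring.CATEGORIES})
        assert overall_score(cs) == 1.0

    def test_single_nonzero_weight_selects_category(self):
        cs = make_cs(
            {"specificity": 0.7, "diversity": 0.2},
            weights={"specificity": 1.0, "diversity": 0.0},
        )
        assert overall_score(cs) == pytest.approx(0.7)

    def test_matches_scalar_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cats = list(pk.scoring.CATEGORIES)
            vals = {c: float(rng.random()) for c in cats}
            w = {c: float(rng.random()) for c in cats}
            cs = make_cs(vals, weights=w)
            expected = sum(w[c] * vals[c] for c in cats) / sum(w.values())
            assert overall_score(cs) == pytest.approx(expected, abs=1e-12)

    def test_weight_scaling_invariance(self):
        """Scaling all weights by a positive constant leaves the overall
        score unchanged (100 random weight vectors)."""
        rng = np.random.default_rng(1)
        vals = {c: float(rng.random()) for c in pk.scoring.CATEGORIES}
        for _ in range(100):
            w = {c: float(rng.random() + 1e-6) for c in pk.scoring.CATEGORIES}
            scale = float(rng.random() * 10 + 0.1)
            a = overall_score(make_cs(vals, weights=w))
            b = overall_score(
                make_cs(vals, weights={c: scale * x for c, x in w.items()})
            )
            assert b == pytest.approx(a, abs=1e-12)

    def test_monotone_in_each_category(self):
        vals = {c: 0.5 for c in pk.scoring.CATEGORIES}
        base = overall_score(make_cs(dict(vals)))
        for c in pk.scoring.CATEGORIES:
            bumped = dict(vals)
            bumped[c] = 0.6
            assert overall_score(make_cs(bumped)) > base

    def test_all_zero_weights_rejected(self):
        cs = make_cs({"diversity": 0.5}, weights={"diversity": 0.0})
        with pytest.raises(DataValidationError):
            overall_score(cs)


class TestCategoryScores:
    def test_compositional_oracle(self, fixture_ds, marker_panel, full_inputs):
        """Each category equals its definition recomputed from the
        individual metric operations."""
        cfg = MetricConfig(seed=0, n_estimators=100)
        cs = pk.category_scores(fixture_ds, marker_panel, config=cfg, **full_inputs)
        assert cs.available == set(pk.scoring.CATEGORIES)
        assert all(0.0 <= v <= 1.0 for v in cs.values.values())

        clf = pk.classification_performance(
            fixture_ds, marker_panel, seed=0, n_estimators=100
        )
        sm = pk.gene_specificity_matrix(fixture_ds, marker_panel)
        ent = pk.panel_entropy_score(sm)
        nmi = pk.variation_recovery_nmi(fixture_ds, marker_panel, seed=0)
        assert cs.values["specificity"] == pytest.approx(
            np.mean([clf.balanced_accuracy, 1 - ent.entropy, nmi]), abs=1e-12
        )

        d = pk.feature_diversity_score(fixture_ds, marker_panel)
        assert cs.values["diversity"] == pytest.approx((d.score + 1) / 2, abs=1e-12)

        universe = set(fixture_ds.gene_ids)
        summary = pk.enrich_pathways(marker_panel, full_inputs["db"], universe)
        pdiv = pk.pathway_diversity_score(summary, full_inputs["db"], universe)
        lr = pk.ligand_receptor_summary(marker_panel, full_inputs["lr_table"])
        assert cs.values["biology"] == pytest.approx(
            np.mean([summary.pct_genes_enriched, pdiv, lr.lr_proportion]), abs=1e-12
        )

        sres = pk.spatial_panel_result(fixture_ds, marker_panel, full_inputs["graph"])
        assert cs.values["spatial"] == pytest.approx(
            np.mean([(v + 1) / 2 for v in sres.morans_i.values()]), abs=1e-12
        )

        psum = pk.panel_perturbation_score(full_inputs["pmodel"], marker_panel)
        assert cs.values["forward"] == pytest.approx(psum.panel_score, abs=1e-12)

    def test_missing_inputs_drop_categories(self, fixture_ds, marker_panel):
        cfg = MetricConfig(seed=0, n_estimators=50)
        cs = pk.category_scores(fixture_ds, marker_panel, config=cfg)
        assert cs.available == {"specificity", "diversity"}


class TestGeneImportance:
    def test_scores_in_unit_interval_and_cover_panel(
        self, fixture_ds, marker_panel, full_inputs
    ):
        imp = pk.gene_importance_scores(
            fixture_ds, marker_panel, config=MetricConfig(seed=0), **full_inputs
        )
        assert set(imp) == set(marker_panel.genes)
        assert all(0.0 <= v <= 1.0 for v in imp.values())

    def test_best_in_every_category_scores_one(self, fixture_ds, pathway_db, lr_table):
        """Min-max endpoints: the gene maximal in all sub-scores gets 1."""
        # two-gene panel: one strong marker in a significant pathway +
        # ligand annotation, one noise gene; the marker wins each category
        import pandas as pd

        panel = make_panel(["M0_0", "NZ_1"])
        lr = pd.DataFrame({"gene": ["M0_0"], "category": ["ligand"]})
        imp = pk.gene_importance_scores(
            fixture_ds, panel, db=pathway_db, lr_table=lr,
            config=MetricConfig(seed=0),
        )
        top = max(imp, key=imp.get)
        assert top == "M0_0"
        # specificity and biology endpoints are exact 1/0 after min-max
        assert imp["M0_0"] > imp["NZ_1"]

    def test_single_gene_panel_degenerates_to_half(self, fixture_ds):
        with pytest.warns(UserWarning, match="single-gene"):
            imp = pk.gene_importance_scores(fixture_ds, make_panel(["M0_0"]))
        assert imp == {"M0_0": 0.5}


class TestGaObjective:
    def test_compositional_oracle(self, fixture_ds, marker_panel, pathway_db, knn_graph):
        cfg = MetricConfig(seed=0)
        obj = pk.ga_objective(
            fixture_ds, marker_panel, db=pathway_db, graph=knn_graph, config=cfg
        )
        universe = set(fixture_ds.gene_ids)
        d = pk.feature_diversity_score(fixture_ds, marker_panel)
        summary = pk.enrich_pathways(marker_panel, pathway_db, universe)
        pdiv = pk.pathway_diversity_score(summary, pathway_db, universe)
        ent = pk.panel_entropy_score(
            pk.gene_specificity_matrix(fixture_ds, marker_panel)
        )
        sres = pk.spatial_panel_result(fixture_ds, marker_panel, knn_graph)
        spat = np.mean([(v + 1) / 2 for v in sres.morans_i.values()])
        nmi = pk.variation_recovery_nmi(fixture_ds, marker_panel, seed=0)
        expected = np.mean(
            [(d.score + 1) / 2, pdiv, 1 - ent.entropy, spat, nmi]
        )
        assert obj == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= obj <= 1.0

    def test_no_coords_renormalizes_over_four_terms(
        self, fixture_ds, marker_panel, pathway_db
    ):
        cfg = MetricConfig(seed=0)
        obj = pk.ga_objective(fixture_ds, marker_panel, db=pathway_db, config=cfg)
        universe = set(fixture_ds.gene_ids)
        d = pk.feature_diversity_score(fixture_ds, marker_panel)
        summary = pk.enrich_pathways(marker_panel, pathway_db, universe)
        pdiv = pk.pathway_diversity_score(summary, pathway_db, universe)
        ent = pk.panel_entropy_score(
            pk.gene_specificity_matrix(fixture_ds, marker_panel)
        )
        nmi = pk.variation_recovery_nmi(fixture_ds, marker_panel, seed=0)
        expected = np.mean([(d.score + 1) / 2, pdiv, 1 - ent.entropy, nmi])
        assert obj == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seeds(self, fixture_ds, marker_panel, pathway_db,
                                       knn_graph):
        cfg = MetricConfig(seed=3)
        a = pk.ga_objective(fixture_ds, marker_panel, db=pathway_db,
                            graph=knn_graph, config=cfg)
        b = pk.ga_objective(fixture_ds, marker_panel, db=pathway_db,
                            graph=knn_graph, config=cfg)
        assert a == b


class TestReports:
    def test_characterize_report_consistent(self, fixture_ds, marker_panel,
                                            full_inputs):
        cfg = MetricConfig(seed=0, n_estimators=100)
        report = pk.characterize_panel(
            fixture_ds, marker_panel, config=cfg, **full_inputs
        )
        assert report.overall == pytest.approx(
            overall_score(report.category_scores), abs=1e-12
        )
        payload = report.to_json_dict()
        assert payload["schema_version"] == 1
        assert payload["provenance"]["config"]["seed"] == 0

    def test_multi_panel_table_standardized(self, fixture_ds, marker_panel,
                                            noise_panel_eq, full_inputs):
        cfg = MetricConfig(seed=0, n_estimators=50)
        reports = [
            pk.characterize_panel(fixture_ds, p, config=cfg, **full_inputs)
            for p in (marker_panel, noise_panel_eq)
        ]
        table = pk.multi_panel_score_table(reports)
        assert set(table.index) == {"markers", "noise"}
        # z-scores over two panels are +/- the same magnitude per column
        np.testing.assert_allclose(table.sum(axis=0), 0.0, atol=1e-12)
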
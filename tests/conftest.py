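import numpy as np
import pytest

import panelkit as pk
from panelkit.core_data import ExpressionDataset, GenePanel


@pytest.fixture(scope="session")
def sim_cfg():
    return pk.SimConfig(seed=0)


@pytest.fixture(scope="session")
def fixture_ds(sim_cfg):
    """Default synthetic dataset (3 types x 100 cells x 60 genes), normalized."""
    return pk.normalize(pk.simulate_dataset(sim_cfg))


@pytest.fixture(scope="session")
def marker_panel(sim_cfg):
    return sim_cfg.marker_panel()


@pytest.fixture(scope="session")
def noise_panel_eq(sim_cfg, marker_panel):
    """Noise panel matched in size to the marker panel."""
    return sim_cfg.noise_panel(size=len(marker_panel))


@pytest.fixture(scope="session")
def hk_panel(sim_cfg):
    return sim_cfg.housekeeping_panel()


@pytest.fixture(scope="session")
def pathway_db(sim_cfg):
    return pk.simulate_pathway_db(sim_cfg)


@pytest.fixture(scope="session")
def lr_table(sim_cfg):
    return pk.simulate_lr_table(sim_cfg, lr_fraction=0.3)


@pytest.fixture(scope="session")
def knn_graph(fixture_ds):
    return pk.build_knn_graph(fixture_ds.coords, k=6)


def make_dataset(
    counts, gene_ids=None, cell_types=None, coords=None, lognorm=None
) -> ExpressionDataset:
    """Small-dataset helper for hand-built examples."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return ExpressionDataset(
        counts=counts,
        gene_ids=gene_ids or [f"g{j}" for j in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        cell_types=np.asarray(
            cell_types if cell_types is not None else ["t0"] * n_cells, dtype=object
        ),
        coords=coords,
        lognorm=lognorm,
    )


def make_panel(genes, name="p") -> GenePanel:
    return GenePanel(name, tuple(genes))
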
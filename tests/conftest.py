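import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scolitis import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation: 2 patients/cohort, 300 cells, 200 genes."""
    return syn.SimConfig(
        n_patients_per_cohort={"MC": 2, "chronic_diarrhea": 2, "unaffected": 2},
        n_cells_per_patient=300,
        n_genes=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syn.generate_cell_dataset(small_config)


@pytest.fixture(scope="session")
def small_repertoires(small_config):
    return syn.generate_repertoire(small_config)


def make_adata(counts, gene_names, barcodes=None, obs=None):
    """Build a small AnnData from a dense count array."""
    counts = np.asarray(counts)
    adata = ad.AnnData(X=sp.csr_matrix(counts))
    adata.var_names = list(gene_names)
    if barcodes is None:
        barcodes = [f"cell{i}" for i in range(counts.shape[0])]
    adata.obs_names = list(barcodes)
    if obs is not None:
        for k, v in obs.items():
            adata.obs[k] = pd.Series(v, index=adata.obs_names)
    return adata
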
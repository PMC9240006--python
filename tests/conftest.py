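import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from matfet.simulate import (
    simulate_cell_allele_counts,
    simulate_trio_genotypes,
)


@pytest.fixture(scope="session")
def trio():
    """Mid-size trio shared by feature/origin tests."""
    return simulate_trio_genotypes(2000, informative_fraction=0.3, seed=42)


@pytest.fixture(scope="session")
def balanced_obs(trio):
    """600 balanced cells at the default coverage/error conditions."""
    return simulate_cell_allele_counts(
        trio, 600, fetal_fraction=0.5, error_rate=0.01, seed=7
    )


def make_adata(counts, mito_flags=None, library_ids=None, cell_types=None):
    """Dense-counts helper: build an AnnData with the conventions qc expects."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    var = pd.DataFrame(
        {
            "mito": np.zeros(n_genes, bool) if mito_flags is None else np.asarray(mito_flags, bool)
        },
        index=pd.Index([f"G{j}" for j in range(n_genes)], name="gene"),
    )
    obs = pd.DataFrame(
        index=pd.Index([f"C{i}" for i in range(n_cells)], name="cell")
    )
    obs["library_id"] = "lib1" if library_ids is None else np.asarray(library_ids)
    if cell_types is not None:
        obs["cell_type"] = np.asarray(cell_types)
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
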
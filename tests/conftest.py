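import numpy as np
import pandas as pd
import anndata as ad
import pytest


def make_counts(X, cell_ids=None, gene_ids=None, biotype=None, labels=None):
    """Small helper assembling a count AnnData from raw pieces."""
    X = np.asarray(X, dtype=np.int64)
    n, g = X.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    var = pd.DataFrame(
        {"biotype": biotype if biotype is not None else ["protein_coding"] * g},
        index=gene_ids,
    )
    obs = pd.DataFrame(index=cell_ids)
    if labels is not None:
        obs["cell_label"] = labels
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_counts(rng):
    """200 cells x 50 genes of sparse-ish Poisson counts."""
    X = rng.poisson(rng.lognormal(0.0, 1.0, 50)[None, :] * 0.5, size=(200, 50))
    return make_counts(X)
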
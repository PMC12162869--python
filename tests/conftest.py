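import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from sctme import clustering as cl
from sctme import matrix as mx
from sctme import synthetic as syn


def make_adata(X, genes=None, cells=None, obs=None) -> AnnData:
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = genes or [f"g{j:04d}" for j in range(g)]
    cells = cells or [f"c{i:04d}" for i in range(n)]
    ad = AnnData(
        X=sp.csr_matrix(X),
        obs=obs if obs is not None else pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if obs is not None:
        ad.obs.index = pd.Index(cells, name="cell")
    return ad


@pytest.fixture(scope="session")
def planted():
    """Three well-separated planted types (>=200 cells each), 10% mis-sorting,
    a planted CAF age program, and two planted LR channels; full pipeline run
    through the silhouette sweep."""
    cfg = syn.SynthConfig(
        n_genes=800,
        n_cells_per_sample=200,
        n_samples_per_group=2,
        group_proportions={"young": [1 / 3, 1 / 3, 1 / 3], "adult": [1 / 3, 1 / 3, 1 / 3]},
        missort_fraction=0.1,
        de_spec=syn.DESpec(cell_type="caf", n_genes=40, log2fc=1.0),
        lr_spec=[syn.LRChannelSpec("tcell", "caf"), syn.LRChannelSpec("caf", "cancer")],
        seed=7,
    )
    adata, truth = syn.generate_tme_dataset(cfg)
    mx.normalize_log(adata)
    hvg = mx.select_hvg(adata, 300)
    mx.compute_pca(adata, hvg, n_components=60)
    graph = mx.build_snn_graph(adata)
    sweep = cl.silhouette_sweep(graph, adata.obsm["X_pca"], seed=1)
    best = cl.select_optimal_resolution(sweep)
    part = sweep.partitions[sweep.resolutions.index(best)]
    return {
        "config": cfg,
        "adata": adata,
        "truth": truth,
        "graph": graph,
        "sweep": sweep,
        "best_resolution": best,
        "partition": part,
    }
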
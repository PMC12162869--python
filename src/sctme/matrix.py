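"""Count-matrix IO, per-sample QC, log normalization, HVG, PCA, SNN graph.

The in-memory container throughout the package is :class:`anndata.AnnData`
with cells as rows.  Raw counts live in ``.X``; :func:`normalize_log` adds a
``"lognorm"`` layer; :func:`compute_pca` adds ``.obsm["X_pca"]``;
:func:`build_snn_graph` returns (and stores in ``.obsp["snn"]``) a symmetric
sparse matrix of Jaccard shared-nearest-neighbor weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


class FormatError(ValueError):
    pass


class EmptyAfterQCError(ValueError):
    pass


def read_10x_triplet(path: str | Path) -> AnnData:
    """Read a 10x triplet directory (matrix.mtx genes x cells, features.tsv,
    barcodes.tsv; optional metadata.tsv joined by barcode)."""
    from scipy.io import mmread

    path = Path(path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / fname).exists():
            raise FormatError(f"missing {fname} in {path}")
    mat = mmread(str(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(
        path / "barcodes.tsv", sep="\t", header=None, skip_blank_lines=False
    )[0].astype(str) if (path / "barcodes.tsv").stat().st_size else pd.Series([], dtype=str)
    if genes.duplicated().any():
        raise FormatError("duplicate gene identifiers in features.tsv")
    if barcodes.duplicated().any():
        raise FormatError("duplicate barcodes in barcodes.tsv")
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape}, expected ({len(genes)}, {len(barcodes)})"
        )
    data = np.asarray(sp.coo_matrix(mat).data)
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError("matrix.mtx contains non-integer entries")
    X = sp.csr_matrix(mat.T).astype(np.int64)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    meta_path = path / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs = obs.join(meta, how="left")
    return AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


@dataclass
class QCThresholds:
    """Cell-level QC gates; per-sample overrides win over the defaults."""

    min_genes_per_cell: int = 0
    max_counts_per_cell: float = np.inf
    max_mito_fraction: float = 1.0
    mito_prefix: str = "mt-"
    per_sample: dict[str, "QCThresholds"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")

    def resolve(self, sample: str) -> "QCThresholds":
        return self.per_sample.get(sample, self)


def qc_filter(
    adata: AnnData, thresholds: QCThresholds
) -> tuple[AnnData, pd.DataFrame]:
    """Keep cells passing min-genes, max-counts, and max-mito gates.

    Gates are resolved per sample (``.obs["sample"]`` if present).  Returns
    the filtered AnnData and a per-sample report of cells removed per
    criterion.  Mito fraction is 0 when no gene matches the mito prefix.
    """
    X = sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = adata.var_names.str.lower().str.startswith(
        thresholds.mito_prefix.lower()
    )
    if mito_mask.any():
        mito_counts = np.asarray(X[:, np.where(mito_mask)[0]].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    else:
        mito_frac = np.zeros(adata.n_obs)

    samples = (
        adata.obs["sample"].astype(str)
        if "sample" in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    keep = np.ones(adata.n_obs, dtype=bool)
    rows = []
    for sample in pd.unique(samples):
        thr = thresholds.resolve(sample)
        m = (samples == sample).to_numpy()
        fail_genes = m & (n_genes < thr.min_genes_per_cell)
        fail_counts = m & (totals > thr.max_counts_per_cell)
        fail_mito = m & (mito_frac > thr.max_mito_fraction)
        keep &= ~(fail_genes | fail_counts | fail_mito)
        rows.append(
            {
                "sample": sample,
                "n_cells": int(m.sum()),
                "removed_min_genes": int(fail_genes.sum()),
                "removed_max_counts": int(fail_counts.sum()),
                "removed_mito": int(fail_mito.sum()),
                "kept": int((m & keep).sum()),
            }
        )
    if not keep.any():
        raise EmptyAfterQCError("no cells pass QC: empty after QC")
    return adata[keep].copy(), pd.DataFrame(rows)


def normalize_log(
    adata: AnnData, scale_factor: float = 1e4, layer: str = "lognorm"
) -> AnnData:
    """Library-size log normalization: log1p(count / total * scale_factor).

    Stores the result as a sparse layer and records provenance in ``.uns``.
    Invariant to per-cell depth rescaling.  Raises when a cell has zero
    total count, naming the cell.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = adata.obs_names[np.where(totals <= 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total count; filter before normalizing")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers[layer] = norm
    adata.uns["normalization"] = {"scale_factor": scale_factor, "pseudo_count": 1.0}
    return adata


def select_hvg(
    adata: AnnData, n_top: int = 3000, layer: str = "lognorm", n_bins: int = 20
) -> list[str]:
    """Top genes by standardized dispersion (variance/mean of normalized
    values, z-scored within equal-frequency mean bins).

    Constant genes (zero variance) are never selected while any
    non-constant gene remains.  Order is deterministic: by decreasing
    standardized dispersion, ties broken by gene name.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > adata.n_vars:
        raise ValueError("n_top exceeds the number of genes")
    X = sp.csc_matrix(adata.layers[layer])
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    constant = var <= 1e-10 * np.maximum(sq, 1.0)  # zero up to rounding
    var[constant] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    df = pd.DataFrame(
        {"gene": adata.var_names, "mean": mean, "dispersion": dispersion}
    )
    nb = min(n_bins, max(1, df["mean"].nunique()))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), nb, labels=False)
    grp = df.groupby("bin")["dispersion"]
    mu = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    df["z"] = np.where(sd > 0, (df["dispersion"] - mu) / sd, 0.0)
    df.loc[constant, "z"] = -np.inf  # constant genes last
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n_top).tolist()


def compute_pca(
    adata: AnnData,
    genes: list[str] | None = None,
    n_components: int = 60,
    layer: str = "lognorm",
    scale: bool = True,
) -> AnnData:
    """Deterministic PCA on the (scaled) HVG submatrix.

    Genes are centered and, by default, unit-scaled.  Component signs follow
    a fixed convention: the largest-magnitude loading of each component is
    made positive.  Coordinates go to ``.obsm["X_pca"]``; explained-variance
    ratios to ``.uns["pca"]["variance_ratio"]``.
    """
    if genes is None:
        genes = list(adata.var_names)
    sub = adata[:, genes]
    X = np.asarray(sp.csr_matrix(sub.layers[layer]).todense(), dtype=float)
    n_components = min(n_components, len(genes))
    if adata.n_obs < n_components:
        raise ValueError("fewer cells than requested components")
    mu = X.mean(axis=0)
    X = X - mu
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    for j in range(n_components):
        load = pca.components_[j]
        k = np.argmax(np.abs(load))
        if load[k] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    adata.obsm["X_pca"] = coords
    adata.uns["pca"] = {
        "variance_ratio": pca.explained_variance_ratio_.tolist(),
        "n_components": n_components,
        "genes": list(genes),
    }
    return adata


def build_snn_graph(
    adata: AnnData,
    n_pcs: int = 50,
    k: int = 20,
    prune: float = 1.0 / 15.0,
    key: str = "snn",
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    kNN (Euclidean, first ``n_pcs`` PCs, neighbor sets include the cell
    itself as in the Seurat convention); edge weight between two cells is
    the Jaccard overlap of their neighbor sets; weights below ``prune`` are
    removed, as are self-loops.  Symmetric by construction.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    coords = adata.obsm["X_pca"][:, : min(n_pcs, adata.obsm["X_pca"].shape[1])]
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    # include self explicitly (sklearn returns self only when distance 0 ties allow)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n), dtype=float
    )
    adj[np.arange(n), np.arange(n)] = 1.0
    adj.data[:] = 1.0
    inter = adj @ adj.T
    inter = sp.csr_matrix(inter)
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    r, c = inter.nonzero()
    union = sizes[r] + sizes[c] - inter.data
    jac = inter.data / union
    snn = sp.csr_matrix((jac, (r, c)), shape=(n, n))
    snn.setdiag(0.0)
    snn.data[snn.data < prune] = 0.0
    snn.eliminate_zeros()
    adata.obsp[key] = snn
    return snn
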
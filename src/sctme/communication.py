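"""Ligand-receptor communication scoring and between-group similarity.

Per (sender cluster, receiver cluster, ligand, receptor): a specificity
channel (NATMI-style edge specificity — the product of the ligand's share
of sender-summed expression and the receptor's share of receiver-summed
expression, summing to 1 over the sender x receiver grid) and a magnitude
channel (SingleCellSignalR LRscore — sqrt(l*r)/(mu + sqrt(l*r)) with mu the
global mean of the normalized matrix, bounded in [0,1)).  The interaction
score is their product; a consensus aggregated rank in (0,1] combines the
two channels by the geometric mean of normalized ranks (lower = stronger).
Between-group similarity is the Jaccard index of interaction keys retained
at increasing aggregated-rank thresholds.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .clustering import ClusterPartition

logger = logging.getLogger(__name__)

KEY = ["sender", "receiver", "ligand", "receptor"]


def cluster_mean_expression(
    adata: AnnData,
    labels: np.ndarray | pd.Series,
    layer: str = "lognorm",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Arithmetic mean of normalized expression per cluster (clusters x
    genes); clusters with <= ``min_cells`` cells are excluded and logged."""
    labels = np.asarray(pd.Series(labels))
    X = sp.csr_matrix(adata.layers[layer])
    rows = []
    kept = []
    for cl in pd.unique(labels):
        mask = labels == cl
        if mask.sum() <= min_cells:
            logger.info("cluster %r excluded (%d cells <= %d)", cl, mask.sum(), min_cells)
            continue
        rows.append(np.asarray(X[mask].mean(axis=0)).ravel())
        kept.append(cl)
    if not rows:
        raise ValueError("all clusters excluded by the min-cells filter")
    return pd.DataFrame(rows, index=pd.Index(kept, name="cluster"), columns=adata.var_names)


def natmi_edge_specificity(means: pd.DataFrame, ligand: str, receptor: str) -> pd.DataFrame:
    """Edge specificity per (sender, receiver): ligand sender-share times
    receptor receiver-share; sums to 1 over the grid when both genes are
    expressed somewhere."""
    lig = means[ligand].to_numpy(float)
    rec = means[receptor].to_numpy(float)
    lsum, rsum = lig.sum(), rec.sum()
    if lsum == 0 or rsum == 0:
        warnings.warn(
            f"{ligand if lsum == 0 else receptor} has zero mean in every cluster",
            stacklevel=2,
        )
        grid = np.zeros((len(means), len(means)))
    else:
        grid = np.outer(lig / lsum, rec / rsum)
    return pd.DataFrame(grid, index=means.index.rename("sender"), columns=means.index.rename("receiver"))


def sca_lr_score(
    means: pd.DataFrame, ligand: str, receptor: str, mu: float
) -> pd.DataFrame:
    """SingleCellSignalR magnitude: sqrt(l*r)/(mu + sqrt(l*r)), in [0,1),
    monotone increasing in each cluster mean."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    root = np.sqrt(np.outer(means[ligand].to_numpy(float), means[receptor].to_numpy(float)))
    grid = root / (mu + root)
    return pd.DataFrame(grid, index=means.index.rename("sender"), columns=means.index.rename("receiver"))


def aggregate_ranks(scores: pd.DataFrame) -> pd.Series:
    """Consensus rank in (0,1] across score columns (higher score = better).

    Each column becomes ascending fractional ranks of (-score) normalized
    by the number of entries; the aggregate is their geometric mean.
    All-constant columns are dropped with a warning.
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one score column")
    cols = []
    for c in scores.columns:
        if scores[c].nunique() <= 1:
            warnings.warn(f"score column {c!r} is constant; dropped", stacklevel=2)
            continue
        cols.append((-scores[c]).rank(method="average") / len(scores))
    if not cols:
        raise ValueError("all score columns constant")
    ranks = pd.concat(cols, axis=1)
    return np.exp(np.log(ranks).mean(axis=1)).rename("aggregated_rank")


def score_interactions(
    adata: AnnData,
    partition: ClusterPartition | np.ndarray | pd.Series,
    lrdb: pd.DataFrame,
    layer: str = "lognorm",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Score every retained (sender, receiver) pair (autocrine included)
    for every LR pair present in the matrix.

    Columns: specificity, magnitude, interaction_score (their exact
    product), aggregated_rank (consensus over the two channels, computed
    across all rows of the table).
    """
    if lrdb.empty:
        raise ValueError("empty ligand-receptor database")
    labels = partition.labels if isinstance(partition, ClusterPartition) else partition
    means = cluster_mean_expression(adata, labels, layer=layer, min_cells=min_cells)
    if len(means) < 2:
        raise ValueError("need at least two retained clusters")
    X = adata.layers[layer]
    mu = float(X.mean()) if not sp.issparse(X) else float(X.sum() / np.prod(X.shape))
    present = set(adata.var_names)
    rows = []
    for _, pair in lrdb.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in present or rec not in present:
            continue
        lsum = means[lig].sum()
        rsum = means[rec].sum()
        if lsum == 0 or rsum == 0:
            continue
        spec = natmi_edge_specificity(means, lig, rec)
        mag = sca_lr_score(means, lig, rec, mu)
        for s in means.index:
            for r in means.index:
                rows.append(
                    {
                        "sender": s,
                        "receiver": r,
                        "ligand": lig,
                        "receptor": rec,
                        "specificity": spec.loc[s, r],
                        "magnitude": mag.loc[s, r],
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no LR pair from the database is expressed in the matrix")
    table["interaction_score"] = table["specificity"] * table["magnitude"]
    table["aggregated_rank"] = aggregate_ranks(table[["specificity", "magnitude"]]).to_numpy()
    return table


def jaccard_similarity_sweep(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    thresholds=None,
) -> pd.DataFrame:
    """Jaccard index of interaction keys retained at each aggregated-rank
    threshold (1 when both sets are empty)."""
    if thresholds is None:
        thresholds = [round(0.05 * i, 2) for i in range(1, 21)]  # 0.05..1.0
    keys_a = table_a.set_index(KEY)["aggregated_rank"]
    keys_b = table_b.set_index(KEY)["aggregated_rank"]
    rows = []
    for t in thresholds:
        sa = set(keys_a.index[keys_a <= t])
        sb = set(keys_b.index[keys_b <= t])
        union = sa | sb
        jac = 1.0 if not union else len(sa & sb) / len(union)
        rows.append({"threshold": t, "jaccard": jac, "n_A": len(sa), "n_B": len(sb)})
    return pd.DataFrame(rows)


def ortholog_map(lrdb: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Translate LR pairs through a one-to-at-most-one symbol mapping;
    pairs with an unmapped member are dropped (and counted in the log)."""
    counts = mapping.groupby("symbol")["ortholog"].nunique()
    used = set(lrdb["ligand"]) | set(lrdb["receptor"])
    offenders = sorted(set(counts.index[counts > 1]) & used)
    if offenders:
        raise ValueError(f"one-to-many ortholog mapping for: {offenders}")
    m = mapping.drop_duplicates("symbol").set_index("symbol")["ortholog"]
    lig = lrdb["ligand"].map(m)
    rec = lrdb["receptor"].map(m)
    ok = lig.notna() & rec.notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%d LR pairs dropped (unmapped symbols)", dropped)
    return pd.DataFrame({"ligand": lig[ok], "receptor": rec[ok]}).reset_index(drop=True)
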
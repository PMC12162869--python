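"""Leiden clustering, silhouette-based resolution selection, compartment
reassignment, and a membership-flow stability diagnostic."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

#: plurality tie-break priority for compartment reassignment
COMPARTMENT_PRIORITY = ("immune", "stromal", "cancer")


@dataclass
class ClusterPartition:
    """A cell -> cluster assignment at one resolution (ids contiguous from 0,
    relabeled by decreasing cluster size for determinism)."""

    resolution: float
    labels: np.ndarray
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class SweepResult:
    """Resolution sweep: one row per resolution with its partition and the
    mean silhouette width on the first 60 PCs (-1 when unscoreable)."""

    resolutions: list[float]
    partitions: list[ClusterPartition]
    silhouettes: list[float]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resolution": self.resolutions,
                "n_clusters": [p.n_clusters for p in self.partitions],
                "silhouette": self.silhouettes,
            }
        )


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous 0-based ids, ordered by decreasing cluster size (ties by
    first occurrence)."""
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == i) for i in ids])
    order = np.lexsort((first, -counts))
    mapping = {int(ids[o]): new for new, o in enumerate(order)}
    return np.array([mapping[int(x)] for x in labels], dtype=int)


def leiden_partition(
    graph: sp.spmatrix, resolution: float, seed: int = 0
) -> ClusterPartition:
    """Leiden with the resolution-parameterized (RB) modularity objective."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    adj = sp.csr_matrix(graph)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    upper = sp.triu(adj, k=1).tocoo()
    sources, targets, weights = upper.row, upper.col, upper.data
    g = ig.Graph(n=adj.shape[0], edges=list(zip(sources.tolist(), targets.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights.tolist() if len(weights) else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return ClusterPartition(resolution, _relabel(np.array(part.membership)), seed)


def silhouette_sweep(
    graph: sp.spmatrix,
    embedding: np.ndarray,
    resolutions: list[float] | None = None,
    n_pcs: int = 60,
    seed: int = 0,
) -> SweepResult:
    """Cluster at each resolution and score the partition by the mean
    silhouette width (Euclidean, first ``n_pcs`` embedding components, or
    all available if fewer).  Single-cluster partitions score -1."""
    if resolutions is None:
        resolutions = [round(0.2 + 0.1 * i, 1) for i in range(19)]  # 0.2..2.0
    if not resolutions:
        raise ValueError("empty resolution list")
    coords = embedding[:, : min(n_pcs, embedding.shape[1])]
    partitions, sils = [], []
    for res in resolutions:
        part = leiden_partition(graph, res, seed=seed)
        if part.n_clusters < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(coords, part.labels, metric="euclidean"))
            if np.isnan(sil):  # all points identical: (b-a)/max(a,b) -> 0/0
                sil = 0.0
        partitions.append(part)
        sils.append(sil)
    return SweepResult(list(resolutions), partitions, sils)


def select_optimal_resolution(sweep: SweepResult) -> float:
    """Resolution maximizing mean silhouette; ties go to the lower
    resolution (fewer clusters, parsimony)."""
    if not sweep.resolutions:
        raise ValueError("empty sweep")
    if all(s == -1.0 for s in sweep.silhouettes):
        raise ValueError("all partitions unscoreable (single cluster everywhere)")
    order = np.argsort(sweep.resolutions, kind="mergesort")
    best, best_sil = None, -np.inf
    for i in order:
        if sweep.silhouettes[i] > best_sil:
            best_sil = sweep.silhouettes[i]
            best = sweep.resolutions[i]
    return float(best)


def reassign_compartments(
    partition: ClusterPartition,
    sorted_compartment: pd.Series,
    priority: tuple[str, ...] = COMPARTMENT_PRIORITY,
) -> pd.Series:
    """Majority-vote compartment reassignment.

    Each cluster takes the plurality compartment of its member cells'
    sorted labels; every member is assigned that compartment.  Ties break
    by fixed priority (immune > stromal > cancer) and are logged.
    Idempotent: reapplying to its own output is a no-op.
    """
    labels = partition.labels
    out = sorted_compartment.copy()
    rank = {c: i for i, c in enumerate(priority)}
    for cl in range(labels.max() + 1):
        members = sorted_compartment.index[labels == cl]
        counts = sorted_compartment.loc[members].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            top.sort(key=lambda c: rank.get(c, len(priority)))
            logger.info(
                "cluster %d: compartment tie %s broken to %r", cl, top, top[0]
            )
        out.loc[members] = top[0]
    return out.rename("compartment")


def membership_flow_stability(partitions: list[ClusterPartition]) -> pd.DataFrame:
    """Per-resolution stability of the cluster structure across a sweep.

    For consecutive partitions, a cluster's stability is the largest
    fraction of its cells landing in a single cluster of the next
    partition; the per-resolution score is the cell-weighted mean over
    clusters.  1 means membership flows intact; fragmentation lowers it.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    n = len(partitions[0].labels)
    if any(len(p.labels) != n for p in partitions):
        raise ValueError("partitions cover different cell sets")
    rows = []
    for a, b in zip(partitions[:-1], partitions[1:]):
        ct = pd.crosstab(a.labels, b.labels)
        per_cluster = ct.max(axis=1) / ct.sum(axis=1)
        weights = ct.sum(axis=1) / n
        rows.append(
            {
                "resolution": a.resolution,
                "next_resolution": b.resolution,
                "stability": float((per_cluster * weights).sum()),
            }
        )
    return pd.DataFrame(rows)
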
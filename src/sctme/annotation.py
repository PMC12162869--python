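"""Marker-based cluster annotation with specificity-weighted scoring.

The scoring follows the scType scheme: genes are z-scored across cells,
weighted by how specific they are to a single cell type in the marker
database, summed per cell (positive markers add, negative subtract, each
sum scaled by sqrt of its gene count), and accumulated per cluster with a
1/sqrt(n_cells) scaling.  A cluster whose best score falls below a fraction
of its size is flagged unknown.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .clustering import ClusterPartition

logger = logging.getLogger(__name__)


@dataclass
class AnnotationResult:
    scores: pd.DataFrame  # cluster x cell type
    labels: pd.Series  # cluster -> assigned label
    flags: pd.Series  # cluster -> "assigned" | "unknown"
    provenance: pd.Series = field(default=None)  # cluster -> "auto" | "manual"

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = pd.Series("auto", index=self.labels.index)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "score": self.scores.max(axis=1),
                "flag": self.flags,
                "provenance": self.provenance,
            }
        )


def marker_specificity_weights(db: pd.DataFrame) -> pd.Series:
    """w(g) = 1 - (t_g - 1)/max(T - 1, 1): 1 for a gene unique to one type,
    0 for a gene listed as positive by every type."""
    if db.empty:
        raise ValueError("empty marker database")
    pos = db[db["sign"] == "positive"]
    T = db["cell_type"].nunique()
    t_g = pos.groupby("gene")["cell_type"].nunique()
    w = 1.0 - (t_g - 1) / max(T - 1, 1)
    # negative-only markers default to full weight
    neg_only = set(db["gene"]) - set(w.index)
    if neg_only:
        w = pd.concat([w, pd.Series(1.0, index=sorted(neg_only))])
    return w.rename("weight")


def score_clusters(
    adata: AnnData,
    partition: ClusterPartition,
    db: pd.DataFrame,
    weights: pd.Series | None = None,
    layer: str = "lognorm",
    unknown_fraction: float = 0.25,
) -> AnnotationResult:
    """Specificity-weighted marker scoring of clusters against a marker DB.

    Types with no marker present in the matrix score -inf and trigger a
    warning.  Assignment is the argmax type per cluster (ties broken
    lexicographically by type name); flagged ``unknown`` when the best
    score is below ``unknown_fraction * n_cells``.
    """
    if weights is None:
        weights = marker_specificity_weights(db)
    X = np.asarray(sp.csr_matrix(adata.layers[layer]).todense(), dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    gene_idx = {g: j for j, g in enumerate(adata.var_names)}

    types = sorted(db["cell_type"].unique())
    cell_scores = np.zeros((adata.n_obs, len(types)))
    dead_types = []
    for ti, t in enumerate(types):
        sub = db[db["cell_type"] == t]
        total = np.zeros(adata.n_obs)
        any_present = False
        for sign, direction in (("positive", 1.0), ("negative", -1.0)):
            genes = [g for g in sub.loc[sub["sign"] == sign, "gene"] if g in gene_idx]
            if not genes:
                continue
            any_present = True
            cols = [gene_idx[g] for g in genes]
            w = weights.reindex(genes).fillna(1.0).to_numpy()
            total += direction * (Z[:, cols] * w).sum(axis=1) / np.sqrt(len(genes))
        if not any_present:
            dead_types.append(t)
        cell_scores[:, ti] = total
    if dead_types:
        warnings.warn(
            f"marker types absent from the matrix, scored as -inf: {dead_types}",
            stacklevel=2,
        )

    clusters = np.arange(partition.n_clusters)
    rows = np.zeros((len(clusters), len(types)))
    sizes = np.zeros(len(clusters), dtype=int)
    for cl in clusters:
        mask = partition.labels == cl
        sizes[cl] = mask.sum()
        rows[cl] = cell_scores[mask].sum(axis=0) / np.sqrt(max(sizes[cl], 1))
    for t in dead_types:
        rows[:, types.index(t)] = -np.inf
    scores = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"), columns=types)

    labels = scores.idxmax(axis=1)  # lexicographic tie-break via sorted columns
    best = scores.max(axis=1)
    flags = pd.Series(
        np.where(best < unknown_fraction * sizes, "unknown", "assigned"),
        index=scores.index,
    )
    return AnnotationResult(scores=scores, labels=labels, flags=flags)


def apply_manual_overrides(
    result: AnnotationResult, overrides: dict[int, str]
) -> AnnotationResult:
    """Relabel listed clusters, marking them manual in provenance."""
    labels = result.labels.copy()
    prov = result.provenance.copy()
    known_types = set(result.scores.columns)
    for cl, label in overrides.items():
        if cl not in labels.index:
            raise KeyError(f"unknown cluster id {cl}")
        if label not in known_types:
            warnings.warn(
                f"override label {label!r} absent from marker database", stacklevel=2
            )
        labels.loc[cl] = label
        prov.loc[cl] = "manual"
    return AnnotationResult(
        scores=result.scores, labels=labels, flags=result.flags, provenance=prov
    )
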
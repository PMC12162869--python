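"""Differential expression, signature derivation, module scoring,
over-representation, and signature-based classifier validation.

The DE test is the Wilcoxon rank-sum (Mann-Whitney U) on log-normalized
values, with the Seurat-style gene gates: a gene is tested only if it is
detected in at least ``min_pct`` of cells in one of the two groups and its
|log2FC| (computed on expm1-back-transformed means with a +1 pseudocount)
clears ``logfc_threshold``.  The age-signature is the directional
intersection of two such DE runs.  Module scores subtract bin-matched
control genes; over-representation is the upper-tail hypergeometric with
BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterPartition

EXACT_MAX_N = 20  # exact Wilcoxon enumeration up to this combined group size


@dataclass
class SignatureSet:
    """Up/down gene lists derived from two DE comparisons (disjoint)."""

    up: list[str]
    down: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets overlap")

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


@dataclass
class ClassifierResult:
    sensitivity: float
    specificity: float
    accuracy: float
    importance: pd.Series
    seed: int
    n_train: int
    n_test: int


def _dense(adata: AnnData, layer: str) -> np.ndarray:
    X = adata.layers[layer]
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def wilcoxon_de(
    adata: AnnData,
    cells_a,
    cells_b,
    layer: str = "lognorm",
    min_pct: float = 0.1,
    logfc_threshold: float = 0.1,
    method: str = "auto",
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of group A vs group B on log-normalized values.

    Returns a gene table (log2FC, pct_A, pct_B, p, p_adj) restricted to
    genes passing the detection and fold-change gates; BH adjustment is
    across the tested genes.  ``method`` is ``"exact"`` (full enumeration),
    ``"normal"`` (tie-corrected normal approximation with continuity
    correction) or ``"auto"`` (exact when n_A + n_B <= 20).
    """
    idx = adata.obs_names
    mask_a = idx.isin(cells_a) if not isinstance(cells_a, np.ndarray) or cells_a.dtype != bool else cells_a
    mask_b = idx.isin(cells_b) if not isinstance(cells_b, np.ndarray) or cells_b.dtype != bool else cells_b
    if (mask_a & mask_b).any():
        raise ValueError("cell sets overlap")
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both cell sets must be non-empty")
    A = _dense(adata[mask_a], layer)
    B = _dense(adata[mask_b], layer)
    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)
    log2fc = np.log2(np.expm1(A).mean(axis=0) + 1) - np.log2(np.expm1(B).mean(axis=0) + 1)
    tested = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (
        np.abs(log2fc) >= logfc_threshold
    )
    cols = np.where(tested)[0]
    if method == "auto":
        method = "exact" if A.shape[0] + B.shape[0] <= EXACT_MAX_N else "normal"
    if len(cols) == 0:
        return pd.DataFrame(
            columns=["log2FC", "pct_A", "pct_B", "p", "p_adj"],
            index=pd.Index([], name="gene"),
        )
    if method == "exact":
        p = np.array(
            [
                stats.mannwhitneyu(A[:, j], B[:, j], method="exact").pvalue
                for j in cols
            ]
        )
    elif method == "normal":
        p = stats.mannwhitneyu(A[:, cols], B[:, cols], method="asymptotic", axis=0).pvalue
    else:
        raise ValueError("method must be 'auto', 'exact', or 'normal'")
    p_adj = multipletests(p, method="fdr_bh")[1]
    return (
        pd.DataFrame(
            {
                "gene": adata.var_names[cols],
                "log2FC": log2fc[cols],
                "pct_A": pct_a[cols],
                "pct_B": pct_b[cols],
                "p": p,
                "p_adj": p_adj,
            }
        )
        .set_index("gene")
        .sort_values("p")
    )


def find_all_markers(
    adata: AnnData,
    partition: ClusterPartition,
    layer: str = "lognorm",
    min_pct: float = 0.1,
    logfc_threshold: float = 0.1,
) -> dict[int, pd.DataFrame]:
    """One-vs-rest Wilcoxon markers per cluster (both signs retained)."""
    if partition.n_clusters < 2:
        raise ValueError("need at least two clusters")
    out = {}
    for cl in range(partition.n_clusters):
        mask = partition.labels == cl
        out[cl] = wilcoxon_de(
            adata,
            mask,
            ~mask,
            layer=layer,
            min_pct=min_pct,
            logfc_threshold=logfc_threshold,
        )
    return out


def derive_consensus_signature(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> SignatureSet:
    """Directional intersection of two DE runs.

    A gene enters the up (down) set iff it clears adjusted p < ``alpha``
    and |log2FC| >= ``logfc_threshold`` in BOTH comparisons with the same
    sign in both.  Symmetric in its two inputs.
    """
    def passing(de: pd.DataFrame) -> pd.DataFrame:
        return de[(de["p_adj"] < alpha) & (de["log2FC"].abs() >= logfc_threshold)]

    a, b = passing(de1), passing(de2)
    common = a.index.intersection(b.index)
    same_sign = np.sign(a.loc[common, "log2FC"]) == np.sign(b.loc[common, "log2FC"])
    common = common[same_sign]
    up = sorted(common[a.loc[common, "log2FC"] > 0])
    down = sorted(common[a.loc[common, "log2FC"] < 0])
    if not up and not down:
        warnings.warn("directional intersection is empty", stacklevel=2)
    return SignatureSet(
        up=up,
        down=down,
        provenance={"logfc_threshold": logfc_threshold, "alpha": alpha},
    )


def module_score(
    adata: AnnData,
    genes: list[str],
    ctrl: int = 10,
    nbin: int = 24,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.Series:
    """Bin-matched module score per cell.

    Genes are binned into ``nbin`` equal-frequency bins by average
    expression; for each signature gene, ``ctrl`` control genes are drawn
    without replacement from its bin (seeded).  Score = mean over signature
    genes minus mean over the pooled control genes, per cell.
    """
    genes = [g for g in genes if g in set(adata.var_names)]
    if not genes:
        raise ValueError("no signature gene present in the matrix")
    X = _dense(adata, layer)
    avg = X.mean(axis=0)
    ranks = pd.Series(avg, index=adata.var_names).rank(method="first")
    bins = pd.qcut(ranks, min(nbin, adata.n_vars), labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}
    control: list[int] = []
    for g in genes:
        pool = bins.index[(bins == bins[g]) & (bins.index != g)]
        take = min(ctrl, len(pool))
        if take:
            chosen = rng.choice(len(pool), size=take, replace=False)
            control.extend(gene_pos[pool[i]] for i in chosen)
    sig_cols = [gene_pos[g] for g in genes]
    sig_mean = X[:, sig_cols].mean(axis=1)
    ctrl_mean = X[:, control].mean(axis=1) if control else np.zeros(adata.n_obs)
    return pd.Series(sig_mean - ctrl_mean, index=adata.obs_names, name="module_score")


def hypergeometric_enrichment(
    gene_list, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    Each set is intersected with the universe before testing; the odds
    ratio comes from the 2x2 table with a Haldane +0.5 correction when any
    cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & universe
        k = len(gene_list & s)
        M, n, N = len(universe), len(s), len(gene_list)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        a, b = k, N - k
        c, d = n - k, M - n - (N - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": n,
                "list_size": N,
                "universe_size": M,
                "p": p,
                "odds_ratio": (a * d) / (b * c),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_set")
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df


def train_signature_classifier(
    adata: AnnData,
    group_labels: pd.Series,
    signature: SignatureSet | list[str],
    n_per_group: int = 1000,
    seed: int = 0,
    layer: str = "lognorm",
    n_trees: int = 500,
    n_importance_repeats: int = 5,
) -> ClassifierResult:
    """Random-forest separation of two groups on signature-gene expression.

    Balanced subsample of ``n_per_group`` cells per group, 50/50
    train/test split, features scaled/centered on the training set and
    applied to the test set; reports held-out sensitivity and specificity
    and per-feature permutation importance.
    """
    genes = signature.genes if isinstance(signature, SignatureSet) else list(signature)
    genes = [g for g in genes if g in set(adata.var_names)]
    if not genes:
        raise ValueError("no signature gene present in the matrix")
    group_labels = pd.Series(group_labels, index=adata.obs_names)
    groups = sorted(group_labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)
    picked = []
    for g in groups:
        pool = np.where((group_labels == g).to_numpy())[0]
        if len(pool) < n_per_group:
            raise ValueError(f"group {g!r} has fewer than {n_per_group} cells")
        picked.append(rng.choice(pool, size=n_per_group, replace=False))
    X = _dense(adata[:, genes], layer)
    Xs = np.vstack([X[p] for p in picked])
    y = np.concatenate([np.full(n_per_group, i) for i in range(2)])
    order = rng.permutation(len(y))
    Xs, y = Xs[order], y[order]
    half = len(y) // 2
    scaler = StandardScaler().fit(Xs[:half])
    Xtr, Xte = scaler.transform(Xs[:half]), scaler.transform(Xs[half:])
    ytr, yte = y[:half], y[half:]
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31))
    ).fit(Xtr, ytr)
    pred = clf.predict(Xte)
    # class 1 = positive
    tp = int(((pred == 1) & (yte == 1)).sum())
    tn = int(((pred == 0) & (yte == 0)).sum())
    fn = int(((pred == 0) & (yte == 1)).sum())
    fp = int(((pred == 1) & (yte == 0)).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    imp = permutation_importance(
        clf,
        Xte,
        yte,
        n_repeats=n_importance_repeats,
        random_state=int(rng.integers(2**31)),
    )
    importance = pd.Series(imp.importances_mean, index=genes, name="importance")
    return ClassifierResult(
        sensitivity=sens,
        specificity=spec,
        accuracy=float((pred == yte).mean()),
        importance=importance,
        seed=seed,
        n_train=half,
        n_test=len(y) - half,
    )


def importance_overlap_test(
    imp1: pd.Series, imp2: pd.Series, thresholds
) -> pd.DataFrame:
    """Overlap of top-feature sets at each importance threshold, with a
    two-sided Fisher exact p against the shared feature universe."""
    if not imp1.index.sort_values().equals(imp2.index.sort_values()):
        raise ValueError("importance vectors cover different feature universes")
    imp2 = imp2.reindex(imp1.index)
    n = len(imp1)
    rows = []
    for t in thresholds:
        s1 = set(imp1.index[imp1 >= t])
        s2 = set(imp2.index[imp2 >= t])
        k = len(s1 & s2)
        table = [
            [k, len(s1) - k],
            [len(s2) - k, n - len(s1) - len(s2) + k],
        ]
        p = 1.0 if not s1 or not s2 else float(stats.fisher_exact(table)[1])
        rows.append(
            {"threshold": t, "top1": len(s1), "top2": len(s2), "overlap": k, "fisher_p": p}
        )
    return pd.DataFrame(rows)


def write_gmt(signatures: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out
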
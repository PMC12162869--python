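"""Synthetic multi-sample TME scRNA-seq data with planted ground truth.

Emulates FACS-sorted captures (cancer / immune / stromal compartments) from
young and adult mice: negative-binomial counts with type-specific marker
elevation, age-group-dependent cell-type proportions, planted differentially
expressed genes within one target type (a collagen-like matrix-CAF program),
a fraction of mis-sorted cells, and planted sender->receiver ligand-receptor
co-expression channels.  Every downstream pipeline stage can be tested
against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData


class ConfigError(ValueError):
    """Raised when a synthetic-data configuration violates its invariants."""


@dataclass(frozen=True)
class CellTypeSpec:
    """One planted cell type and the compartment it is sorted into."""

    name: str
    compartment: str
    n_marker_genes: int = 25
    marker_log2_elevation: float = 3.0


@dataclass(frozen=True)
class DESpec:
    """A planted age-group expression program inside one cell type.

    ``n_genes`` genes are elevated by ``log2fc`` in cells of ``cell_type``
    belonging to ``up_group``; half of them can instead be elevated in the
    other group by setting ``symmetric`` (up genes in ``up_group``, down
    genes mirrored), mimicking an up/down signature.
    """

    cell_type: str
    n_genes: int = 40
    log2fc: float = 1.0
    up_group: str = "adult"
    symmetric: bool = True
    # planted program genes sit on a high-expression baseline (collagens are
    # among the most abundant fibroblast transcripts)
    baseline_log2_boost: float = 3.0


@dataclass(frozen=True)
class LRChannelSpec:
    """A planted directed ligand-receptor channel between two cell types."""

    sender: str
    receiver: str
    log2_elevation: float = 3.0
    ligand: str | None = None
    receptor: str | None = None


@dataclass
class SynthConfig:
    """Full description of a synthetic TME dataset.

    ``group_proportions`` maps each age group to a vector of cell-type
    proportions (same order as ``cell_types``); each vector must sum to 1.
    Counts are NB with mean = baseline x elevations x library factor and a
    shared inverse-dispersion ``nb_dispersion`` (var = m + m^2/dispersion).
    """

    n_genes: int = 2000
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("cancer", "cancer"),
            CellTypeSpec("tcell", "immune"),
            CellTypeSpec("caf", "stromal"),
        ]
    )
    group_proportions: dict[str, list[float]] = field(
        default_factory=lambda: {
            "young": [0.4, 0.3, 0.3],
            "adult": [0.4, 0.4, 0.2],
        }
    )
    n_cells_per_sample: int = 500
    n_samples_per_group: int = 2
    de_spec: DESpec | None = None
    missort_fraction: float = 0.0
    lr_spec: list[LRChannelSpec] = field(default_factory=list)
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple[float, float] = (0.0, 0.25)
    baseline_lognormal: tuple[float, float] = (np.log(0.3), 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_cells_per_sample <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("zero cells requested")
        if not self.cell_types:
            raise ConfigError("at least one cell type is required")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell type names")
        for group, props in self.group_proportions.items():
            if len(props) != len(self.cell_types):
                raise ConfigError(
                    f"group {group!r}: {len(props)} proportions for "
                    f"{len(self.cell_types)} cell types"
                )
            if any(p < 0 for p in props):
                raise ConfigError(f"group {group!r}: negative proportion")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigError(
                    f"group {group!r}: proportions sum to {sum(props)}, not 1"
                )
        if not (0.0 <= self.missort_fraction < 0.5):
            raise ConfigError("missort_fraction must lie in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.de_spec is not None:
            if self.de_spec.cell_type not in names:
                raise ConfigError(f"de_spec targets unknown type {self.de_spec.cell_type!r}")
            if self.de_spec.up_group not in self.group_proportions:
                raise ConfigError(f"de_spec up_group {self.de_spec.up_group!r} unknown")
        for ch in self.lr_spec:
            if ch.sender not in names or ch.receiver not in names:
                raise ConfigError("lr_spec references unknown cell type")
            if ch.ligand is not None and ch.ligand == ch.receptor:
                raise ConfigError("ligand gene equal to receptor gene in lr_spec")


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset.

    ``gene_roles`` maps gene name -> role (``marker:<type>``, ``de_up``,
    ``de_down``, ``lr_ligand:<i>``, ``lr_receptor:<i>``); unlisted genes are
    background.  ``log2_proportion_shift`` gives, per cell type, the planted
    log2 ratio of its proportion between the two groups (second over first,
    in the order of ``group_names``).
    """

    true_type: pd.Series
    true_compartment: pd.Series
    gene_roles: dict[str, str]
    markers: dict[str, list[str]]
    de_up: list[str]
    de_down: list[str]
    de_target_type: str | None
    de_up_group: str | None
    lr_channels: list[dict]
    log2_proportion_shift: dict[str, float]
    group_names: list[str]

    def to_json(self) -> str:
        payload = {
            "true_type": self.true_type.tolist(),
            "true_compartment": self.true_compartment.tolist(),
            "cells": self.true_type.index.tolist(),
            "gene_roles": self.gene_roles,
            "markers": self.markers,
            "de_up": self.de_up,
            "de_down": self.de_down,
            "de_target_type": self.de_target_type,
            "de_up_group": self.de_up_group,
            "lr_channels": self.lr_channels,
            "log2_proportion_shift": self.log2_proportion_shift,
            "group_names": self.group_names,
        }
        return json.dumps(payload, indent=1)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_tme_dataset(config: SynthConfig) -> tuple[AnnData, GroundTruth]:
    """Generate counts + per-cell metadata + ground truth.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse integer
    counts in ``.X``; ``sample``, ``age_group``, ``treatment``,
    ``sorted_compartment`` in ``.obs``) and the planted :class:`GroundTruth`.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config.n_genes)
    gene_index = {g: j for j, g in enumerate(genes)}
    type_names = [t.name for t in config.cell_types]
    groups = list(config.group_proportions)

    # assign disjoint planted gene blocks: markers, DE, LR, background
    cursor = 0
    gene_roles: dict[str, str] = {}
    markers: dict[str, list[str]] = {}
    for t in config.cell_types:
        if cursor + t.n_marker_genes > config.n_genes:
            raise ConfigError("n_genes too small for requested planted genes")
        markers[t.name] = genes[cursor : cursor + t.n_marker_genes]
        for g in markers[t.name]:
            gene_roles[g] = f"marker:{t.name}"
        cursor += t.n_marker_genes

    de_up: list[str] = []
    de_down: list[str] = []
    if config.de_spec is not None:
        n_de = config.de_spec.n_genes
        if cursor + n_de > config.n_genes:
            raise ConfigError("n_genes too small for planted DE genes")
        block = genes[cursor : cursor + n_de]
        cursor += n_de
        if config.de_spec.symmetric:
            half = n_de // 2
            de_up, de_down = block[:half], block[half:]
        else:
            de_up, de_down = block, []
        for g in de_up:
            gene_roles[g] = "de_up"
        for g in de_down:
            gene_roles[g] = "de_down"

    lr_channels: list[dict] = []
    for i, ch in enumerate(config.lr_spec):
        if ch.ligand is None or ch.receptor is None:
            if cursor + 2 > config.n_genes:
                raise ConfigError("n_genes too small for planted LR genes")
            lig = ch.ligand or genes[cursor]
            rec = ch.receptor or genes[cursor + 1]
            cursor += 2
        else:
            lig, rec = ch.ligand, ch.receptor
        gene_roles[lig] = f"lr_ligand:{i}"
        gene_roles[rec] = f"lr_receptor:{i}"
        lr_channels.append(
            {
                "ligand": lig,
                "receptor": rec,
                "sender": ch.sender,
                "receiver": ch.receiver,
                "log2_elevation": ch.log2_elevation,
            }
        )

    # per-gene baseline means
    mlog, sdlog = config.baseline_lognormal
    baseline = rng.lognormal(mlog, sdlog, size=config.n_genes)
    if config.de_spec is not None and config.de_spec.baseline_log2_boost:
        for g in de_up + de_down:
            baseline[gene_index[g]] *= 2.0**config.de_spec.baseline_log2_boost

    # per-(type, gene) log2 elevation matrix
    elev = np.zeros((len(type_names), config.n_genes))
    for ti, t in enumerate(config.cell_types):
        for g in markers[t.name]:
            elev[ti, gene_index[g]] = t.marker_log2_elevation
    for ch in lr_channels:
        si = type_names.index(ch["sender"])
        ri = type_names.index(ch["receiver"])
        elev[si, gene_index[ch["ligand"]]] += ch["log2_elevation"]
        elev[ri, gene_index[ch["receptor"]]] += ch["log2_elevation"]

    # draw cells sample by sample
    cells: list[str] = []
    obs_rows: list[tuple[str, str, str, str]] = []
    true_types: list[str] = []
    blocks: list[sp.csr_matrix] = []
    de_ti = type_names.index(config.de_spec.cell_type) if config.de_spec else -1
    de_cols_up = np.array([gene_index[g] for g in de_up], dtype=int)
    de_cols_down = np.array([gene_index[g] for g in de_down], dtype=int)

    for group in groups:
        props = np.asarray(config.group_proportions[group], dtype=float)
        for s in range(config.n_samples_per_group):
            sample = f"{group}_s{s}"
            n = config.n_cells_per_sample
            type_idx = rng.choice(len(type_names), size=n, p=props)
            libsize = rng.lognormal(*config.libsize_lognormal, size=n)
            log2elev = elev[type_idx, :].copy()
            if config.de_spec is not None and group == config.de_spec.up_group:
                mask = type_idx == de_ti
                log2elev[np.ix_(mask, de_cols_up)] += config.de_spec.log2fc
            elif config.de_spec is not None:
                mask = type_idx == de_ti
                log2elev[np.ix_(mask, de_cols_down)] += config.de_spec.log2fc
            mean = baseline[None, :] * 2.0**log2elev * libsize[:, None]
            # NB via gamma-Poisson mixture
            theta = config.nb_dispersion
            lam = rng.gamma(theta, mean / theta)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))
            for i in range(n):
                cells.append(f"{sample}_c{i:05d}")
            obs_rows.extend(
                (sample, group, "naive", config.cell_types[ti].compartment)
                for ti in type_idx
            )
            true_types.extend(type_names[ti] for ti in type_idx)

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows,
        columns=["sample", "age_group", "treatment", "sorted_compartment"],
        index=pd.Index(cells, name="cell"),
    )
    true_type = pd.Series(true_types, index=obs.index, name="true_type")
    comp_of = {t.name: t.compartment for t in config.cell_types}
    true_comp = true_type.map(comp_of).rename("true_compartment")

    # mis-sorting: wrong compartment label, true type unchanged
    if config.missort_fraction > 0:
        n_cells = len(cells)
        n_bad = int(round(config.missort_fraction * n_cells))
        bad = rng.choice(n_cells, size=n_bad, replace=False)
        compartments = sorted({t.compartment for t in config.cell_types})
        for i in bad:
            others = [c for c in compartments if c != true_comp.iloc[i]]
            if others:
                obs.iloc[i, obs.columns.get_loc("sorted_compartment")] = others[
                    rng.integers(len(others))
                ]

    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))

    shifts: dict[str, float] = {}
    if len(groups) >= 2:
        pa = np.asarray(config.group_proportions[groups[1]], float)
        pb = np.asarray(config.group_proportions[groups[0]], float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfd = np.log2(pa) - np.log2(pb)
        shifts = dict(zip(type_names, lfd.tolist()))

    truth = GroundTruth(
        true_type=true_type,
        true_compartment=true_comp,
        gene_roles=gene_roles,
        markers=markers,
        de_up=de_up,
        de_down=de_down,
        de_target_type=config.de_spec.cell_type if config.de_spec else None,
        de_up_group=config.de_spec.up_group if config.de_spec else None,
        lr_channels=lr_channels,
        log2_proportion_shift=shifts,
        group_names=groups,
    )
    return adata, truth


def generate_marker_db(
    truth: GroundTruth, n_decoys: int = 0, decoy_genes: list[str] | None = None
) -> pd.DataFrame:
    """Marker database table (cell_type, gene, sign) from planted markers.

    Optionally injects ``n_decoys`` decoy genes listed as positive markers of
    *every* type, to exercise specificity down-weighting.
    """
    if not truth.markers or all(len(v) == 0 for v in truth.markers.values()):
        raise ConfigError("ground truth contains no planted markers")
    for t, genes in truth.markers.items():
        if not genes:
            raise ConfigError(f"cell type {t!r} has zero markers")
    rows = [
        (t, g, "positive") for t, genes in truth.markers.items() for g in genes
    ]
    if n_decoys > 0:
        if decoy_genes is None:
            pool = [g for g, r in truth.gene_roles.items() if not r.startswith("marker")]
            pool += [f"decoy{i:03d}" for i in range(max(0, n_decoys - len(pool)))]
            decoy_genes = pool[:n_decoys]
        for g in decoy_genes[:n_decoys]:
            rows.extend((t, g, "positive") for t in truth.markers)
    return pd.DataFrame(rows, columns=["cell_type", "gene", "sign"])


def generate_lr_database(
    config: SynthConfig,
    truth: GroundTruth,
    n_background_pairs: int = 16,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LR pair table (planted + background pairs) and an ortholog mapping.

    Background pairs are drawn among genes with no planted role.  The
    mapping table (``symbol``, ``ortholog``) covers every gene used and is a
    bijection, so mapping then inverse-mapping round-trips.
    """
    if not truth.lr_channels:
        raise ConfigError("lr_spec is empty: no planted LR channels")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pairs = {(ch["ligand"], ch["receptor"]) for ch in truth.lr_channels}
    for lig, rec in pairs:
        if lig == rec:
            raise ConfigError("ligand gene equal to receptor gene in a pair")
    background = [
        g for g in _gene_names(config.n_genes) if g not in truth.gene_roles
    ]
    bg_pairs: set[tuple[str, str]] = set()
    while len(bg_pairs) < n_background_pairs and len(background) >= 2:
        i, j = rng.choice(len(background), size=2, replace=False)
        pair = (background[i], background[j])
        if pair not in pairs:
            bg_pairs.add(pair)
    planted = sorted(pairs)
    table = pd.DataFrame(
        planted + sorted(bg_pairs), columns=["ligand", "receptor"]
    ).drop_duplicates(ignore_index=True)
    used = sorted(set(table["ligand"]) | set(table["receptor"]))
    mapping = pd.DataFrame(
        {"symbol": used, "ortholog": [f"H{g.upper()}" for g in used]}
    )
    return table, mapping


def write_10x_triplet(
    adata: AnnData, path: str | Path, truth: GroundTruth | None = None
) -> None:
    """Write 10x triplet (matrix.mtx genes x cells, features.tsv,
    barcodes.tsv) plus metadata.tsv and, if given, ground_truth.json."""
    from scipy.io import mmwrite

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(adata.X).T.astype(np.int64)  # genes x cells
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(mat), field="integer")
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(path / "metadata.tsv", sep="\t")
    if truth is not None:
        (path / "ground_truth.json").write_text(truth.to_json())
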
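"""Quality control, normalisation, embedding, clustering and annotation.

Implements the standard droplet scRNA-seq preprocessing chain: strict
detected-gene and mitochondrial-fraction cell filters, a minimum-cells gene
filter, library-size log-normalisation, bin-standardised-dispersion HVG
selection, scaled PCA, SNN-graph Leiden clustering, marker-panel cell-type
annotation and per-condition composition tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from stxmicro._graphcluster import snn_leiden
from stxmicro.dataset import CellDataset


@dataclass
class QCParams:
    """Quality-control and embedding parameters.

    Cells are kept when their detected-gene count lies in
    ``[min_genes, max_genes]`` and their mitochondrial UMI fraction is at
    most ``max_mito`` (the removal criteria are strict: "less than 200",
    "more than 3000", "over 10%"); genes must be detected in at least
    ``min_cells_per_gene`` retained cells.
    """

    min_genes: int = 200
    max_genes: int = 3000
    min_cells_per_gene: int = 3
    max_mito: float = 0.10
    n_hvg: int = 2000
    n_pcs: int = 30
    resolution: float = 1.0
    scale_factor: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 < self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in (0, 1]")
        if min(self.min_cells_per_gene, self.n_hvg, self.n_pcs) < 1:
            raise ValueError("min_cells_per_gene, n_hvg, n_pcs must be >= 1")


#: Marker panels for cluster annotation (mouse brain cell types).
DEFAULT_MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "Astrocyte": ("F3", "Gja1", "Slc1a3", "Gjb6"),
    "B cells": ("Cd19", "Cd79a"),
    "Choroid plexus cells": ("Ttr", "Clic6", "Sostdc1", "Car12", "Prlr", "Htr2c"),
    "Endothelial Cells": ("Cldn5", "Ly6c1", "Ly6a", "Itm2a"),
    "Ependymal": ("Calml4", "Chchd10", "Clu"),
    "Microglia": ("Hexb", "C1qa", "Tmem119", "Gpr34", "Olfml3"),
    "Monocyte": ("Cd14", "Cd86"),
    "Neuron": ("Rtn1", "Sox4"),
    "Neutrophil": ("Trem1", "Mmp8"),
    "Oligodendrocyte progenitor cells": ("Olig1", "Olig2", "Pdgfra", "Tnr", "C1ql1", "Matn4"),
    "Oligodendrocytes": ("Cldn11", "Mag", "Opalin", "Ermn", "Mog"),
    "Pericytes": ("Kcnj8", "Atp13a5", "Anpep", "Abcc9", "Cd248"),
    "T cells": ("Cd8a", "Klrd1", "Cd4"),
    "Vascular Smooth-muscle Cells": ("Acta2", "Des", "Tpm2", "Filip1l"),
}


@dataclass
class MarkerPanelSet:
    """Named cell-type marker panels used for cluster annotation."""

    panels: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()})

    def __post_init__(self) -> None:
        for name, genes in self.panels.items():
            if not genes:
                raise ValueError(f"marker panel {name!r} is empty")

    def items(self):
        return self.panels.items()


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts_mtx(directory, conditions_file=None) -> CellDataset:
    """Read a 10x-style MTX triplet (genes x cells) plus a conditions TSV.

    ``conditions_file`` defaults to ``conditions.tsv`` inside ``directory``;
    every barcode must carry a condition label.
    """
    directory = Path(directory)
    matrix_path = directory / "matrix.mtx"
    genes_path = directory / "genes.tsv"
    barcodes_path = directory / "barcodes.tsv"
    conditions_path = Path(conditions_file) if conditions_file else directory / "conditions.tsv"
    for p in (matrix_path, genes_path, barcodes_path, conditions_path):
        if not p.exists():
            raise FileNotFoundError(f"required input file missing: {p}")

    mat = scipy.io.mmread(matrix_path)  # genes x cells, 1-based on disk
    if np.issubdtype(np.asarray(mat.data if sp.issparse(mat) else mat).dtype, np.floating):
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{matrix_path}: non-integer matrix entries")
    counts = sp.csr_matrix(mat.T).astype(np.int64)

    genes = np.array(genes_path.read_text().splitlines(), dtype=object)
    # tolerate the two-column Ensembl-id + symbol layout of CellRanger exports
    genes = np.array([g.split("\t")[-1] for g in genes], dtype=object)
    barcodes = np.array(barcodes_path.read_text().splitlines(), dtype=object)
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix is {counts.shape[1]} genes x {counts.shape[0]} cells but found "
            f"{len(genes)} gene names and {len(barcodes)} barcodes"
        )

    label_map: dict[str, str] = {}
    for line in conditions_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{conditions_path}: malformed line {line!r}")
        label_map[parts[0]] = parts[1]
    missing = [b for b in barcodes if b not in label_map]
    if missing:
        raise ValueError(f"no condition label for barcode(s): {', '.join(map(str, missing[:5]))}")
    condition = np.array([label_map[b] for b in barcodes], dtype=object)
    return CellDataset(counts=counts, gene_names=genes, cell_barcodes=barcodes, condition=condition)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(dataset: CellDataset, params: QCParams | None = None) -> CellDataset:
    """Apply the cell and gene quality filters.

    Keeps cells with detected-gene count in ``[min_genes, max_genes]`` and
    mitochondrial fraction <= ``max_mito``, then genes detected in at least
    ``min_cells_per_gene`` of the retained cells; the two criteria are
    iterated to a fixed point so the returned dataset itself satisfies
    both (which also makes the filter idempotent).  Cell and gene order
    are preserved.
    """
    params = params or QCParams()
    current = dataset
    while True:
        detected = current.n_genes_by_cell
        keep_cells = (
            (detected >= params.min_genes)
            & (detected <= params.max_genes)
            & (current.mito_fraction <= params.max_mito + 1e-12)
        )
        cells_idx = np.flatnonzero(keep_cells)
        after_cells = current.subset(cell_idx=cells_idx) if cells_idx.size < current.n_cells else current
        cells_per_gene = np.asarray((after_cells.counts > 0).sum(axis=0)).ravel()
        keep_genes = cells_per_gene >= params.min_cells_per_gene
        genes_idx = np.flatnonzero(keep_genes)
        changed = cells_idx.size < current.n_cells or genes_idx.size < current.n_genes
        current = after_cells.subset(gene_idx=genes_idx) if genes_idx.size < after_cells.n_genes else after_cells
        if not changed:
            break
    if current.n_cells == 0 or current.n_genes == 0:
        warnings.warn("quality filtering removed all cells or all genes")
    return current


def log_normalize(dataset: CellDataset, scale_factor: float = 1e4) -> CellDataset:
    """lognorm[i, j] = ln(1 + counts[i, j] / total_counts[i] * scale_factor)."""
    total = dataset.total_counts.astype(float)
    if np.any(total == 0):
        bad = dataset.cell_barcodes[total == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    dense = dataset.counts.toarray().astype(float)
    dataset.lognorm = np.log1p(dense / total[:, None] * scale_factor)
    return dataset


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

def select_hvg(dataset: CellDataset, n_hvg: int = 2000, n_bins: int = 20) -> CellDataset:
    """Flag the ``n_hvg`` genes with highest bin-standardised dispersion.

    Dispersion = variance/mean of the log-normalised values, z-scored
    within mean-quantile bins.  Zero-variance genes rank strictly below any
    gene with positive variance; remaining ties break by gene name.
    """
    if dataset.lognorm is None:
        raise ValueError("run log_normalize before select_hvg")
    n_genes = dataset.n_genes
    if n_genes == 0 or dataset.n_cells == 0:
        raise ValueError("dataset has no cells or no genes (did QC remove everything?)")
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds the {n_genes} genes present")
    X = dataset.lognorm
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    n_bins = max(1, min(n_bins, n_genes))
    # quantile bins on the mean; duplicate edges collapse for skewed data
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    bin_id = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2) if len(edges) > 1 else np.zeros(n_genes, int)

    z = np.zeros(n_genes)
    for b in np.unique(bin_id):
        in_bin = bin_id == b
        d = disp[in_bin]
        sd = d.std()
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0

    constant = var == 0
    order = sorted(
        range(n_genes),
        key=lambda g: (constant[g], -z[g], -disp[g], str(dataset.gene_names[g])),
    )
    mask = np.zeros(n_genes, dtype=bool)
    mask[order[:n_hvg]] = True
    dataset.hvg_mask = mask
    return dataset


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

def scale_matrix(X: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-score with values clipped at +/- ``clip``; constant genes map to 0."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    return np.clip((X - mean) / std_safe, -clip, clip)


def fix_component_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|loading| entry of each
    component is made positive (first such entry on ties)."""
    components = components.copy()
    scores = scores.copy()
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return components, scores


def embed_pca(dataset: CellDataset, n_pcs: int = 30) -> CellDataset:
    """PCA scores of the scaled HVG log-normalised matrix."""
    from sklearn.decomposition import PCA

    if dataset.hvg_mask is None:
        raise ValueError("run select_hvg before embed_pca")
    X = scale_matrix(dataset.lognorm[:, dataset.hvg_mask])
    limit = min(X.shape)
    if n_pcs >= limit:
        raise ValueError(f"n_pcs={n_pcs} must be < min(n_cells, n_hvg) = {limit}")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    _, scores = fix_component_signs(pca.components_, scores)
    dataset.embedding = scores
    return dataset


# ---------------------------------------------------------------------------
# Clustering and annotation
# ---------------------------------------------------------------------------

def cluster_cells(dataset: CellDataset, resolution: float = 1.0, seed: int = 0) -> CellDataset:
    """Leiden communities of the SNN graph built on the PCA embedding."""
    if dataset.embedding is None:
        raise ValueError("run embed_pca before cluster_cells")
    dataset.cluster = snn_leiden(dataset.embedding, resolution=resolution, seed=seed)
    return dataset


def annotate_clusters(dataset: CellDataset, panels: MarkerPanelSet | None = None) -> CellDataset:
    """Assign each cluster the cell type whose marker panel scores highest.

    A panel's score in a cluster is the mean z-scored log-normalised
    expression of its genes over the cluster's cells; absent panel genes are
    ignored with a warning, and a panel with no gene present is ineligible.
    Equal top scores break alphabetically and are flagged ambiguous.
    """
    panels = panels or MarkerPanelSet()
    if dataset.cluster is None:
        raise ValueError("run cluster_cells before annotate_clusters")
    Z = scale_matrix(dataset.lognorm, clip=np.inf)
    name_to_idx = {g: i for i, g in enumerate(dataset.gene_names)}

    panel_idx: dict[str, list[int]] = {}
    for ctype, genes in panels.items():
        present = [name_to_idx[g] for g in genes if g in name_to_idx]
        absent = [g for g in genes if g not in name_to_idx]
        if absent:
            warnings.warn(f"panel {ctype!r}: marker gene(s) absent from data: {', '.join(absent)}")
        if present:
            panel_idx[ctype] = present
    if not panel_idx:
        raise ValueError("no marker panel has any gene present in the dataset")

    clusters = sorted(set(dataset.cluster), key=str)
    rows = []
    assignment: dict[str, str] = {}
    for cl in clusters:
        cells = dataset.cluster == cl
        scores = {ctype: float(Z[np.ix_(cells, idx)].mean()) for ctype, idx in panel_idx.items()}
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best_type, best = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else float("-inf")
        ambiguous = bool(len(ranked) > 1 and best == runner_up)
        if ambiguous:
            warnings.warn(f"cluster {cl}: tied annotation scores; alphabetical tie-break -> {best_type}")
        assignment[cl] = best_type
        rows.append({"cluster": cl, "cell_type": best_type, "score": best,
                     "margin": best - runner_up, "ambiguous": ambiguous})
    dataset.cell_type = np.array([assignment[c] for c in dataset.cluster], dtype=object)
    dataset.annotation_scores = pd.DataFrame(rows)
    return dataset


def composition_table(dataset: CellDataset) -> pd.DataFrame:
    """Percentage of each cell type within each condition (rows sum to 100)."""
    if dataset.cell_type is None:
        raise ValueError("run annotate_clusters before composition_table")
    counts = pd.crosstab(pd.Series(dataset.condition, name="condition"),
                         pd.Series(dataset.cell_type, name="cell_type"))
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
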
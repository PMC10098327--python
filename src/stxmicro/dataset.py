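"""Core in-memory container for multi-condition single-cell count data.

``CellDataset`` holds a cells x genes UMI count matrix together with
per-cell condition labels and the derived layers the pipeline fills in as
it runs (log-normalised expression, HVG mask, PCA embedding, cluster and
cell-type labels).  Conversion to/from :class:`anndata.AnnData` gives h5ad
persistence without inventing a container format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

MITO_PREFIX = "mt-"


def is_mito(gene_names) -> np.ndarray:
    """Boolean mask of mitochondrial genes, by case-insensitive ``mt-`` prefix
    (the standard mouse symbol convention, e.g. mt-Co1, mt-Nd1)."""
    return np.array([str(g).lower().startswith(MITO_PREFIX) for g in gene_names], dtype=bool)


@dataclass
class CellDataset:
    """Cells x genes UMI counts with per-cell condition labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell (stored sparse CSR).
    gene_names, cell_barcodes
        Row/column identifiers; unique within the dataset.
    condition
        Per-cell categorical label, e.g. ``sham``/``day1``/``day3``/``day7``.
    """

    counts: sp.csr_matrix
    gene_names: np.ndarray
    cell_barcodes: np.ndarray
    condition: np.ndarray
    lognorm: np.ndarray | None = None
    hvg_mask: np.ndarray | None = None
    embedding: np.ndarray | None = None
    cluster: np.ndarray | None = None
    cell_type: np.ndarray | None = None
    annotation_scores: "object | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if np.issubdtype(self.counts.dtype, np.floating):
            data = self.counts.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.counts.shape != (len(self.cell_barcodes), len(self.gene_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_barcodes)} barcodes x {len(self.gene_names)} genes"
            )
        if len(self.condition) != self.n_cells:
            raise ValueError("one condition label required per cell")

    # -- derived per-cell QC fields -------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes_by_cell(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    @property
    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def mito_mask(self) -> np.ndarray:
        return is_mito(self.gene_names)

    @property
    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs on mitochondrial genes (0 for empty cells)."""
        total = self.total_counts.astype(float)
        mito = np.asarray(self.counts[:, self.mito_mask].sum(axis=1)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return frac

    # -- subsetting ------------------------------------------------------
    def subset(self, cell_idx=None, gene_idx=None) -> "CellDataset":
        """Return a new dataset restricted to the given cell/gene indices
        (order preserved as given); derived layers are sliced where defined."""
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        out = CellDataset(
            counts=self.counts[ci][:, gi],
            gene_names=self.gene_names[gi],
            cell_barcodes=self.cell_barcodes[ci],
            condition=self.condition[ci],
        )
        if self.lognorm is not None:
            out.lognorm = self.lognorm[np.ix_(ci, gi)]
        if self.hvg_mask is not None:
            out.hvg_mask = self.hvg_mask[gi]
        if self.embedding is not None:
            out.embedding = self.embedding[ci]
        if self.cluster is not None:
            out.cluster = self.cluster[ci]
        if self.cell_type is not None:
            out.cell_type = self.cell_type[ci]
        return out

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_names == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not present in dataset")
        return int(hits[0])

    # -- AnnData / h5ad interop ------------------------------------------
    def to_anndata(self):
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame({"condition": pd.Categorical(self.condition)},
                             index=pd.Index(self.cell_barcodes.astype(str), name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_names.astype(str), name="gene")),
        )
        if self.lognorm is not None:
            adata.layers["lognorm"] = np.asarray(self.lognorm)
        if self.hvg_mask is not None:
            adata.var["highly_variable"] = self.hvg_mask
        if self.embedding is not None:
            adata.obsm["X_pca"] = np.asarray(self.embedding)
        if self.cluster is not None:
            adata.obs["cluster"] = pd.Categorical(self.cluster)
        if self.cell_type is not None:
            adata.obs["cell_type"] = pd.Categorical(self.cell_type)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CellDataset":
        ds = cls(
            counts=sp.csr_matrix(adata.X),
            gene_names=np.asarray(adata.var_names, dtype=object),
            cell_barcodes=np.asarray(adata.obs_names, dtype=object),
            condition=np.asarray(adata.obs["condition"], dtype=object),
        )
        if "lognorm" in adata.layers:
            ds.lognorm = np.asarray(adata.layers["lognorm"])
        if "highly_variable" in adata.var:
            ds.hvg_mask = np.asarray(adata.var["highly_variable"], dtype=bool)
        if "X_pca" in adata.obsm:
            ds.embedding = np.asarray(adata.obsm["X_pca"])
        if "cluster" in adata.obs:
            ds.cluster = np.asarray(adata.obs["cluster"], dtype=object)
        if "cell_type" in adata.obs:
            ds.cell_type = np.asarray(adata.obs["cell_type"], dtype=object)
        return ds

    def save(self, path) -> None:
        self.to_anndata().write_h5ad(Path(path))

    @classmethod
    def load(cls, path) -> "CellDataset":
        import anndata as ad

        return cls.from_anndata(ad.read_h5ad(Path(path)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellDataset):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.gene_names, other.gene_names)
            and np.array_equal(self.cell_barcodes, other.cell_barcodes)
            and np.array_equal(self.condition, other.condition)
        )
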
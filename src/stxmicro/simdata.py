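"""Synthetic multi-condition scRNA-seq counts and paired bulk/proteome tables.

The generator reproduces the statistical scenario the transition analysis is
built for: cell-type heterogeneity much stronger than the condition effect
of interest, with the condition-driven expression shift planted only in a
subpopulation of one cell type in one condition.  Counts follow a negative
binomial law with log-normal per-cell library sizes; a configurable fraction
of genes is mitochondrial (``mt-`` prefixed) so the QC stage can be
exercised with the same symbol convention as real mouse data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from stxmicro.dataset import CellDataset
from stxmicro.omics import DiffTable

# fraction of (non-transition, non-mito) genes carrying each cell-type signature
_SIGNATURE_GENE_FRACTION = 0.10
_LIBRARY_SIZE_SIGMA = 0.30


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell experiment.

    Defaults describe the reference scenario used throughout the test suite:
    two cell types whose signature shifts (log-scale magnitude
    ``cell_type_effect_scale`` = 5) dominate a planted condition shift
    (``transition_effect`` = 1, natural-log scale) carried by half the cells
    of one cell type in the ``day1`` condition.
    """

    n_genes: int = 500
    n_cells_per_condition: dict = field(default_factory=lambda: {"sham": 1000, "day1": 1000})
    n_cell_types: int = 2
    cell_type_effect_scale: float = 5.0
    transition_genes: frozenset = frozenset(range(40))
    transition_effect: float = 1.0
    affected_fraction: float = 0.5
    mito_gene_fraction: float = 0.05
    nb_dispersion: float = 0.1
    library_size_mean: float = 2000.0
    seed: int = 0
    affected_condition: str | None = None  # default: second condition listed
    affected_cell_type: int = 0

    def __post_init__(self) -> None:
        self.transition_genes = frozenset(int(g) for g in self.transition_genes)
        if self.n_genes < 1 or self.n_cell_types < 1:
            raise ValueError("n_genes and n_cell_types must be >= 1")
        if not self.n_cells_per_condition or any(n < 1 for n in self.n_cells_per_condition.values()):
            raise ValueError("every condition needs at least one cell")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ValueError("mito_gene_fraction must lie in [0, 1]")
        if self.cell_type_effect_scale <= 0 or self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("cell_type_effect_scale, nb_dispersion, library_size_mean must be positive")
        if self.transition_genes and (min(self.transition_genes) < 0 or max(self.transition_genes) >= self.n_genes):
            raise ValueError("transition_genes must be indices in [0, n_genes)")
        if not self.transition_genes and self.transition_effect != 0:
            raise ValueError("transition_effect is nonzero but transition_genes is empty")
        if not 0 <= self.affected_cell_type < self.n_cell_types:
            raise ValueError("affected_cell_type out of range")
        conds = list(self.n_cells_per_condition)
        if self.affected_condition is None:
            self.affected_condition = conds[1] if len(conds) > 1 else conds[0]
        elif self.affected_condition not in conds:
            raise ValueError(f"affected_condition {self.affected_condition!r} not among conditions {conds}")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: per-cell type labels, the mask of
    cells carrying the planted shift, and the per-gene shift vector
    (natural-log scale, zero outside the transition genes)."""

    cell_type_labels: np.ndarray
    affected_cell_mask: np.ndarray
    planted_shift_vector: np.ndarray


def _gene_names(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    names = np.array(
        [f"Gene{i:04d}" for i in range(config.n_genes - n_mito)]
        + [f"mt-Sim{i:02d}" for i in range(n_mito)],
        dtype=object,
    )
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    if n_mito:
        mito_mask[-n_mito:] = True
    return names, mito_mask


def simulate_counts(config: SimConfig) -> tuple[CellDataset, SyntheticTruth]:
    """Draw one synthetic dataset; identical config + seed is bit-identical.

    Per-cell NB mean = baseline gene abundance x library size x
    exp(cell-type signature + planted shift), the shift applying only to
    affected cells on the transition genes.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_names, mito_mask = _gene_names(config)

    # baseline relative abundance (log-normal across genes), normalised so a
    # cell's expected library equals its drawn library size before shifts
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    base_p = base / base.sum()

    trans_idx = np.fromiter(sorted(config.transition_genes), dtype=int) if config.transition_genes else np.empty(0, int)
    shift_vec = np.zeros(n_genes)
    shift_vec[trans_idx] = config.transition_effect

    # sparse cell-type signatures; transition genes are eligible on purpose,
    # so the type heterogeneity sits on (a share of) the very genes carrying
    # the condition effect -- the masking scenario the analysis targets.
    # Mitochondrial genes stay signature-free to keep QC fractions stable.
    eligible = np.flatnonzero(~mito_mask)
    n_sig = max(1, int(round(_SIGNATURE_GENE_FRACTION * n_genes)))
    type_shift = np.zeros((config.n_cell_types, n_genes))
    for t in range(config.n_cell_types):
        sig_genes = rng.choice(eligible, size=min(n_sig, eligible.size), replace=False)
        mags = rng.uniform(0.5, 1.0, size=sig_genes.size) * config.cell_type_effect_scale
        signs = rng.choice([-1.0, 1.0], size=sig_genes.size)
        type_shift[t, sig_genes] = mags * signs

    conditions, barcodes, cell_types = [], [], []
    for cond, n in config.n_cells_per_condition.items():
        conditions.extend([cond] * n)
        barcodes.extend(f"{cond}-{i:05d}" for i in range(n))
        cell_types.append(rng.integers(config.n_cell_types, size=n))
    condition = np.array(conditions, dtype=object)
    cell_types = np.concatenate(cell_types)

    candidates = np.flatnonzero(
        (condition == config.affected_condition) & (cell_types == config.affected_cell_type)
    )
    n_affected = int(round(config.affected_fraction * candidates.size))
    affected = np.zeros(len(condition), dtype=bool)
    if n_affected:
        affected[rng.choice(candidates, size=n_affected, replace=False)] = True

    n_cells = len(condition)
    lib = config.library_size_mean * np.exp(
        rng.normal(0.0, _LIBRARY_SIZE_SIGMA, size=n_cells) - _LIBRARY_SIZE_SIGMA**2 / 2
    )

    log_mu = np.log(base_p)[None, :] + type_shift[cell_types]
    log_mu = log_mu + np.outer(affected.astype(float), shift_vec)
    mu = lib[:, None] * np.exp(log_mu)

    theta = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    dataset = CellDataset(
        counts=sp.csr_matrix(counts),
        gene_names=gene_names,
        cell_barcodes=np.array(barcodes, dtype=object),
        condition=condition,
    )
    truth = SyntheticTruth(
        cell_type_labels=cell_types,
        affected_cell_mask=affected,
        planted_shift_vector=shift_vec,
    )
    return dataset, truth


def simulate_paired_omics(
    n_bulk: int,
    n_prot: int,
    n_overlap: int,
    effect_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> tuple[DiffTable, DiffTable]:
    """Paired bulk-RNA and proteome differential tables with a planted overlap.

    Exactly ``n_overlap`` shared genes pass |log2FC| >= 1 and p < 0.05 in
    BOTH tables; every other gene fails at least one of the two filters in
    its own table, so the downstream filter-and-intersect step recovers
    exactly the planted set.
    """
    if min(n_bulk, n_prot, n_overlap) < 0:
        raise ValueError("table sizes must be non-negative")
    if n_overlap > min(n_bulk, n_prot):
        raise ValueError("n_overlap cannot exceed the size of either table")
    lo, hi = effect_range
    if lo < 1.0 or hi < lo:
        raise ValueError("effect_range must satisfy 1 <= lo <= hi so planted genes pass the |log2FC| >= 1 filter")
    rng = np.random.default_rng(seed)

    def passing_rows(names):
        k = len(names)
        lfc = rng.uniform(lo, hi, k) * rng.choice([-1.0, 1.0], k)
        return pd.DataFrame({"gene": names, "log2fc": lfc, "p": rng.uniform(1e-8, 0.049, k)})

    def failing_rows(names):
        k = len(names)
        lfc = np.empty(k)
        p = np.empty(k)
        # fail mode per gene: underpowered fold change, non-significant p, or both
        mode = rng.integers(3, size=k)
        small = rng.uniform(0.0, 0.99, k) * rng.choice([-1.0, 1.0], k)
        big = rng.uniform(lo, hi, k) * rng.choice([-1.0, 1.0], k)
        lfc = np.where(mode == 1, big, small)
        p = np.where(mode == 0, rng.uniform(1e-8, 0.049, k), rng.uniform(0.05, 1.0, k))
        return pd.DataFrame({"gene": names, "log2fc": lfc, "p": p})

    shared_pass = [f"Shared{i:03d}" for i in range(n_overlap)]
    # some additional genes appear in both tables but fail in at least one,
    # so the intersection is decided by the filters rather than by presence
    n_shared_fail = min(n_bulk - n_overlap, n_prot - n_overlap) // 2
    shared_fail = [f"SharedFail{i:03d}" for i in range(n_shared_fail)]
    bulk_only = [f"BulkGene{i:03d}" for i in range(n_bulk - n_overlap - n_shared_fail)]
    prot_only = [f"ProtGene{i:03d}" for i in range(n_prot - n_overlap - n_shared_fail)]

    bulk = pd.concat(
        [passing_rows(shared_pass), failing_rows(shared_fail), failing_rows(bulk_only)],
        ignore_index=True,
    )
    prot = pd.concat(
        [passing_rows(shared_pass), failing_rows(shared_fail), failing_rows(prot_only)],
        ignore_index=True,
    )
    return DiffTable(bulk, source="rna"), DiffTable(prot, source="protein")


def simulate_ppi_edges(
    genes,
    seed: int = 0,
    n_complexes: int = 2,
    complex_size: int = 5,
    background_p: float = 0.03,
    score_range: tuple[float, float] = (400.0, 999.0),
) -> pd.DataFrame:
    """STRING-style edge table over ``genes`` with planted dense complexes.

    The first ``n_complexes * complex_size`` genes form fully connected
    cliques (the planted complexes); remaining pairs connect independently
    with probability ``background_p``.  Scores are uniform in
    ``score_range``.  Returns a node1/node2/combined_score DataFrame.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    rows = []

    def score():
        return float(np.round(rng.uniform(*score_range), 0))

    clique_members = set()
    for c in range(n_complexes):
        members = genes[c * complex_size:(c + 1) * complex_size]
        clique_members.update(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rows.append((members[i], members[j], score()))
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if genes[i] in clique_members and genes[j] in clique_members:
                continue
            if rng.random() < background_p:
                rows.append((genes[i], genes[j], score()))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def simulate_gene_sets(
    universe,
    planted: dict | None = None,
    n_random: int = 10,
    set_size: int = 8,
    seed: int = 0,
):
    """Gene-set collection over ``universe`` with optional planted sets.

    ``planted`` maps set names to member lists (used verbatim); ``n_random``
    additional sets of ``set_size`` genes are drawn uniformly from the
    universe.  Returns a :class:`~stxmicro.enrichment.GeneSetCollection`.
    """
    from stxmicro.enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets = dict(planted or {})
    for i in range(n_random):
        k = min(set_size, len(universe))
        sets[f"RandomSet{i:02d}"] = list(rng.choice(universe, size=k, replace=False))
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_fixture(dataset: CellDataset, directory) -> dict:
    """Write a 10x-style MTX triplet plus conditions.tsv; returns the paths.

    The matrix is written genes x cells with 1-based MatrixMarket indices,
    matching the CellRanger export layout the reader expects.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "genes": directory / "genes.tsv",
        "barcodes": directory / "barcodes.tsv",
        "conditions": directory / "conditions.tsv",
    }
    try:
        scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.counts.T), field="integer")
        paths["genes"].write_text("".join(f"{g}\n" for g in dataset.gene_names))
        paths["barcodes"].write_text("".join(f"{b}\n" for b in dataset.cell_barcodes))
        paths["conditions"].write_text(
            "".join(f"{b}\t{c}\n" for b, c in zip(dataset.cell_barcodes, dataset.condition))
        )
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths
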
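import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stxmicro import SimConfig, simulate_counts
from stxmicro.preprocess import log_normalize

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_sim():
    """Fast 100-cell, 100-gene simulation with a planted shift."""
    cfg = SimConfig(
        n_genes=100,
        n_cells_per_condition={"sham": 50, "day1": 50},
        transition_genes=frozenset(range(10)),
        seed=42,
    )
    return cfg, *simulate_counts(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the reference configuration, log-normalised."""
    cfg = SimConfig(seed=7)
    ds, truth = simulate_counts(cfg)
    ds = log_normalize(ds)
    return cfg, ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def build_qc_boundary_dataset():
    """Dataset with cells sitting exactly on the QC decision boundaries.

    3150 genes (last 5 mitochondrial); six ballast cells keep every gene
    detected in >= 3 retained cells so the gene filter is neutral, and five
    probe cells carry 199/200/3000/3001 detected genes and 10.0%/10.1%
    mitochondrial fractions.  Returns (dataset, expected_kept_barcodes,
    expected_removed_barcodes).
    """
    import scipy.sparse as sp

    from stxmicro.dataset import CellDataset

    n_genes = 3150
    gene_names = [f"g{i:04d}" for i in range(n_genes - 5)] + [f"mt-{i}" for i in range(5)]
    half = (n_genes - 5 + 5) // 2  # 1575: ballast halves, second half includes mt genes

    rows, cols, vals = [], [], []
    barcodes, conditions = [], []

    def add_cell(name, gene_counts):
        i = len(barcodes)
        barcodes.append(name)
        conditions.append("sham")
        for g, c in gene_counts:
            rows.append(i)
            cols.append(g)
            vals.append(c)

    for b in range(3):
        add_cell(f"ballast_lo{b}", [(g, 1) for g in range(half)])
        add_cell(f"ballast_hi{b}", [(g, 1) for g in range(half, n_genes)])
    add_cell("probe_199", [(g, 1) for g in range(199)])
    add_cell("probe_200", [(g, 1) for g in range(200)])
    add_cell("probe_3000", [(g, 1) for g in range(3000)])
    add_cell("probe_3001", [(g, 1) for g in range(3001)])
    # 1000 UMIs each; mito share exactly 10.0% and 10.1%
    add_cell("probe_mito_100", [(g, 1) for g in range(900)] + [(n_genes - 5 + j, 20) for j in range(5)])
    add_cell("probe_mito_101", [(g, 1) for g in range(899)]
             + [(n_genes - 5, 21)] + [(n_genes - 4 + j, 20) for j in range(4)])

    counts = sp.csr_matrix((vals, (rows, cols)), shape=(len(barcodes), n_genes), dtype=np.int64)
    ds = CellDataset(counts, gene_names=gene_names, cell_barcodes=barcodes, condition=conditions)
    kept = {f"ballast_lo{b}" for b in range(3)} | {f"ballast_hi{b}" for b in range(3)}
    kept |= {"probe_200", "probe_3000", "probe_mito_100"}
    removed = {"probe_199", "probe_3001", "probe_mito_101"}
    return ds, kept, removed
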
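"""Configuration and single-command orchestration of the full analysis.

``run_pipeline`` executes simulate -> preprocess -> scstar -> omics ->
network -> enrichment (each stage toggleable), writing every artifact plus
a provenance manifest (config hash, global seed, per-stage derived seeds,
SHA-256 of every output).  One global seed fans out to per-stage seeds by
stable hashing so stages can be rerun independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from stxmicro import enrichment as enr
from stxmicro import network as net
from stxmicro import omics, preprocess, scstar, simdata
from stxmicro.dataset import CellDataset

log = logging.getLogger("stxmicro")

STAGES = ("simulate", "preprocess", "scstar", "omics", "network", "enrichment")


@dataclass
class OmicsOptions:
    rna_file: str | None = None
    prot_file: str | None = None
    n_bulk: int = 300
    n_prot: int = 200
    n_overlap: int = 44
    min_abs_lfc: float = 1.0
    max_p: float = 0.05


@dataclass
class EnrichmentOptions:
    gmt_file: str | None = None
    method: str = "bonferroni"
    alpha: float = 0.05
    itgb2_mode: bool = False
    extra_gene: str = "Itgb2"


@dataclass
class PipelineConfig:
    """Validated nested configuration for one pipeline run."""

    out_dir: str = "stxmicro_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    counts_dir: str | None = None
    conditions_file: str | None = None
    edges_file: str | None = None
    scstar_pairs: list = field(default_factory=list)  # e.g. [["sham", "day1"]]
    partition_gene: str | None = None
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    qc: preprocess.QCParams = field(default_factory=preprocess.QCParams)
    scstar_params: scstar.SCSTARParams = field(default_factory=scstar.SCSTARParams)
    network_params: net.NetworkParams = field(default_factory=net.NetworkParams)
    omics_options: OmicsOptions = field(default_factory=OmicsOptions)
    enrichment_options: EnrichmentOptions = field(default_factory=EnrichmentOptions)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}; valid stages are {list(STAGES)}")
        for path_attr in ("counts_dir", "conditions_file", "edges_file"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{path_attr} points to a missing path: {p}")
        gmt = self.omics_and_files().get("gmt_file")
        if gmt is not None and not Path(gmt).exists():
            raise ValueError(f"gmt_file points to a missing path: {gmt}")

    def omics_and_files(self) -> dict:
        return {"gmt_file": self.enrichment_options.gmt_file}

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived by stable hashing of (global seed, stage)."""
        return zlib.crc32(f"{self.seed}:{stage}".encode()) % (2**31)


_SECTION_TYPES = {
    "sim": simdata.SimConfig,
    "qc": preprocess.QCParams,
    "scstar_params": scstar.SCSTARParams,
    "network_params": net.NetworkParams,
    "omics_options": OmicsOptions,
    "enrichment_options": EnrichmentOptions,
}
_SCALAR_KEYS = {
    "out_dir", "seed", "stages", "counts_dir", "conditions_file",
    "edges_file", "scstar_pairs", "partition_gene",
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    An empty file yields all defaults; unknown keys (top-level or within a
    section) are rejected with the offending key named.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value or {}) - valid
            if unknown:
                raise ValueError(f"{path}: unknown key(s) {sorted(unknown)} in section {key!r}")
            section = dict(value or {})
            if key == "sim" and "transition_genes" in section:
                section["transition_genes"] = frozenset(section["transition_genes"])
            kwargs[key] = cls(**section)
        elif key in _SCALAR_KEYS:
            kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown top-level key {key!r}")
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    data = {k: enc(getattr(config, k)) for k in
            list(_SCALAR_KEYS) + list(_SECTION_TYPES)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the artifact manifest.

    A stage failure raises with the stage named; artifacts written before
    the failure remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []

    def register(stage: str, path: Path):
        artifacts.append({"stage": stage, "path": str(path),
                          "sha256": _sha256(path), "bytes": path.stat().st_size})

    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("stage %s disabled; skipping", stage)
            continue
        log.info("running stage %s (seed %d)", stage, config.stage_seed(stage))
        try:
            _RUNNERS[stage](config, out, state, register)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg_path = out / "config_resolved.yaml"
    dump_config(config, cfg_path)
    register("config", cfg_path)
    manifest = {
        "seed": config.seed,
        "config_sha256": _sha256(cfg_path),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(config, out, state, register):
    sim_cfg = dataclasses.replace(config.sim, seed=config.stage_seed("simulate"))
    dataset, truth = simdata.simulate_counts(sim_cfg)
    state["dataset"], state["truth"] = dataset, truth
    fixture_dir = out / "sim"
    paths = simdata.write_fixture(dataset, fixture_dir)
    for p in paths.values():
        register("simulate", Path(p))
    truth_path = fixture_dir / "truth.tsv"
    import pandas as pd

    pd.DataFrame({
        "barcode": dataset.cell_barcodes,
        "cell_type": truth.cell_type_labels,
        "affected": truth.affected_cell_mask,
    }).to_csv(truth_path, sep="\t", index=False)
    register("simulate", truth_path)


def _stage_preprocess(config, out, state, register):
    if config.counts_dir is not None:
        ds = preprocess.read_counts_mtx(config.counts_dir, config.conditions_file)
    elif "dataset" in state:
        ds = state["dataset"]
    else:
        raise ValueError("preprocess needs counts_dir when the simulate stage is disabled")
    ds = preprocess.qc_filter(ds, config.qc)
    ds = preprocess.log_normalize(ds, config.qc.scale_factor)
    n_hvg = min(config.qc.n_hvg, ds.n_genes)
    ds = preprocess.select_hvg(ds, n_hvg)
    n_pcs = min(config.qc.n_pcs, min(ds.n_cells, n_hvg) - 1)
    ds = preprocess.embed_pca(ds, n_pcs)
    ds = preprocess.cluster_cells(ds, config.qc.resolution, seed=config.stage_seed("preprocess"))
    try:
        ds = preprocess.annotate_clusters(ds)
        comp = preprocess.composition_table(ds)
        comp_path = out / "composition.tsv"
        comp.to_csv(comp_path, sep="\t")
        register("preprocess", comp_path)
    except ValueError as exc:
        log.warning("annotation skipped: %s", exc)
    ds_path = out / "dataset.h5ad"
    ds.save(ds_path)
    register("preprocess", ds_path)
    state["dataset"] = ds


def _stage_scstar(config, out, state, register):
    ds: CellDataset = state.get("dataset")
    if ds is None or ds.lognorm is None:
        raise ValueError("scstar requires a preprocessed dataset")
    pairs = [tuple(p) for p in config.scstar_pairs]
    if not pairs:
        conds = list(dict.fromkeys(ds.condition))
        pairs = [(conds[0], c) for c in conds[1:]]
    params = dataclasses.replace(config.scstar_params, seed=config.stage_seed("scstar"))
    state["scstar"] = {}
    import pandas as pd

    for pair in pairs:
        st = scstar.run_scstar(ds, pair, params)
        tag = f"{pair[0]}_vs_{pair[1]}"
        state["scstar"][pair] = st
        ap = out / f"scstar_{tag}_assignment.tsv"
        st.assignment.to_csv(ap, sep="\t", index=False)
        register("scstar", ap)
        tp = out / f"scstar_{tag}_transition.tsv"
        pd.DataFrame(st.transition, index=st.cells.astype(str),
                     columns=st.gene_names.astype(str)).to_csv(tp, sep="\t")
        register("scstar", tp)
        for cl, table in st.marker_genes.items():
            mp = out / f"scstar_{tag}_markers_cluster{cl}.tsv"
            table.to_csv(mp, sep="\t", index=False)
            register("scstar", mp)
    if config.partition_gene:
        st = scstar.gene_partition_run(ds, config.partition_gene, params)
        for name, tab in (("positivity", st.contingency_positivity),
                          ("condition", st.contingency_condition)):
            cp = out / f"partition_{config.partition_gene}_{name}.tsv"
            tab.to_csv(cp, sep="\t")
            register("scstar", cp)
        state["partition"] = st


def _stage_omics(config, out, state, register):
    opts = config.omics_options
    if opts.rna_file and opts.prot_file:
        rna = omics.DiffTable.read_tsv(opts.rna_file, source="rna")
        prot = omics.DiffTable.read_tsv(opts.prot_file, source="protein")
    else:
        rna, prot = simdata.simulate_paired_omics(
            opts.n_bulk, opts.n_prot, opts.n_overlap, seed=config.stage_seed("omics")
        )
    shared = omics.intersect_degs(
        omics.filter_degs(rna, opts.min_abs_lfc, opts.max_p),
        omics.filter_degs(prot, opts.min_abs_lfc, opts.max_p),
    )
    sp = out / "shared_degs.tsv"
    shared.to_csv(sp, sep="\t", index=False)
    register("omics", sp)
    state["shared_degs"] = shared


def _stage_network(config, out, state, register):
    if config.edges_file:
        edges_path = Path(config.edges_file)
    else:
        shared = state.get("shared_degs")
        if shared is None or shared.empty:
            raise ValueError("network stage needs edges_file or a non-empty omics intersection")
        edges = simdata.simulate_ppi_edges(list(shared["gene"]), seed=config.stage_seed("network"))
        edges_path = out / "edges.tsv"
        edges.to_csv(edges_path, sep="\t", index=False)
        register("network", edges_path)
    g = net.read_edge_list(edges_path, config.network_params)
    g = net.prune_isolated(g)
    if g.number_of_nodes() >= 2:
        net.centralities(g)
        hubs = net.hub_score(g)
        hp = out / "hub_scores.tsv"
        hubs.to_csv(hp, sep="\t", index=False)
        register("network", hp)
        state["hubs"] = hubs
    complexes = net.mcode_complexes(g)
    cxp = out / "mcode_complexes.tsv"
    net.write_complexes(complexes, cxp)
    register("network", cxp)
    state["graph"], state["complexes"] = g, complexes


def _stage_enrichment(config, out, state, register):
    opts = config.enrichment_options
    complexes = state.get("complexes", [])
    graph = state.get("graph")
    if opts.gmt_file:
        collection = enr.read_gmt(opts.gmt_file)
    else:
        if graph is None or graph.number_of_nodes() == 0:
            raise ValueError("enrichment needs gmt_file or an upstream network")
        universe = sorted(graph.nodes, key=str)
        planted = {f"PlantedComplexSet{i}": c["nodes"] for i, c in enumerate(complexes, 1)}
        collection = simdata.simulate_gene_sets(universe, planted=planted,
                                                seed=config.stage_seed("enrichment"))
    reports = enr.mcode_term_report(
        complexes, collection, itgb2_mode=opts.itgb2_mode,
        extra_gene=opts.extra_gene, method=opts.method, alpha=opts.alpha,
    )
    for name, table in reports.items():
        rp = out / f"enrichment_{name}.tsv"
        table.to_csv(rp, sep="\t", index=False)
        register("enrichment", rp)
    state["enrichment"] = reports


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "scstar": _stage_scstar,
    "omics": _stage_omics,
    "network": _stage_network,
    "enrichment": _stage_enrichment,
}
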
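"""PPI network topology: STRING-style edge ingestion, centralities, hub
scoring and MCODE-style dense-complex detection.

Hub importance follows the median-of-three-centralities rule: each node's
score is the median of its normalised degree, betweenness and closeness
centralities ("medium centrality" and "compactness centrality" in the
Cytoscape NetworkAnalyzer vocabulary read as betweenness and closeness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class NetworkParams:
    """``min_combined_score``: STRING combined-score cutoff on the 0-1000
    scale (400 = "medium confidence" 0.4), inclusive."""

    min_combined_score: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_combined_score <= 1000.0:
            raise ValueError("min_combined_score must lie in [0, 1000]")


_NODE1_ALIASES = ("node1", "#node1", "protein1", "item_id_a", "source")
_NODE2_ALIASES = ("node2", "protein2", "item_id_b", "target")
_SCORE_ALIASES = ("combined_score", "score", "weight")


def read_edge_list(path, params: NetworkParams | None = None) -> nx.Graph:
    """Build an undirected PPI graph from a STRING-export TSV.

    Edges below ``min_combined_score`` are dropped; duplicate pairs (either
    orientation) collapse keeping the maximum score; self-loops are ignored.
    Files without a recognised header are read as node1/node2/score columns.
    """
    params = params or NetworkParams()
    from pathlib import Path

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    g = nx.Graph()
    if not lines:
        warnings.warn(f"{path}: empty edge file; returning empty graph")
        return g

    header = [c.strip().lower() for c in lines[0].split("\t")]

    def _find(aliases):
        for a in aliases:
            if a in header:
                return header.index(a)
        return None

    i1, i2, isc = _find(_NODE1_ALIASES), _find(_NODE2_ALIASES), _find(_SCORE_ALIASES)
    if i1 is not None and i2 is not None and isc is not None:
        body = lines[1:]
    else:
        i1, i2, isc = 0, 1, 2
        body = lines

    for lineno, line in enumerate(body, start=2 if body is not lines else 1):
        parts = line.split("\t")
        try:
            u, v = parts[i1].strip(), parts[i2].strip()
            score = float(parts[isc])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
        if u == v:
            continue
        if score < params.min_combined_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], score)
        else:
            g.add_edge(u, v, combined_score=score)
    return g


def prune_isolated(g: nx.Graph) -> nx.Graph:
    """Remove degree-zero nodes; edges are untouched."""
    out = g.copy()
    out.remove_nodes_from([n for n, d in g.degree() if d == 0])
    return out


def centralities(g: nx.Graph) -> nx.Graph:
    """Annotate nodes with normalised degree, betweenness and closeness.

    degree_c = deg/(N-1); betweenness is pair-normalised; closeness uses the
    Wasserman-Faust component correction.  All three lie in [0, 1].
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("centralities need at least 2 nodes")
    deg = nx.degree_centrality(g)
    bet = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=True)
    for node in g.nodes:
        g.nodes[node]["degree_c"] = deg[node]
        g.nodes[node]["betweenness_c"] = bet[node]
        g.nodes[node]["closeness_c"] = clo[node]
    return g


def hub_score(g: nx.Graph) -> pd.DataFrame:
    """Rank genes by the median of the three normalised centralities.

    Ties in score break alphabetically; returns a table with the three
    centralities, the hub score and the 1-based rank, and stores
    ``hub_score`` on each node.
    """
    if not g.nodes or "degree_c" not in g.nodes[next(iter(g.nodes))]:
        g = centralities(g)
    rows = []
    for node, data in g.nodes(data=True):
        score = float(np.median([data["degree_c"], data["betweenness_c"], data["closeness_c"]]))
        g.nodes[node]["hub_score"] = score
        rows.append({"gene": node, "degree_c": data["degree_c"],
                     "betweenness_c": data["betweenness_c"], "closeness_c": data["closeness_c"],
                     "hub_score": score})
    table = pd.DataFrame(rows).sort_values(
        by=["hub_score", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# MCODE-style complexes
# ---------------------------------------------------------------------------

def _density(sub: nx.Graph) -> float:
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def _node_weights(g: nx.Graph, degree_cutoff: int) -> dict:
    """MCODE vertex weighting: core number k of the closed neighbourhood's
    highest k-core times that core's density; low-degree nodes score 0."""
    weights = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph(list(g.neighbors(v)) + [v])
        core_num = nx.core_number(closed)
        k = max(core_num.values())
        kcore = closed.subgraph([u for u, c in core_num.items() if c >= k])
        weights[v] = k * _density(kcore)
    return weights


def mcode_complexes(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
) -> list[dict]:
    """Detect dense complexes by seeded greedy expansion over k-core weights.

    Seeds are unclaimed local weight maxima taken in descending weight
    order; expansion admits neighbours whose weight is within
    ``node_score_cutoff`` of the seed's.  Each candidate is reduced to the
    connected ``k_core``-core containing its seed, guaranteeing minimum
    internal degree >= ``k_core``; complexes are vertex-disjoint (greedy
    claim by rank) and returned sorted by density x size, then size, then
    lexicographically smallest member.
    """
    weights = _node_weights(g, degree_cutoff)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    claimed: set = set()
    complexes = []
    for seed in order:
        if seed in claimed or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in g.neighbors(v):
                if u in members or u in claimed:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append(u)
        sub = g.subgraph(members)
        core = nx.k_core(sub, k=k_core)
        if core.number_of_nodes() == 0:
            continue
        if seed in core:
            component = nx.node_connected_component(core, seed)
        else:
            component = max(nx.connected_components(core), key=lambda c: (len(c), sorted(map(str, c))))
        final = g.subgraph(component)
        claimed |= set(component)
        complexes.append({
            "nodes": sorted(component, key=str),
            "n_nodes": final.number_of_nodes(),
            "n_edges": final.number_of_edges(),
            "density": _density(final),
            "score": _density(final) * final.number_of_nodes(),
            "seed": seed,
        })
    complexes.sort(key=lambda c: (-c["score"], -c["n_nodes"], c["nodes"]))
    return complexes


def write_node_table(g: nx.Graph, path) -> None:
    hub_score(g).to_csv(path, sep="\t", index=False)


def write_complexes(complexes: list[dict], path) -> None:
    rows = []
    for i, c in enumerate(complexes, start=1):
        for node in c["nodes"]:
            rows.append({"complex": f"MCODE-{i}", "gene": node,
                         "score": c["score"], "density": c["density"], "size": c["n_nodes"]})
    pd.DataFrame(rows, columns=["complex", "gene", "score", "density", "size"]).to_csv(
        path, sep="\t", index=False
    )
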
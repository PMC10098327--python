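"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exact rational arithmetic,
exhaustive enumeration, pure-python graph walks — and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# hypergeometric tail by exact enumeration
# ---------------------------------------------------------------------------

def hypergeom_sf_exact(x: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(max(x, 0), min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def hypergeom_tail_table(N: int, K: int, n: int) -> list[Fraction]:
    """[P(X >= x) for x in 0..min(K, n) + 1] via one pmf enumeration."""
    total = comb(N, n)
    upper = min(K, n)
    pmf = [Fraction(comb(K, i) * comb(N - K, n - i), total) for i in range(upper + 1)]
    tails = []
    running = Fraction(0)
    for i in range(upper, -1, -1):
        running += pmf[i]
        tails.append(running)
    tails.reverse()
    tails.append(Fraction(0))  # P(X >= upper + 1)
    return tails


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum two-sided p by exhaustive permutation
# ---------------------------------------------------------------------------

def wilcoxon_perm_p(group_a, group_b) -> Fraction:
    """Two-sided permutation p-value of the Mann-Whitney U statistic.

    Enumerates every split of the pooled values into groups of the observed
    sizes; p = fraction of splits whose U deviates from its null mean at
    least as much as the observed one.
    """
    pooled = list(group_a) + list(group_b)
    n1, n2 = len(group_a), len(group_b)
    mu = Fraction(n1 * n2, 2)

    def u_stat(a_vals, b_vals):
        # count of (a, b) pairs with a > b, ties counted half
        u = Fraction(0)
        for a in a_vals:
            for b in b_vals:
                if a > b:
                    u += 1
                elif a == b:
                    u += Fraction(1, 2)
        return u

    obs_dev = abs(u_stat(group_a, group_b) - mu)
    idx = range(len(pooled))
    hits = total = 0
    for a_idx in itertools.combinations(idx, n1):
        a_set = set(a_idx)
        a_vals = [pooled[i] for i in a_idx]
        b_vals = [pooled[i] for i in idx if i not in a_set]
        total += 1
        if abs(u_stat(a_vals, b_vals) - mu) >= obs_dev:
            hits += 1
    return Fraction(hits, total)


# ---------------------------------------------------------------------------
# graph centralities by pure-python path enumeration
# ---------------------------------------------------------------------------

def _bfs_distances(adj: dict, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for v in frontier:
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def _shortest_paths(adj: dict, s, t, dist_st: int):
    """All shortest s-t paths, by depth-bounded DFS."""
    paths = []

    def dfs(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        if len(path) - 1 >= dist_st:
            return
        for u in adj[v]:
            if u not in path:
                path.append(u)
                dfs(path)
                path.pop()

    dfs([s])
    return paths


def brute_centralities(nodes, edges) -> dict:
    """degree / betweenness / closeness (Wasserman-Faust) for every node.

    Normalisations match the standard conventions: degree/(N-1),
    pair-normalised betweenness, component-corrected closeness.
    """
    nodes = list(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    result = {v: {} for v in nodes}
    for v in nodes:
        result[v]["degree_c"] = len(adj[v]) / (n - 1)

    # betweenness: enumerate all shortest paths per pair
    bet = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = _bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = _shortest_paths(adj, s, t, dist[t])
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += Fraction(through, len(paths))
    norm = Fraction((n - 1) * (n - 2), 2)
    for v in nodes:
        result[v]["betweenness_c"] = float(bet[v] / norm) if norm else 0.0

    for v in nodes:
        dist = _bfs_distances(adj, v)
        r = len(dist)  # reachable including v
        totsp = sum(dist.values())
        if totsp > 0 and n > 1:
            result[v]["closeness_c"] = ((r - 1) / totsp) * ((r - 1) / (n - 1))
        else:
            result[v]["closeness_c"] = 0.0
    return result


def brute_k_core(nodes, edges, k: int) -> set:
    """Node set of the k-core by iterated removal of low-degree nodes."""
    nodes = set(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u in nodes and v in nodes:
            adj[u].add(v)
            adj[v].add(u)
    changed = True
    while changed:
        changed = False
        for v in list(nodes):
            if len(adj[v] & nodes) < k:
                nodes.discard(v)
                changed = True
    return nodes


def enumerate_graphs(n: int):
    """Yield every labeled simple graph on nodes 0..n-1 as an edge list."""
    possible = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(possible)):
        yield [e for i, e in enumerate(possible) if bits >> i & 1]
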
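"""Local over-representation analysis against GMT gene-set collections.

Replaces web-service enrichment with a one-sided hypergeometric test per
gene set plus Bonferroni or Benjamini-Hochberg multiple-testing correction,
run against user-supplied collections (GO/KEGG/Reactome-like) and an
explicit background universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def _norm(g: str) -> str:
    return str(g).strip().lower()


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and a background universe.

    The universe defaults to the union of all set members; gene matching is
    case-insensitive.
    """

    sets: dict
    descriptions: dict = field(default_factory=dict)
    universe: set | None = None

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            members = {_norm(g) for g in genes}
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean
        if self.universe is None:
            self.universe = set().union(*self.sets.values())
        else:
            self.universe = {_norm(g) for g in self.universe}
            # harmonise: sets restricted to the declared universe
            self.sets = {n: s & self.universe for n, s in self.sets.items()}
            self.sets = {n: s for n, s in self.sets.items() if s}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene...)."""
    sets: dict = {}
    descriptions: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g.strip()]
        sets[name] = genes  # duplicates collapse in the set constructor
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p).  ``bh``: Benjamini-Hochberg step-up with
    monotonicity enforcement.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        if p.size == 0:
            return p.copy()
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError("method must be 'bonferroni' or 'bh'")


def ora_hypergeometric(
    query,
    collection: GeneSetCollection,
    universe=None,
    method: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    For a set with K members out of a universe of N genes and a query of n
    genes overlapping it in k, p = P(X >= k), X ~ Hypergeometric(N, K, n).
    Query genes outside the universe are dropped with a warning; rows are
    ranked by p then set name.
    """
    uni = collection.universe if universe is None else {_norm(g) for g in universe}
    q_raw = [_norm(g) for g in query]
    q = sorted(set(q_raw) & uni)
    dropped = set(q_raw) - uni
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe dropped")
    if not q:
        raise ValueError("query is empty after harmonization with the universe")
    N, n = len(uni), len(q)
    qset = set(q)
    rows = []
    for name, members in collection.sets.items():
        members = members & uni
        if not members:
            continue
        K = len(members)
        overlap = sorted(qset & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "description": collection.descriptions.get(name, ""),
                     "k": k, "n": n, "K": K, "N": N, "p": p,
                     "overlap_genes": ",".join(overlap)})
    result = pd.DataFrame(rows)
    result["p_adj"] = adjust_pvalues(result["p"].to_numpy(), method=method)
    result["significant"] = result["p_adj"] < alpha
    return result.sort_values(["p", "set"]).reset_index(drop=True)


def mcode_term_report(
    complexes,
    collection: GeneSetCollection,
    universe=None,
    itgb2_mode: bool = False,
    extra_gene: str = "Itgb2",
    method: str = "bh",
    alpha: float = 0.05,
    top: int = 3,
) -> dict:
    """Top enriched terms per MCODE complex, optionally adding one gene of
    interest (Itgb2 by default) to every query.

    Returns ``{complex id: DataFrame}`` where each table is the full ORA
    result annotated with an ``in_top`` flag on the ``top`` best terms by
    p-value; complexes with no gene in the universe are skipped with a
    warning.
    """
    reports = {}
    for i, cpx in enumerate(complexes, start=1):
        name = f"MCODE-{i}"
        query = list(cpx["nodes"]) if isinstance(cpx, dict) else list(cpx)
        if itgb2_mode and _norm(extra_gene) not in {_norm(g) for g in query}:
            query = query + [extra_gene]
        try:
            res = ora_hypergeometric(query, collection, universe=universe,
                                     method=method, alpha=alpha)
        except ValueError:
            warnings.warn(f"{name}: no gene in the universe; skipped")
            continue
        res["in_top"] = np.arange(len(res)) < top
        reports[name] = res
    return reports


def write_enrichment_report(result: pd.DataFrame, path, top: int = 20) -> None:
    """Markdown report of the top enriched terms for one query."""
    lines = ["| set | k/K | p | adjusted p | significant |", "|---|---|---|---|---|"]
    for _, row in result.head(top).iterrows():
        lines.append(
            f"| {row['set']} | {row['k']}/{row['K']} | {row['p']:.3g} | "
            f"{row['p_adj']:.3g} | {'yes' if row['significant'] else 'no'} |"
        )
    Path(path).write_text("\n".join(lines) + "\n")
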
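"""Cross-condition cell state-transition analysis via dual PLS.

Cells from two biological conditions are matched into real-virtual pairs:
a pair of partial-least-squares regression models (one per direction) maps
each cell's expression profile into the opposite condition's space, and the
difference between the virtual counterpart and the real profile is that
cell's state transition.  Because both members of a pair share everything
except the condition, variation unrelated to the intervention (dominant
cell-type heterogeneity in particular) cancels, leaving the
condition-driven shift.  Transition profiles are then graph-clustered, and
each transition cluster is assigned to the condition(s) over-represented in
it by a one-sided hypergeometric test; clusters with no significant
condition are called "stable".

The published description of the method leaves the real-virtual pairing
construction unstated; here each cell is paired with the mean profile of
its k nearest opposite-condition neighbours in a joint PCA embedding (the
central documented gap-filling choice; k equal to the full group size
recovers a mutual-centroid pairing for sensitivity checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stxmicro._graphcluster import snn_leiden
from stxmicro.dataset import CellDataset
from stxmicro.preprocess import fix_component_signs

STABLE_LABEL = "stable"


@dataclass
class SCSTARParams:
    """Tunable parameters of the transition analysis.

    ``n_components``: PLS latent components (capped at min(n_cells, n_genes) - 1).
    ``pairing_k``: opposite-condition neighbours averaged into the
    pseudo-partner.  A generous neighbourhood matters: averaging regresses
    the partner toward the local state mean, cancelling the bias that
    nearest-neighbour selection would otherwise introduce along the
    condition-shift direction.
    ``gene_filter_min_cv``: multiple of the mean-CV trend a gene must exceed
    to survive adaptive filtering (0 keeps every non-constant gene).
    ``assign_alpha``: hypergeometric significance level for cluster-condition
    assignment.
    ``cluster_resolution``: Leiden resolution for transition clustering; the
    default is coarser than typical expression clustering because transition
    space holds few dynamic states and the stable cells form one diffuse
    near-zero cloud that should stay a single community.
    """

    n_components: int = 10
    pairing_k: int = 20
    gene_filter_min_cv: float = 1.0
    assign_alpha: float = 0.05
    cluster_resolution: float = 0.3
    n_pairing_pcs: int = 30
    pairing_refinements: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0.0 < self.assign_alpha < 1.0:
            raise ValueError("assign_alpha must lie in (0, 1)")
        if self.pairing_k < 1:
            raise ValueError("pairing_k must be >= 1")


@dataclass
class StateTransitionSet:
    """Per-cell real-virtual difference profiles for two condition groups.

    ``transition`` has one row per cell of both groups, expressed in the
    A -> B direction (rows of B cells are sign-harmonised).
    """

    cells: np.ndarray
    transition: np.ndarray
    gene_names: np.ndarray
    condition_of_origin: np.ndarray
    group_of_origin: np.ndarray
    transition_cluster: np.ndarray | None = None
    embedding: np.ndarray | None = None
    assignment: pd.DataFrame | None = None
    cluster_labels: dict = field(default_factory=dict)
    marker_genes: dict = field(default_factory=dict)
    contingency_positivity: pd.DataFrame | None = None
    contingency_condition: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return self.transition.shape[0]


@dataclass
class PseudoPairs:
    """k-NN pseudo-pairing of one group's cells with opposite-group profiles."""

    x: np.ndarray            # real profiles (n_cells x genes)
    y: np.ndarray            # pseudo-partner profiles in the other condition
    neighbor_idx: np.ndarray  # (n_cells x k) indices into the other group


@dataclass
class DualPLSModel:
    """Two directed PLS regression operators between condition spaces."""

    a_to_b: object
    b_to_a: object
    n_components: int
    explained_covariance_ab: np.ndarray
    explained_covariance_ba: np.ndarray
    centroid_error_ab: float
    centroid_error_ba: float
    n_genes: int


# ---------------------------------------------------------------------------
# adaptive gene filtering
# ---------------------------------------------------------------------------

def filter_genes_adaptive(lognorm: np.ndarray, params: SCSTARParams | None = None,
                          n_bins: int = 20) -> np.ndarray:
    """Keep genes whose coefficient of variation exceeds the mean-CV trend.

    The baseline approximates the technical-noise CV floor at a given mean
    expression: the lower-quartile CV within mean-quantile bins.  A gene
    survives when CV > ``gene_filter_min_cv`` x baseline(mean), i.e. when it
    carries variance in excess of the noise floor for its expression level.
    With a threshold of 0 every non-constant gene survives; constant genes
    never do.  This is a transparent substitute for adaptive noise-model
    gene filters used in the single-cell literature.
    """
    params = params or SCSTARParams()
    mean = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.maximum(mean, 1e-12), 0.0)
    n_genes = lognorm.shape[1]

    expressed = mean > 0
    baseline = np.zeros(n_genes)
    if expressed.any():
        m = mean[expressed]
        edges = np.unique(np.quantile(m, np.linspace(0, 1, max(2, min(n_bins, expressed.sum()) + 1))))
        if len(edges) > 1:
            bins = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2)
        else:
            bins = np.zeros(n_genes, int)
        for b in np.unique(bins[expressed]):
            sel = expressed & (bins == b)
            baseline[sel] = np.quantile(cv[sel], 0.25)
    mask = cv > params.gene_filter_min_cv * baseline
    mask &= sd > 0
    if not mask.any():
        raise ValueError("adaptive gene filter removed every gene; relax gene_filter_min_cv")
    return mask


# ---------------------------------------------------------------------------
# pseudo-pairing and dual PLS
# ---------------------------------------------------------------------------

def _joint_pca(A: np.ndarray, B: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.decomposition import PCA

    X = np.vstack([A, B])
    q = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if q < 1:
        return A.copy(), B.copy()
    pca = PCA(n_components=q, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    _, scores = fix_component_signs(pca.components_, scores)
    return scores[: A.shape[0]], scores[A.shape[0]:]


def build_pseudo_pairs(group_a: np.ndarray, group_b: np.ndarray, pairing_k: int = 5,
                       n_pairing_pcs: int = 30,
                       match_query: np.ndarray | None = None) -> PseudoPairs:
    """Pair each A cell with the mean of its k nearest B cells.

    Neighbours are found in a joint PCA embedding of both groups in the
    shared gene space, so matching is driven by the dominant structure
    (cell types and states) -- the working assumption of the whole
    analysis is that this heterogeneity is large relative to the condition
    effect.  Partner profiles are averaged in the original gene space.
    ``match_query`` optionally replaces the A-side coordinates used for
    neighbour search (e.g. first-pass virtual counterparts during pairing
    refinement) while partner profiles still come from ``group_b``.  Use
    the symmetric call with swapped arguments for the B -> A pairing.
    """
    from sklearn.neighbors import NearestNeighbors

    if group_a.shape[0] == 0 or group_b.shape[0] == 0:
        raise ValueError("both condition groups must be non-empty")
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups must share one gene space")
    k = pairing_k
    if k > group_b.shape[0]:
        warnings.warn(f"pairing_k={pairing_k} exceeds group size {group_b.shape[0]}; capping")
        k = group_b.shape[0]
    query = group_a if match_query is None else match_query
    emb_a, emb_b = _joint_pca(query, group_b, n_pairing_pcs)
    nn = NearestNeighbors(n_neighbors=k).fit(emb_b)
    _, idx = nn.kneighbors(emb_a)
    partners = group_b[idx].mean(axis=1)
    return PseudoPairs(x=group_a, y=partners, neighbor_idx=idx)


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int):
    from sklearn.cross_decomposition import PLSRegression

    cap = min(n_components, X.shape[0] - 1, X.shape[1])
    if cap < n_components:
        warnings.warn(f"reducing PLS components from {n_components} to {cap} (rank limit)")
    cap = max(cap, 1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        model = PLSRegression(n_components=cap, scale=False).fit(X, Y)
    # covariance captured per latent component (diagnostic only)
    cov = np.abs(np.einsum("ij,ij->j", model.x_scores_, model.y_scores_)) / max(X.shape[0] - 1, 1)
    return model, cov


def fit_dual_pls(pairs_ab: PseudoPairs, pairs_ba: PseudoPairs,
                 params: SCSTARParams | None = None) -> DualPLSModel:
    """Fit the two directed PLS regressions on the pseudo-pairs."""
    params = params or SCSTARParams()
    model_ab, cov_ab = _fit_pls(pairs_ab.x, pairs_ab.y, params.n_components)
    model_ba, cov_ba = _fit_pls(pairs_ba.x, pairs_ba.y, params.n_components)
    cen_ab = float(np.max(np.abs(
        model_ab.predict(pairs_ab.x.mean(axis=0, keepdims=True)) - pairs_ab.y.mean(axis=0)
    )))
    cen_ba = float(np.max(np.abs(
        model_ba.predict(pairs_ba.x.mean(axis=0, keepdims=True)) - pairs_ba.y.mean(axis=0)
    )))
    return DualPLSModel(
        a_to_b=model_ab,
        b_to_a=model_ba,
        n_components=int(model_ab.n_components),
        explained_covariance_ab=cov_ab,
        explained_covariance_ba=cov_ba,
        centroid_error_ab=cen_ab,
        centroid_error_ba=cen_ba,
        n_genes=pairs_ab.x.shape[1],
    )


def project_virtual(profiles: np.ndarray, model: DualPLSModel, direction: str = "a_to_b") -> np.ndarray:
    """Predict the virtual counterpart profile(s) in the opposite condition."""
    profiles = np.atleast_2d(profiles)
    if profiles.shape[1] != model.n_genes:
        raise ValueError(
            f"profile has {profiles.shape[1]} genes but the model was fitted on {model.n_genes}"
        )
    if direction == "a_to_b":
        return model.a_to_b.predict(profiles)
    if direction == "b_to_a":
        return model.b_to_a.predict(profiles)
    raise ValueError("direction must be 'a_to_b' or 'b_to_a'")


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------

def state_transition_matrix(
    group_a: np.ndarray,
    group_b: np.ndarray,
    params: SCSTARParams | None = None,
    gene_names=None,
    barcodes_a=None,
    barcodes_b=None,
    conditions_a="A",
    conditions_b="B",
) -> StateTransitionSet:
    """Per-cell transition profiles (virtual - real) in the A -> B direction.

    A cells are projected A -> B; B cells B -> A with the sign flipped so
    every row expresses the same direction of change.  ``conditions_*`` may
    be scalars or per-cell arrays (the latter when group membership does not
    coincide with the biological condition, as in marker-gene partitions).

    Pairing is refined once by default: after a first fit, each cell's
    predicted counterpart (its virtual profile) replaces the raw profile
    when searching for opposite-group neighbours, removing the selection
    bias that raw nearest-neighbour matching introduces along the
    condition-shift direction.
    """
    params = params or SCSTARParams()
    n_a, n_b = group_a.shape[0], group_b.shape[0]
    pairs_ab = build_pseudo_pairs(group_a, group_b, params.pairing_k, params.n_pairing_pcs)
    pairs_ba = build_pseudo_pairs(group_b, group_a, params.pairing_k, params.n_pairing_pcs)
    model = fit_dual_pls(pairs_ab, pairs_ba, params)
    virtual_a = project_virtual(group_a, model, "a_to_b")
    virtual_b = project_virtual(group_b, model, "b_to_a")

    for _ in range(max(0, params.pairing_refinements)):
        pairs_ab = build_pseudo_pairs(group_a, group_b, params.pairing_k,
                                      params.n_pairing_pcs, match_query=virtual_a)
        pairs_ba = build_pseudo_pairs(group_b, group_a, params.pairing_k,
                                      params.n_pairing_pcs, match_query=virtual_b)
        model = fit_dual_pls(pairs_ab, pairs_ba, params)
        virtual_a = project_virtual(group_a, model, "a_to_b")
        virtual_b = project_virtual(group_b, model, "b_to_a")

    trans_a = virtual_a - group_a          # A cell moved into B space
    trans_b = group_b - virtual_b          # sign-harmonised to A -> B

    def _labels(spec, n, default_prefix):
        if spec is None:
            return np.array([f"{default_prefix}{i}" for i in range(n)], dtype=object)
        return np.asarray(spec, dtype=object)

    def _conds(spec, n):
        if np.ndim(spec) == 0:
            return np.full(n, spec, dtype=object)
        return np.asarray(spec, dtype=object)

    st = StateTransitionSet(
        cells=np.concatenate([_labels(barcodes_a, n_a, "A-"), _labels(barcodes_b, n_b, "B-")]),
        transition=np.vstack([trans_a, trans_b]),
        gene_names=np.asarray(gene_names if gene_names is not None
                              else [f"g{i}" for i in range(group_a.shape[1])], dtype=object),
        condition_of_origin=np.concatenate([_conds(conditions_a, n_a), _conds(conditions_b, n_b)]),
        group_of_origin=np.array(["A"] * n_a + ["B"] * n_b, dtype=object),
    )
    st.model = model
    return st


# ---------------------------------------------------------------------------
# clustering, assignment, markers
# ---------------------------------------------------------------------------

def _pca_embed(X: np.ndarray, n_pcs: int = 30) -> np.ndarray:
    from sklearn.decomposition import PCA

    q = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if q < 1:
        return X - X.mean(axis=0)
    pca = PCA(n_components=q, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    _, scores = fix_component_signs(pca.components_, scores)
    return scores


def cluster_transitions(st: StateTransitionSet, resolution: float | None = None,
                        seed: int | None = None,
                        params: SCSTARParams | None = None) -> StateTransitionSet:
    """Graph-cluster the transition profiles (PCA embedding + SNN Leiden)."""
    params = params or SCSTARParams()
    resolution = params.cluster_resolution if resolution is None else resolution
    seed = params.seed if seed is None else seed
    st.embedding = _pca_embed(st.transition)
    st.transition_cluster = snn_leiden(st.embedding, resolution=resolution, seed=seed)
    return st


def hypergeom_sf(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def assign_clusters_to_conditions(st: StateTransitionSet, alpha: float = 0.05) -> StateTransitionSet:
    """One-sided hypergeometric over-representation of each condition in each
    transition cluster; clusters with no condition at p < alpha are "stable"."""
    if st.transition_cluster is None:
        raise ValueError("run cluster_transitions first")
    N = st.n_cells
    rows = []
    labels: dict[str, object] = {}
    clusters = sorted(set(st.transition_cluster), key=str)
    conds = sorted(set(st.condition_of_origin), key=str)
    for cl in clusters:
        in_cl = st.transition_cluster == cl
        n = int(in_cl.sum())
        assigned = []
        for c in conds:
            of_c = st.condition_of_origin == c
            K = int(of_c.sum())
            x = int((in_cl & of_c).sum())
            p = hypergeom_sf(x, N, K, n)
            hit = p < alpha
            if hit:
                assigned.append((c, p))
            rows.append({"cluster": cl, "condition": c, "x": x, "n": n, "K": K, "N": N,
                         "p": p, "assigned": hit})
        labels[cl] = {c: p for c, p in assigned} if assigned else STABLE_LABEL
    st.assignment = pd.DataFrame(rows)
    st.cluster_labels = labels
    return st


def _wilcoxon_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    both = np.concatenate([a, b])
    if np.all(both == both[0]):
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(min(res.pvalue, 1.0))


def find_cluster_markers(obj, cluster, alpha: float = 0.05) -> pd.DataFrame:
    """Marker genes of one cluster vs all other cells.

    Two-sided Wilcoxon rank-sum per gene on the log-normalised (or
    transition) values, Bonferroni-corrected over the genes tested;
    significance = adjusted p < ``alpha``.  Ranked by |effect| (mean
    difference) descending, then p, then gene name.
    """
    if isinstance(obj, StateTransitionSet):
        X, labels, genes = obj.transition, obj.transition_cluster, obj.gene_names
    elif isinstance(obj, CellDataset):
        X, labels, genes = obj.lognorm, obj.cluster, obj.gene_names
    else:
        raise TypeError("expected a StateTransitionSet or CellDataset")
    if X is None or labels is None:
        raise ValueError("values and cluster labels must be present")
    in_cl = labels == cluster
    if in_cl.sum() < 2:
        raise ValueError(f"cluster {cluster!r} has fewer than 2 cells")
    if (~in_cl).sum() < 1:
        raise ValueError("no cells outside the cluster to compare against")

    m = X.shape[1]
    pvals = np.empty(m)
    effects = np.empty(m)
    for g in range(m):
        a, b = X[in_cl, g], X[~in_cl, g]
        pvals[g] = _wilcoxon_two_sided(a, b)
        effects[g] = a.mean() - b.mean()
    adj = np.minimum(pvals * m, 1.0)
    table = pd.DataFrame({
        "gene": genes, "effect": effects, "p": pvals, "p_adj": adj,
        "significant": adj < alpha,
    })
    table = table.sort_values(
        by=["effect", "p", "gene"], key=lambda s: -s.abs() if s.name == "effect" else s,
    ).reset_index(drop=True)
    return table


def all_cluster_markers(st: StateTransitionSet, alpha: float = 0.05) -> dict:
    """Marker table for every transition cluster (size >= 2)."""
    out = {}
    for cl in sorted(set(st.transition_cluster), key=str):
        in_cl = st.transition_cluster == cl
        if in_cl.sum() >= 2 and (~in_cl).sum() >= 1:
            out[cl] = find_cluster_markers(st, cl, alpha=alpha)
    st.marker_genes = out
    return out


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def run_scstar(dataset: CellDataset, condition_pair: tuple[str, str],
               params: SCSTARParams | None = None) -> StateTransitionSet:
    """Full transition analysis between two conditions of a normalised dataset.

    Adaptive gene filtering -> pseudo-pairing -> dual PLS -> transition
    matrix -> transition clustering -> hypergeometric condition assignment
    -> per-cluster markers.
    """
    params = params or SCSTARParams()
    if dataset.lognorm is None:
        raise ValueError("dataset must be log-normalised")
    cond_a, cond_b = condition_pair
    sel = np.isin(dataset.condition, [cond_a, cond_b])
    if not sel.any():
        raise ValueError(f"no cells in conditions {condition_pair}")
    sub = dataset.subset(cell_idx=np.flatnonzero(sel))
    gene_mask = filter_genes_adaptive(sub.lognorm, params)
    X = sub.lognorm[:, gene_mask]
    a_idx = np.flatnonzero(sub.condition == cond_a)
    b_idx = np.flatnonzero(sub.condition == cond_b)
    st = state_transition_matrix(
        X[a_idx], X[b_idx], params,
        gene_names=sub.gene_names[gene_mask],
        barcodes_a=sub.cell_barcodes[a_idx],
        barcodes_b=sub.cell_barcodes[b_idx],
        conditions_a=cond_a,
        conditions_b=cond_b,
    )
    st.gene_mask = gene_mask
    st.cell_index = np.concatenate([np.flatnonzero(sel)[a_idx], np.flatnonzero(sel)[b_idx]])
    cluster_transitions(st, params=params)
    assign_clusters_to_conditions(st, alpha=params.assign_alpha)
    all_cluster_markers(st)
    return st


def gene_partition_run(dataset: CellDataset, gene: str,
                       params: SCSTARParams | None = None) -> StateTransitionSet:
    """Transition analysis with groups defined by expression of one gene.

    Cells with a raw count > 0 for ``gene`` form the positive group; the
    negative -> positive direction is analysed.  The returned set carries
    cluster x positivity and cluster x condition contingency tables
    (chord-diagram inputs) alongside the usual condition assignment.
    """
    params = params or SCSTARParams()
    if dataset.lognorm is None:
        raise ValueError("dataset must be log-normalised")
    gi = dataset.gene_index(gene)  # raises KeyError when absent
    positive = np.asarray(dataset.counts[:, gi].todense()).ravel() > 0
    if not positive.any():
        raise ValueError(f"gene {gene!r} is expressed in zero cells")
    if positive.all():
        raise ValueError(f"gene {gene!r} is expressed in every cell; no negative group")

    gene_mask = filter_genes_adaptive(dataset.lognorm, params)
    X = dataset.lognorm[:, gene_mask]
    neg_idx = np.flatnonzero(~positive)
    pos_idx = np.flatnonzero(positive)
    st = state_transition_matrix(
        X[neg_idx], X[pos_idx], params,
        gene_names=dataset.gene_names[gene_mask],
        barcodes_a=dataset.cell_barcodes[neg_idx],
        barcodes_b=dataset.cell_barcodes[pos_idx],
        conditions_a=dataset.condition[neg_idx],
        conditions_b=dataset.condition[pos_idx],
    )
    st.positivity = np.array([f"{gene}-"] * len(neg_idx) + [f"{gene}+"] * len(pos_idx), dtype=object)
    cluster_transitions(st, params=params)
    assign_clusters_to_conditions(st, alpha=params.assign_alpha)
    st.contingency_positivity = pd.crosstab(
        pd.Series(st.transition_cluster, name="cluster"), pd.Series(st.positivity, name="positivity")
    )
    st.contingency_condition = pd.crosstab(
        pd.Series(st.transition_cluster, name="cluster"),
        pd.Series(st.condition_of_origin, name="condition"),
    )
    return st
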
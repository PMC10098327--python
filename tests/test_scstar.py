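"""Dual-PLS state-transition analysis: pairing, projection, clustering,
hypergeometric assignment and marker detection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.metrics import adjusted_rand_score

import oracles
from stxmicro import SimConfig, simulate_counts
from stxmicro.preprocess import log_normalize
from stxmicro.scstar import (
    STABLE_LABEL,
    SCSTARParams,
    StateTransitionSet,
    assign_clusters_to_conditions,
    build_pseudo_pairs,
    cluster_transitions,
    filter_genes_adaptive,
    find_cluster_markers,
    fit_dual_pls,
    gene_partition_run,
    hypergeom_sf,
    project_virtual,
    run_scstar,
    state_transition_matrix,
)


class TestAdaptiveGeneFilter:
    def test_constant_genes_always_removed(self, rng):
        X = rng.uniform(0, 2, size=(50, 5))
        X[:, 2] = 1.5
        mask = filter_genes_adaptive(X, SCSTARParams(gene_filter_min_cv=0.0))
        assert not mask[2]

    def test_zero_threshold_keeps_all_nonconstant(self, rng):
        X = rng.uniform(0.1, 2, size=(40, 6))
        mask = filter_genes_adaptive(X, SCSTARParams(gene_filter_min_cv=0.0))
        assert mask.all()

    def test_planted_genes_retained(self):
        """Planted high-variance transition genes survive the filter in
        >= 95% of cases over 20 simulation seeds."""
        kept = total = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes=300,
                            n_cells_per_condition={"sham": 300, "day1": 300},
                            transition_genes=frozenset(range(30)))
            ds, truth = simulate_counts(cfg)
            ds = log_normalize(ds)
            mask = filter_genes_adaptive(ds.lognorm)
            planted = truth.planted_shift_vector > 0
            kept += mask[planted].sum()
            total += planted.sum()
        assert kept / total >= 0.95

    def test_all_filtered_raises(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="relax"):
            filter_genes_adaptive(X)


class TestPseudoPairs:
    def test_translated_copy_pairs_counterparts(self, rng):
        # cells well separated relative to the translation
        A = rng.normal(size=(25, 6)) * 20
        B = A + 3.0
        pairs = build_pseudo_pairs(A, B, pairing_k=1)
        assert np.array_equal(pairs.neighbor_idx.ravel(), np.arange(25))
        np.testing.assert_allclose(pairs.y, B, atol=1e-12)

    def test_identical_groups_pair_self(self, rng):
        A = rng.normal(size=(20, 4)) * 3
        pairs = build_pseudo_pairs(A, A, pairing_k=1)
        np.testing.assert_allclose(pairs.y, A, atol=1e-12)

    def test_full_k_gives_centroid(self, rng):
        A = rng.normal(size=(10, 3))
        B = rng.normal(size=(8, 3))
        pairs = build_pseudo_pairs(A, B, pairing_k=8)
        np.testing.assert_allclose(pairs.y, np.tile(B.mean(0), (10, 1)), atol=1e-12)

    def test_oversized_k_capped_with_warning(self, rng):
        A, B = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        with pytest.warns(UserWarning, match="capping"):
            pairs = build_pseudo_pairs(A, B, pairing_k=10)
        assert pairs.neighbor_idx.shape[1] == 4


class TestDualPLS:
    def test_identity_limit(self, rng):
        A = rng.normal(size=(30, 6))
        pab = build_pseudo_pairs(A, A, 1)
        model = fit_dual_pls(pab, pab, SCSTARParams(n_components=6))
        np.testing.assert_allclose(project_virtual(A, model), A, atol=1e-6)

    def test_constant_shift_recovered(self, rng):
        # cells well separated relative to the shift, so k=1 pairing is exact
        A = rng.normal(size=(40, 5)) * 20
        delta = np.array([2.0, -1.0, 0.5, 0.0, 3.0])
        B = A + delta
        model = fit_dual_pls(build_pseudo_pairs(A, B, 1), build_pseudo_pairs(B, A, 1),
                             SCSTARParams(n_components=5))
        np.testing.assert_allclose(project_virtual(A, model), B, atol=1e-6)
        np.testing.assert_allclose(project_virtual(B, model, "b_to_a"), A, atol=1e-6)

    def test_centroid_maps_to_centroid(self, rng):
        A = rng.normal(size=(30, 4))
        B = rng.normal(size=(30, 4)) + 1.0
        model = fit_dual_pls(build_pseudo_pairs(A, B, 3), build_pseudo_pairs(B, A, 3),
                             SCSTARParams(n_components=4))
        assert model.centroid_error_ab < 1e-8
        assert model.centroid_error_ba < 1e-8

    def test_single_component_matches_ols_on_latent_score(self, rng):
        # rank-1 paired data: X and Y driven by one latent factor
        t = rng.normal(size=(50,))
        X = np.outer(t, [1.0, 2.0, 0.5])
        Y = np.outer(3.0 * t, [0.5, 1.0, 1.5])
        from stxmicro.scstar import PseudoPairs

        pairs = PseudoPairs(x=X, y=Y, neighbor_idx=np.zeros((50, 1), int))
        model = fit_dual_pls(pairs, pairs, SCSTARParams(n_components=1))
        pred = project_virtual(X, model)
        # OLS oracle on the latent score
        beta = np.linalg.lstsq(t[:, None], Y, rcond=None)[0]
        np.testing.assert_allclose(pred, t[:, None] @ beta, atol=1e-8)

    def test_gene_space_mismatch_rejected(self, rng):
        A = rng.normal(size=(20, 4))
        model = fit_dual_pls(build_pseudo_pairs(A, A, 1), build_pseudo_pairs(A, A, 1),
                             SCSTARParams(n_components=3))
        with pytest.raises(ValueError, match="genes"):
            project_virtual(rng.normal(size=(2, 5)), model)


class TestStateTransitionMatrix:
    def test_identical_groups_transition_near_zero(self, rng):
        A = rng.normal(size=(40, 6)) * 2
        st = state_transition_matrix(A, A.copy(), SCSTARParams(n_components=6, pairing_k=1))
        assert np.abs(st.transition).max() < 1e-5

    def test_shift_only_scenario_recovers_delta(self, rng):
        A = rng.normal(size=(60, 5)) * 4
        delta = np.array([1.0, 0.0, -2.0, 0.5, 0.0])
        st = state_transition_matrix(A, A + delta, SCSTARParams(n_components=5, pairing_k=1))
        np.testing.assert_allclose(st.transition, np.tile(delta, (120, 1)), atol=0.05 * 2)

    def test_affected_cells_have_larger_transition_norms(self, default_sim):
        cfg, ds, truth = default_sim
        st = run_scstar(ds, ("sham", "day1"), SCSTARParams(seed=0))
        mask = truth.affected_cell_mask[st.cell_index]
        norms = np.linalg.norm(st.transition, axis=1)
        p = mannwhitneyu(norms[mask], norms[~mask], alternative="greater").pvalue
        assert p < 0.01

    def test_planted_shift_recovery(self, default_sim):
        cfg, ds, truth = default_sim
        st = run_scstar(ds, ("sham", "day1"), SCSTARParams(seed=0))
        mask = truth.affected_cell_mask[st.cell_index]
        r = pearsonr(st.transition[mask].mean(axis=0),
                     truth.planted_shift_vector[st.gene_mask])[0]
        assert r >= 0.9
        assert adjusted_rand_score(mask, st.transition_cluster) >= 0.8


class TestClusterTransitions:
    def test_seed_determinism(self, rng):
        X = rng.normal(size=(80, 5))
        st = StateTransitionSet(cells=np.arange(80).astype(object), transition=X,
                                gene_names=np.arange(5).astype(object),
                                condition_of_origin=np.array(["A"] * 40 + ["B"] * 40, dtype=object),
                                group_of_origin=np.array(["A"] * 40 + ["B"] * 40, dtype=object))
        a = cluster_transitions(st, resolution=1.0, seed=3).transition_cluster.copy()
        b = cluster_transitions(st, resolution=1.0, seed=3).transition_cluster
        assert np.array_equal(a, b)

    def test_identical_groups_yield_no_assignment(self, rng):
        A = rng.normal(size=(60, 8)) * 2
        st = state_transition_matrix(A, A.copy(), SCSTARParams(n_components=8, pairing_k=1))
        cluster_transitions(st, params=SCSTARParams())
        assign_clusters_to_conditions(st)
        assert all(v == STABLE_LABEL for v in st.cluster_labels.values())


def _fake_st(cluster_labels, conditions):
    n = len(cluster_labels)
    st = StateTransitionSet(
        cells=np.arange(n).astype(object),
        transition=np.zeros((n, 2)),
        gene_names=np.array(["g0", "g1"], dtype=object),
        condition_of_origin=np.asarray(conditions, dtype=object),
        group_of_origin=np.asarray(conditions, dtype=object),
    )
    st.transition_cluster = np.asarray(cluster_labels, dtype=object)
    return st


class TestHypergeometricAssignment:
    def test_worked_half_case(self):
        # N=10, K=5, n=5, x=3 -> p = 126/252 = 0.5
        st = _fake_st(["k"] * 5 + ["other"] * 5,
                      ["c"] * 3 + ["d"] * 2 + ["c"] * 2 + ["d"] * 3)
        assign_clusters_to_conditions(st, alpha=0.05)
        row = st.assignment.query("cluster == 'k' and condition == 'c'").iloc[0]
        assert row["p"] == pytest.approx(0.5, abs=1e-12)
        assert (row["x"], row["n"], row["K"], row["N"]) == (3, 5, 5, 10)

    def test_pure_cluster_extreme(self):
        # x = n = K: p = 1/C(N, n)
        st = _fake_st(["k"] * 4 + ["o"] * 6, ["c"] * 4 + ["d"] * 6)
        assign_clusters_to_conditions(st)
        row = st.assignment.query("cluster == 'k' and condition == 'c'").iloc[0]
        from math import comb

        assert row["p"] == pytest.approx(1 / comb(10, 4), abs=1e-15)

    def test_zero_overlap_never_assigned(self):
        st = _fake_st(["k"] * 3 + ["o"] * 7, ["d"] * 3 + ["c"] * 7)
        assign_clusters_to_conditions(st)
        row = st.assignment.query("cluster == 'k' and condition == 'c'").iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert not row["assigned"]

    def test_matches_exact_enumeration_small_sweep(self):
        for N, K, n in [(8, 3, 4), (12, 6, 5), (20, 9, 7), (30, 15, 10)]:
            tails = oracles.hypergeom_tail_table(N, K, n)
            for x in range(min(K, n) + 2):
                assert hypergeom_sf(x, N, K, n) == pytest.approx(float(tails[x]), abs=1e-12)


class TestClusterMarkers:
    def _one_gene_st(self, values, in_cluster):
        n = len(values)
        st = StateTransitionSet(
            cells=np.arange(n).astype(object),
            transition=np.asarray(values, dtype=float)[:, None],
            gene_names=np.array(["g"], dtype=object),
            condition_of_origin=np.array(["A"] * n, dtype=object),
            group_of_origin=np.array(["A"] * n, dtype=object),
        )
        st.transition_cluster = np.array(
            ["in" if f else "out" for f in in_cluster], dtype=object)
        return st

    def test_exact_p_against_permutation_oracle(self):
        st = self._one_gene_st([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        table = find_cluster_markers(st, "in")
        expected = oracles.wilcoxon_perm_p([5, 6, 7], [1, 2, 3])
        assert float(expected) == pytest.approx(0.1)
        assert table["p"][0] == pytest.approx(0.1, abs=1e-12)

    def test_bonferroni_over_genes_tested(self, rng):
        n = 12
        X = rng.normal(size=(n, 10))
        st = StateTransitionSet(
            cells=np.arange(n).astype(object), transition=X,
            gene_names=np.array([f"g{i}" for i in range(10)], dtype=object),
            condition_of_origin=np.array(["A"] * n, dtype=object),
            group_of_origin=np.array(["A"] * n, dtype=object))
        st.transition_cluster = np.array(["in"] * 6 + ["out"] * 6, dtype=object)
        table = find_cluster_markers(st, "in")
        np.testing.assert_allclose(table["p_adj"], np.minimum(table["p"] * 10, 1.0))

    def test_constant_gene_p_one(self):
        st = self._one_gene_st([2.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        table = find_cluster_markers(st, "in")
        assert table["p"][0] == 1.0 and not table["significant"][0]

    def test_small_cluster_rejected(self):
        st = self._one_gene_st([1, 2, 3], [1, 0, 0])
        with pytest.raises(ValueError, match="fewer than 2"):
            find_cluster_markers(st, "in")


class TestGenePartition:
    def test_absent_gene_rejected(self, default_sim):
        _, ds, _ = default_sim
        with pytest.raises(KeyError):
            gene_partition_run(ds, "NotAGene")

    def test_partition_recovers_affected_cells(self):
        """A marker expressed in the planted-affected cells plus a matched
        share of baseline cells partitions the data so that the transition
        cluster associated with (positive, shifted-condition) cells is the
        affected population.  Positives must span both conditions -- if the
        positive group consists solely of shifted cells, every cross-group
        pair differs by the same shift and the transition profiles are one
        uniform state with no cluster/positivity association."""
        cfg = SimConfig(seed=4, n_genes=300, n_cell_types=1,
                        n_cells_per_condition={"sham": 300, "day1": 300},
                        transition_genes=frozenset(range(30)))
        ds, truth = simulate_counts(cfg)
        # marker expressed in the affected cells and in an equal number of
        # (unshifted) sham cells
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        positive = truth.affected_cell_mask.copy()
        sham_idx = np.flatnonzero(ds.condition == "sham")
        positive[rng.choice(sham_idx, size=int(positive.sum()), replace=False)] = True
        marker = positive.astype(np.int64)[:, None] * 5
        counts = sp.hstack([ds.counts, sp.csr_matrix(marker)]).tocsr()
        from stxmicro.dataset import CellDataset

        ds2 = CellDataset(counts, gene_names=list(ds.gene_names) + ["Itgb2"],
                          cell_barcodes=ds.cell_barcodes, condition=ds.condition)
        ds2 = log_normalize(ds2)
        st = gene_partition_run(ds2, "Itgb2", SCSTARParams(seed=4))
        order = {b: i for i, b in enumerate(ds2.cell_barcodes)}
        mask = truth.affected_cell_mask[[order[b] for b in st.cells]]
        assert adjusted_rand_score(mask, st.transition_cluster) >= 0.8
        # contingency bookkeeping: row sums equal cluster sizes
        sizes = pd.Series(st.transition_cluster).value_counts()
        for cl, row in st.contingency_positivity.iterrows():
            assert row.sum() == sizes[cl]

    def test_never_expressed_gene_rejected(self, rng):
        import scipy.sparse as sp

        from stxmicro.dataset import CellDataset

        counts = rng.poisson(2.0, size=(30, 5)).astype(np.int64)
        counts[:, 4] = 0
        ds = CellDataset(sp.csr_matrix(counts),
                         gene_names=["a", "b", "c", "d", "silent"],
                         cell_barcodes=[f"c{i}" for i in range(30)],
                         condition=["sham"] * 15 + ["day1"] * 15)
        ds = log_normalize(ds)
        with pytest.raises(ValueError, match="zero cells"):
            gene_partition_run(ds, "silent")


class TestMaskingRobustness:
    def test_transition_analysis_beats_naive_wilcoxon(self):
        """With cell-type heterogeneity 5x the condition effect and realistic
        counting noise, per-gene Wilcoxon between whole conditions loses
        planted genes that the transition route (cluster first, then test)
        still finds."""
        from stxmicro.enrichment import adjust_pvalues

        naive_recalls, transition_recalls = [], []
        for seed in (0, 1, 2):
            cfg = SimConfig(seed=seed, nb_dispersion=0.5)
            ds, truth = simulate_counts(cfg)
            ds = log_normalize(ds)
            planted = truth.planted_shift_vector > 0
            n_planted = planted.sum()

            d1 = ds.condition == "day1"
            p_naive = np.array([
                mannwhitneyu(ds.lognorm[d1, g], ds.lognorm[~d1, g]).pvalue
                for g in range(ds.n_genes)
            ])
            sig_naive = adjust_pvalues(p_naive, "bh") < 0.05
            naive_recalls.append((sig_naive & planted).sum() / n_planted)

            st = run_scstar(ds, ("sham", "day1"), SCSTARParams(seed=seed))
            day1_cl = [cl for cl, lab in st.cluster_labels.items()
                       if lab != STABLE_LABEL and "day1" in lab]
            recall = 0.0
            if day1_cl:
                in_cl = np.isin(st.transition_cluster, day1_cl)
                p_tr = np.array([
                    mannwhitneyu(st.transition[in_cl, g], st.transition[~in_cl, g]).pvalue
                    for g in range(st.transition.shape[1])
                ])
                sig = adjust_pvalues(p_tr, "bh") < 0.05
                pset = set(ds.gene_names[planted])
                recall = sum(1 for g, s in zip(st.gene_names, sig) if s and g in pset) / n_planted
            transition_recalls.append(recall)
        assert np.mean(transition_recalls) > np.mean(naive_recalls)
        assert np.mean(transition_recalls) >= 0.8
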
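import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from germmap.io import CellSet, Embedding
from germmap.otlineage import (
    LineageGraph,
    OTParams,
    TransportMap,
    ancestor_contributions,
    assign_times,
    build_lineage_graph,
    cluster_cells,
    compute_transport_map,
    contribution_matrix,
    detect_communities,
    reconstruct_lineages,
    sparsify,
    transport_chain,
)


def lp_transport_cost(C, a, b):
    """Exact linear-programming optimum of the balanced transport cost."""
    n, m = C.shape
    A_eq = []
    for i in range(n):
        r = np.zeros((n, m))
        r[i, :] = 1
        A_eq.append(r.ravel())
    for j in range(m):
        r = np.zeros((n, m))
        r[:, j] = 1
        A_eq.append(r.ravel())
    res = linprog(
        C.ravel(),
        A_eq=np.array(A_eq),
        b_eq=np.concatenate([a, b]),
        bounds=(0, None),
        method="highs",
    )
    assert res.status == 0
    return res.fun


class TestAssignTimes:
    def _cells(self, samples, time_h):
        n = len(samples)
        meta = pd.DataFrame({"sample": samples, "time_h": time_h})
        return CellSet(
            np.ones((n, 2), dtype=int),
            [f"c{i}" for i in range(n)],
            ["g0", "g1"],
            meta=meta,
        )

    def test_sample_convention_offsets(self):
        cells = self._cells(["PSC", "PreME", "EB", "EB"], [np.nan, np.nan, 12.0, 48.0])
        times, unique = assign_times(cells, mode="offset")
        np.testing.assert_array_equal(times, [0.0, 12.0, 24.0, 60.0])
        np.testing.assert_array_equal(unique, [0.0, 12.0, 24.0, 60.0])

    def test_absolute_mode_identity(self):
        cells = self._cells(["a", "b"], [5.0, 3.0])
        times, unique = assign_times(cells, mode="absolute")
        np.testing.assert_array_equal(times, [5.0, 3.0])
        np.testing.assert_array_equal(unique, [3.0, 5.0])

    def test_unresolvable_time_errors(self):
        cells = self._cells(["EB"], [np.nan])
        with pytest.raises(ValueError, match="resolvable"):
            assign_times(cells, mode="offset")


class TestComputeTransportMap:
    def test_product_coupling_limit_at_large_epsilon(self):
        src = np.array([[0.0], [1.0]])
        tgt = np.array([[0.0], [1.0]])
        params = OTParams(balanced=True, epsilon=1e4, cost_normalisation="none")
        tm = compute_transport_map(src, tgt, params)
        np.testing.assert_allclose(tm.gamma, 0.25, atol=1e-3)

    def test_identity_cost_concentrates_on_diagonal(self):
        # embed so the squared-Euclidean cost is [[0, 1], [1, 0]]
        src = np.array([[0.0], [1.0]])
        tgt = np.array([[0.0], [1.0]])
        params = OTParams(balanced=True, epsilon=0.01, cost_normalisation="none")
        tm = compute_transport_map(src, tgt, params)
        np.testing.assert_allclose(np.diag(tm.gamma), 0.5, atol=1e-3)
        assert tm.gamma[0, 1] < 1e-3 and tm.gamma[1, 0] < 1e-3

    def test_balanced_marginals_and_lp_cost_on_random_instances(self, rng):
        for _ in range(3):
            src = rng.normal(size=(20, 5))
            tgt = rng.normal(size=(20, 5))
            C = cdist(src, tgt, "sqeuclidean")
            C = C / np.median(C)
            a = np.full(20, 1 / 20)
            b = np.full(20, 1 / 20)
            eps = 1e-3 * np.median(C)
            params = OTParams(
                balanced=True, epsilon=eps, cost_normalisation="none", max_iter=30000
            )
            tm = compute_transport_map(src, tgt, params)
            cost = float((tm.gamma * C).sum())
            assert cost <= 1.01 * lp_transport_cost(C, a, b) + 1e-12
        # marginal convergence to 1e-8 at a moderate epsilon
        params = OTParams(balanced=True, epsilon=0.05, max_iter=30000)
        tm = compute_transport_map(src, tgt, params)
        assert tm.converged
        assert tm.marginal_violation < 1e-8

    def test_balanced_limit_of_unbalanced_solver_conserves_mass(self, rng):
        src = rng.normal(size=(15, 4))
        tgt = rng.normal(size=(15, 4))
        params = OTParams(lambda1=1e6, lambda2=1e6, epsilon=0.05)
        tm = compute_transport_map(src, tgt, params)
        assert tm.gamma.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.abs(tm.gamma.sum(axis=1) - tm.source_marginal).max() < 1e-6
        assert np.abs(tm.gamma.sum(axis=0) - tm.target_marginal).max() < 1e-6

    def test_relaxation_weights_shape_marginal_violations(self, rng):
        """lambda2 >> lambda1 keeps the target marginal much tighter than
        the source marginal."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            src = r.normal(size=(30, 5))
            tgt = r.normal(size=(25, 5)) + 0.3
            tm = compute_transport_map(src, tgt, OTParams())
            src_viol = np.abs(tm.gamma.sum(axis=1) - tm.source_marginal).sum()
            tgt_viol = np.abs(tm.gamma.sum(axis=0) - tm.target_marginal).sum()
            assert tgt_viol < src_viol

    def test_nonconvergence_reported_not_silent(self, rng):
        src = rng.normal(size=(10, 3))
        tgt = rng.normal(size=(10, 3))
        params = OTParams(balanced=True, epsilon=0.001, max_iter=20)
        tm = compute_transport_map(src, tgt, params)
        assert tm.converged is False

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_transport_map(np.zeros((0, 2)), np.ones((3, 2)))


class TestAncestorContributions:
    def _balanced_map(self, rng, n, m):
        src = rng.normal(size=(n, 3))
        tgt = rng.normal(size=(m, 3))
        params = OTParams(balanced=True, epsilon=0.5)
        return compute_transport_map(src, tgt, params)

    def test_full_target_returns_source_marginal(self, rng):
        tm = self._balanced_map(rng, 8, 8)
        (mass,) = ancestor_contributions([tm], np.ones(8))
        np.testing.assert_allclose(mass, tm.gamma.sum(axis=1), atol=1e-12)

    def test_empty_target_gives_zero_mass(self, rng):
        maps = [self._balanced_map(rng, 6, 5), self._balanced_map(rng, 5, 7)]
        masses = ancestor_contributions(maps, np.zeros(7))
        for m in masses:
            np.testing.assert_array_equal(m, 0.0)

    def test_two_step_chain_matches_rownormalised_product_oracle(self, rng):
        g1 = self._balanced_map(rng, 6, 5)
        g2 = self._balanced_map(rng, 5, 7)
        s = np.zeros(7)
        s[[1, 3]] = 1.0
        masses = ancestor_contributions([g1, g2], s)
        P2 = g2.gamma / g2.gamma.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(masses[0], g1.gamma @ (P2 @ s), atol=1e-12)
        np.testing.assert_allclose(masses[1], g2.gamma @ s, atol=1e-12)

    def test_mass_conserved_through_balanced_chain(self, rng):
        g1 = self._balanced_map(rng, 10, 10)
        g2 = self._balanced_map(rng, 10, 10)
        s = np.zeros(10)
        s[:4] = 1.0
        masses = ancestor_contributions([g1, g2], s)
        target_mass = float(g2.gamma.sum(axis=0) @ s)
        for m in masses:
            assert m.sum() == pytest.approx(target_mass, abs=1e-6)

    def test_chain_gap_errors(self, rng):
        g1 = self._balanced_map(rng, 6, 5)
        g2 = self._balanced_map(rng, 4, 7)
        with pytest.raises(ValueError, match="gap"):
            ancestor_contributions([g1, g2], np.ones(7))


def _map_from_gamma(gamma):
    gamma = np.asarray(gamma, float)
    return TransportMap(
        gamma=gamma,
        source_marginal=gamma.sum(axis=1),
        target_marginal=gamma.sum(axis=0),
        converged=True,
        marginal_violation=0.0,
        n_iter=0,
    )


class TestContributionMatrix:
    def test_single_cluster_chain_all_ones(self):
        maps = [_map_from_gamma(np.full((2, 2), 0.25))]
        clusters = np.array(["c"] * 4)
        times = np.array([0.0, 0.0, 1.0, 1.0])
        g = contribution_matrix(maps, clusters, times)
        assert g.A.loc["c@0", "c@1"] == 1.0

    def test_permutation_transport_gives_permutation_matrix(self):
        # block-diagonal mass: cluster a -> y, cluster b -> x
        gamma = np.zeros((2, 2))
        gamma[0, 1] = 0.5  # cell of a -> cell of y
        gamma[1, 0] = 0.5  # cell of b -> cell of x
        maps = [_map_from_gamma(gamma)]
        clusters = np.array(["a", "b", "x", "y"])
        times = np.array([0.0, 0.0, 1.0, 1.0])
        for norm in ("source", "target"):
            g = contribution_matrix(maps, clusters, times, normalisation=norm)
            block = g.A.loc[["a@0", "b@0"], ["x@1", "y@1"]].to_numpy()
            np.testing.assert_array_equal(block, [[0, 1], [1, 0]])

    def test_source_mode_rows_sum_to_one(self, rng):
        gamma = rng.uniform(0.01, 1.0, size=(6, 8))
        maps = [_map_from_gamma(gamma)]
        clusters = np.array(["a"] * 3 + ["b"] * 3 + ["x"] * 4 + ["y"] * 4)
        times = np.array([0.0] * 6 + [1.0] * 8)
        g = contribution_matrix(maps, clusters, times, normalisation="source")
        for src in ("a@0", "b@0"):
            assert g.A.loc[src].sum() == pytest.approx(1.0, abs=1e-8)

    def test_target_mode_columns_sum_to_one(self, rng):
        gamma = rng.uniform(0.01, 1.0, size=(6, 8))
        maps = [_map_from_gamma(gamma)]
        clusters = np.array(["a"] * 3 + ["b"] * 3 + ["x"] * 4 + ["y"] * 4)
        times = np.array([0.0] * 6 + [1.0] * 8)
        g = contribution_matrix(maps, clusters, times, normalisation="target")
        for tgt in ("x@1", "y@1"):
            assert g.A[tgt].sum() == pytest.approx(1.0, abs=1e-8)


class TestSparsify:
    def _A(self, values):
        names = [f"n{i}" for i in range(len(values))]
        return pd.DataFrame(np.diag(values), index=names, columns=names)

    def test_power_censor_arithmetic(self):
        A = self._A([1.0, 0.95, 0.90])
        out = sparsify(A, P=30, censor=0.1)
        assert out.iloc[0, 0] == 1.0
        assert out.iloc[1, 1] == pytest.approx(0.95**30)
        assert 0.95**30 == pytest.approx(0.2146, abs=5e-4)
        assert out.iloc[2, 2] == 0.0
        assert 0.90**30 == pytest.approx(0.0424, abs=5e-4)

    def test_masked_mode_keeps_original_values(self):
        A = self._A([0.95, 0.90])
        out = sparsify(A, P=30, censor=0.1, mode="masked")
        assert out.iloc[0, 0] == 0.95
        assert out.iloc[1, 1] == 0.0

    def test_never_creates_mass_and_preserves_zeros(self, rng):
        vals = rng.uniform(0, 1, size=(7, 7))
        vals[rng.uniform(size=(7, 7)) < 0.3] = 0.0
        names = [f"n{i}" for i in range(7)]
        A = pd.DataFrame(vals, index=names, columns=names)
        out = sparsify(A, P=30, censor=0.1)
        assert np.all(out.to_numpy() <= vals**30 + 1e-15)
        assert np.all(out.to_numpy()[vals == 0] == 0.0)


class TestBuildLineageGraph:
    def _graph(self, M, k):
        names = [f"n{i}" for i in range(M.shape[0])]
        nodes = [(f"n{i}", 0) for i in range(M.shape[0])]
        g = LineageGraph(nodes=nodes, A=pd.DataFrame(M, index=names, columns=names))
        g.A_sparse = g.A
        return build_lineage_graph(g, k_graph=k)

    def test_fewer_nonzero_than_k_keeps_all(self):
        M = np.zeros((3, 3))
        M[0, 1] = 0.4
        M[0, 2] = 0.2
        g = self._graph(M, k=5)
        assert len([e for e in g.edges if e[0] == ("n0", 0)]) == 2

    def test_top_k_selection(self, rng):
        M = np.zeros((8, 8))
        M[0, 1:] = rng.uniform(0.1, 1.0, size=7)
        g = self._graph(M, k=5)
        kept = {e[1][0] for e in g.edges if e[0] == ("n0", 0)}
        expect = {f"n{j}" for j in (np.argsort(-M[0])[:5])}
        assert kept == expect

    def test_matches_brute_force_topk(self, rng):
        M = rng.uniform(0, 1, size=(10, 10))
        M[M < 0.4] = 0.0
        np.fill_diagonal(M, 0.0)
        g = self._graph(M, k=3)
        for i in range(10):
            kept = sorted(
                (e[1][0], e[2]) for e in g.edges if e[0] == (f"n{i}", 0)
            )
            nz = np.flatnonzero(M[i])
            top = nz[np.argsort(-M[i, nz], kind="stable")][:3]
            expect = sorted((f"n{j}", M[i, j]) for j in top)
            assert kept == expect


class TestDetectCommunities:
    def _graph_from_edges(self, n, edges):
        nodes = [(f"n{i}", 0) for i in range(n)]
        g = LineageGraph(
            nodes=nodes,
            A=pd.DataFrame(np.zeros((n, n))),
            edges=[((f"n{a}", 0), (f"n{b}", 0), w) for a, b, w in edges],
        )
        return detect_communities(g)

    def test_disconnected_triangles_two_communities(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0),
                 (3, 4, 1.0), (4, 5, 1.0), (5, 3, 1.0)]
        g = self._graph_from_edges(6, edges)
        c = g.communities
        assert len({c[(f"n{i}", 0)] for i in range(6)}) == 2
        assert c[("n0", 0)] == c[("n1", 0)] == c[("n2", 0)]
        assert c[("n3", 0)] == c[("n4", 0)] == c[("n5", 0)]

    def test_uniform_complete_graph_single_community(self):
        edges = [(a, b, 1.0) for a in range(5) for b in range(5) if a < b]
        g = self._graph_from_edges(5, edges)
        assert len(set(g.communities.values())) == 1

    def test_isolated_nodes_become_singletons(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)]
        g = self._graph_from_edges(5, edges)
        c = g.communities
        assert c[("n3", 0)] != c[("n4", 0)]
        assert c[("n3", 0)] != c[("n0", 0)]

    def test_planted_two_block_graph_recovered_exactly(self):
        edges = []
        for block in (0, 1):
            base = 10 * block
            for a in range(10):
                for b in range(a + 1, 10):
                    edges.append((base + a, base + b, 1.0))
        edges.append((0, 10, 0.01))
        g = self._graph_from_edges(20, edges)
        c = g.communities
        first = {c[(f"n{i}", 0)] for i in range(10)}
        second = {c[(f"n{i}", 0)] for i in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second


class TestEndToEndLineageRecovery:
    def test_small_timecourse_recovers_planted_tree(self, small_timecourse):
        """Reduced-scale pipeline run: planted edges recovered, no spurious
        cross-lineage edges, most cells back-annotated consistently."""
        _, cells, emb, tree = small_timecourse
        markers = {
            f"gene{g:04d}": lin
            for lin, genes in tree.marker_genes.items()
            for g in genes
        }
        graph, labels, maps = reconstruct_lineages(cells, emb, markers)
        assert all(m.converged for m in maps)
        edge_set = {(s, d) for s, d, _ in graph.edges}
        planted = set(tree.edges)
        assert planted <= edge_set
        extra = edge_set - planted
        assert not extra
        ok = np.mean(
            [
                labels.iloc[i] in tree.descendants_or_self(cells.meta["cluster"].iloc[i])
                for i in range(cells.n_cells)
            ]
        )
        assert ok >= 0.90

    def test_annotation_tie_yields_unresolved(self, small_timecourse):
        from germmap.otlineage import annotate_metaclusters

        _, cells, emb, tree = small_timecourse
        sub = cells.subset_cells(np.arange(40))
        times = np.zeros(40)
        graph = LineageGraph(
            nodes=[("Epi", 0)],
            A=pd.DataFrame(np.zeros((1, 1)), index=["Epi@0"], columns=["Epi@0"]),
        )
        graph.communities = {("Epi", 0): 0}
        # the same gene for two lineages forces an exact score tie
        markers = {"gene0000": "A", "gene0001": "B"}
        sub.counts[:, 0] = sub.counts[:, 1]  # identical marker columns
        graph, labels = annotate_metaclusters(sub, graph, markers, times)
        assert graph.annotations[0] == "UNRESOLVED"
        assert set(graph.annotation_candidates[0]) == {"A", "B"}


def test_cluster_cells_plumbing_separates_blobs(rng):
    coords = np.vstack([rng.normal(size=(40, 4)), rng.normal(size=(40, 4)) + 15])
    emb = Embedding(coords, [f"c{i}" for i in range(80)], "s")
    membership = cluster_cells(emb, resolution=0.5, n_neighbors=10)
    assert len(set(membership[:40])) == 1
    assert len(set(membership[40:])) == 1
    assert membership[0] != membership[-1]


def test_transport_chain_growth_iterations_shrink_source_violation(rng):
    """Re-feeding the fitted source marginal reduces how much the couplings
    distort the source distribution."""
    coords = np.vstack([rng.normal(size=(60, 4)), rng.normal(size=(80, 4)) + 1.0])
    emb = Embedding(coords, [f"c{i}" for i in range(140)], "s")
    times = np.array([0.0] * 60 + [1.0] * 80)
    maps1, _, _ = transport_chain(emb, times, growth_iters=1)
    maps3, _, _ = transport_chain(emb, times, growth_iters=3)
    v1 = np.abs(maps1[0].gamma.sum(axis=1) - maps1[0].source_marginal).sum()
    v3 = np.abs(maps3[0].gamma.sum(axis=1) - maps3[0].source_marginal).sum()
    assert v3 < v1
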
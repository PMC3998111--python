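"""Binary matrix, uncentered-correlation average linkage, threshold cuts."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from respnet.core import NetworkError
from respnet.matrix import (
    BinaryMatrix,
    average_linkage,
    build_binary_matrix,
    clustered_node_curve,
    cut_at_similarity,
    detect_inflections,
    export_cdt_gtr,
    similarity_matrix,
    uncentered_correlation,
)
from conftest import gene_graph, make_network


def _bm(rows, ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    ids = ids or [f"n{i}" for i in range(rows.shape[0])]
    return BinaryMatrix(list(ids), rows)


class TestBinaryMatrix:
    def test_triangle_has_six_off_diagonal_ones(self):
        net = gene_graph([("a", "b"), ("b", "c"), ("a", "c")])
        bm = build_binary_matrix(net)
        assert bm.values.sum() == 6
        assert np.all(np.diag(bm.values) == 0)
        assert np.array_equal(bm.values, bm.values.T)

    def test_self_loop_sets_diagonal(self):
        net = gene_graph([("a", "a"), ("a", "b")])
        bm = build_binary_matrix(net)
        i = bm.ids.index("a")
        assert bm.values[i, i] == 1

    def test_row_sums_equal_degrees(self, whole_net):
        bm = build_binary_matrix(whole_net)
        for idx, node in enumerate(bm.ids):
            assert bm.values[idx].sum() == len(whole_net.neighbor_set(node))

    def test_isolated_nodes_excluded_by_default(self):
        net = gene_graph([("a", "b")], extra_nodes=["z"])
        assert "z" not in build_binary_matrix(net).ids
        assert "z" in build_binary_matrix(net, include_isolated=True).ids

    def test_empty_network_error(self):
        from respnet.core import InteractionNetwork

        with pytest.raises(NetworkError):
            build_binary_matrix(InteractionNetwork())


class TestUncenteredCorrelation:
    def test_identical_nonzero_vectors(self):
        assert uncentered_correlation([1, 1, 0], [1, 1, 0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert uncentered_correlation([1, 0], [0, 1]) == 0.0

    def test_hand_arithmetic(self):
        assert uncentered_correlation([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_defined_zero(self):
        assert uncentered_correlation([0, 0], [1, 1]) == 0.0

    def test_length_mismatch_error(self):
        with pytest.raises(NetworkError):
            uncentered_correlation([1, 0], [1, 0, 1])

    def test_self_similarity_one_unless_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = (rng.random(8) < 0.4).astype(float)
            expected = 0.0 if not v.any() else 1.0
            assert uncentered_correlation(v, v) == pytest.approx(expected)


def _oracle_average_linkage(bm):
    """Independent oracle: naive agglomeration recomputing every
    cluster-cluster similarity as the explicit mean over cross pairs."""
    base = similarity_matrix(bm)
    n = bm.n
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            sims = [base[i, j] for i in clusters[a] for j in clusters[b]]
            s = float(np.mean(sims))
            key_ids = tuple(
                sorted(
                    (
                        min(bm.ids[i] for i in clusters[a]),
                        min(bm.ids[i] for i in clusters[b]),
                    )
                )
            )
            if best is None or s > best[0] + 1e-15 or (
                abs(s - best[0]) <= 1e-15 and key_ids < best[3]
            ):
                best = (s, a, b, key_ids)
        s, a, b, _ = best
        merges.append((a, b, s, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestAverageLinkage:
    def test_first_merge_joins_identical_rows(self):
        bm = _bm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        tree = average_linkage(bm)
        left, right, sim, size = tree.merges[0]
        assert {left, right} == {0, 1}
        assert sim == pytest.approx(1.0)
        assert size == 2

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(4):
            rows = (rng.random((6, 9)) < 0.45).astype(np.int8)
            rows[~rows.any(axis=1), 0] = 1  # avoid all-zero rows
            bm = _bm(rows)
            ours = average_linkage(bm).merges
            oracle = _oracle_average_linkage(bm)
            for (l1, r1, s1, z1), (l2, r2, s2, z2) in zip(ours, oracle):
                assert {l1, r1} == {l2, r2}, trial
                assert s1 == pytest.approx(s2)
                assert z1 == z2

    def test_matches_scipy_average_linkage(self):
        # tie-free real-valued rows: merge heights agree with the reference
        # implementation on distances 1 - similarity
        rng = np.random.default_rng(8)
        rows = rng.random((10, 12)) + 0.05
        bm = BinaryMatrix([f"n{i}" for i in range(10)], rows)
        tree = average_linkage(bm)
        sims = similarity_matrix(bm)
        z = linkage(squareform(1.0 - sims, checks=False), method="average")
        ours = sorted(1.0 - m[2] for m in tree.merges)
        theirs = sorted(z[:, 2])
        assert np.allclose(ours, theirs)

    def test_merge_similarities_non_increasing(self, whole_net):
        bm = build_binary_matrix(whole_net)
        tree = average_linkage(bm)
        sims = [m[2] for m in tree.merges]
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(13)
        rows = (rng.random((8, 10)) < 0.4).astype(np.int8)
        rows[~rows.any(axis=1), 0] = 1
        ids = [f"n{i}" for i in range(8)]
        perm = rng.permutation(8)
        tree_a = average_linkage(_bm(rows, ids))
        tree_b = average_linkage(_bm(rows[perm], [ids[i] for i in perm]))
        for t in (0.3, 0.5, 0.8):
            cut_a = {frozenset(c) for c in cut_at_similarity(tree_a, t).clusters}
            cut_b = {frozenset(c) for c in cut_at_similarity(tree_b, t).clusters}
            assert cut_a == cut_b

    def test_single_row_error(self):
        with pytest.raises(NetworkError):
            average_linkage(_bm([[1, 0]]))


class TestCuts:
    def test_threshold_above_max_gives_no_clusters(self):
        bm = _bm([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
        tree = average_linkage(bm)
        top = max(m[2] for m in tree.merges)
        assert top < 1.0
        assert cut_at_similarity(tree, 1.0).n_clusters == 0

    def test_threshold_zero_merges_everything(self):
        bm = _bm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        cut = cut_at_similarity(average_linkage(bm), 0.0)
        assert sum(len(c) for c in cut.clusters) == 4

    def test_invalid_threshold_error(self):
        tree = average_linkage(_bm([[1, 0], [0, 1]]))
        with pytest.raises(NetworkError):
            cut_at_similarity(tree, 1.5)

    def test_cluster_internal_merges_reach_threshold(self, whole_net):
        bm = build_binary_matrix(whole_net)
        tree = average_linkage(bm)
        cut = cut_at_similarity(tree, 0.4)
        assert cut.min_size >= 2
        seen = set()
        for c in cut.clusters:
            assert not (seen & set(c))
            seen |= set(c)

    def test_curve_monotone_and_matches_independent_cuts(self, whole_net):
        bm = build_binary_matrix(whole_net)
        tree = average_linkage(bm)
        grid = np.round(np.arange(0.0, 1.01, 0.05), 10)
        curve = clustered_node_curve(tree, grid)
        counts = [c for _, c in curve]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # independent union-find recomputation per threshold
        n = tree.n_leaves
        for t, expected in curve[:: max(1, len(curve) // 7)]:
            parent = list(range(n + len(tree.merges)))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, (l, r, s, _) in enumerate(tree.merges):
                if s >= t:
                    parent[find(l)] = parent[find(r)] = n + i
            groups = {}
            for leaf in range(n):
                groups.setdefault(find(leaf), []).append(leaf)
            total = sum(len(g) for g in groups.values() if len(g) >= 2)
            assert total == expected

    def test_curve_empty_grid_error(self, whole_net):
        tree = average_linkage(build_binary_matrix(whole_net))
        with pytest.raises(NetworkError):
            clustered_node_curve(tree, [])


class TestInflections:
    def test_linear_curve_has_none(self):
        curve = [(0.1 * i, 100 - 10 * i) for i in range(9)]
        assert detect_inflections(curve) == []

    def test_single_knee_detected_at_knee(self):
        ts = np.round(np.arange(0.0, 0.85, 0.05), 10)
        ys = [200 - 100 * t if t <= 0.4 else 160 - 350 * (t - 0.4) + 0 * t for t in ts]
        curve = list(zip(ts, ys))
        assert detect_inflections(curve) == [pytest.approx(0.4)]

    def test_two_knees_detected_in_order(self):
        ts = np.round(np.arange(0.0, 1.01, 0.05), 10)

        def y(t):
            if t <= 0.3:
                return 300 - 100 * t
            if t <= 0.7:
                return 270 - 500 * (t - 0.3)
            return 70 - 100 * (t - 0.7)

        knees = detect_inflections([(t, y(t)) for t in ts])
        assert len(knees) == 2
        assert knees[0] == pytest.approx(0.3)
        assert knees[1] == pytest.approx(0.7)

    def test_short_curve_error(self):
        with pytest.raises(NetworkError):
            detect_inflections([(0.0, 5), (0.5, 3), (1.0, 1)])


class TestExports:
    def test_cdt_gtr_round_structure(self, tmp_path, whole_net):
        bm = build_binary_matrix(whole_net)
        tree = average_linkage(bm)
        cdt, gtr = export_cdt_gtr(bm, tree, tmp_path / "out")
        gtr_lines = gtr.read_text().splitlines()
        assert len(gtr_lines) == len(tree.merges)
        cdt_lines = cdt.read_text().splitlines()
        assert len(cdt_lines) == bm.n + 1  # header + one row per leaf
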
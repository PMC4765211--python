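import math

import numpy as np
import pytest

from conftest import EUCLIDEAN, random_records
from vpsearch.baselines import brute_force_knn
from vpsearch.datamodel import DimensionError, ParameterError
from vpsearch.vptree import (
    PruneDecision,
    VPNode,
    VPTree,
    build_tree,
    prune_decision,
    search_knn,
    select_median,
)


def audit_partition(tree):
    """Verify the node partition invariant over the whole tree."""
    metric, vectors = tree.metric, tree.vectors
    stack = [tree.root] if tree.root is not None else []
    while stack:
        node = stack.pop()
        if node.left is not None:
            for sid in node.left.iter_ids():
                assert metric(vectors[node.vantage_id], vectors[sid]) < node.mu
            stack.append(node.left)
        if node.right is not None:
            for sid in node.right.iter_ids():
                assert metric(vectors[node.vantage_id], vectors[sid]) >= node.mu
            stack.append(node.right)


class TestSelectMedian:
    def test_singleton(self):
        assert select_median([3]) == 3

    def test_even_lower_median(self):
        assert select_median([1, 2, 3, 4]) == 2

    def test_matches_sorting_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            vals = rng.normal(size=m)
            oracle = sorted(vals)[(m - 1) // 2]  # rank ceil(m/2), 1-based
            assert select_median(vals) == oracle

    def test_result_is_attained(self, rng):
        vals = list(rng.normal(size=10))
        assert select_median(vals) in vals

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            select_median([])


class TestBuildTree:
    def test_single_record(self):
        tree = build_tree({"only": np.array([1.0, 2.0])}, EUCLIDEAN, seed=0)
        assert tree.root.vantage_id == "only"
        assert tree.root.mu is None
        assert tree.root.left is None and tree.root.right is None

    def test_empty_input(self):
        tree = build_tree({}, EUCLIDEAN, seed=0)
        assert tree.root is None and tree.n == 0

    def test_three_collinear_points_partition(self):
        # With vantage (1): distances {1, 1}, mu = 1, L empty, R = {(0), (2)}.
        records = {"a": np.array([0.0]), "b": np.array([1.0]), "c": np.array([2.0])}
        for seed in range(50):
            tree = build_tree(records, EUCLIDEAN, seed=seed)
            if tree.root.vantage_id == "b":
                break
        else:
            pytest.fail("no seed put the middle point at the root")
        assert tree.root.mu == 1.0
        assert tree.root.left is None
        assert sorted(tree.root.right.iter_ids()) == ["a", "c"]

    def test_partition_invariant_random_points(self, rng):
        records = random_records(rng, 200, 10)
        tree = build_tree(records, EUCLIDEAN, seed=3)
        audit_partition(tree)
        assert sorted(tree.root.iter_ids()) == sorted(records)

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_build_eval_bound(self, rng, n):
        records = random_records(rng, n, 10)
        tree = build_tree(records, EUCLIDEAN, seed=1)
        assert tree.build_distance_evals <= n * (math.floor(math.log2(n)) + 1)

    def test_deterministic(self, rng):
        records = random_records(rng, 80, 5)

        def shape(node):
            if node is None:
                return None
            return (node.vantage_id, node.mu, shape(node.left), shape(node.right))

        t1 = build_tree(records, EUCLIDEAN, seed=9)
        t2 = build_tree(records, EUCLIDEAN, seed=9)
        assert shape(t1.root) == shape(t2.root)
        q = rng.normal(size=5)
        r1, r2 = search_knn(t1, q, k=5), search_knn(t2, q, k=5)
        assert r1.hits == r2.hits
        assert r1.n_distance_evals == r2.n_distance_evals

    def test_inconsistent_lengths(self):
        with pytest.raises(DimensionError):
            build_tree({"a": np.zeros(2), "b": np.zeros(3)}, EUCLIDEAN, seed=0)

    def test_duplicate_vectors_allowed(self):
        records = {f"d{i}": np.zeros(3) for i in range(20)}
        tree = build_tree(records, EUCLIDEAN, seed=0)
        assert sorted(tree.root.iter_ids()) == sorted(records)
        audit_partition(tree)


class TestPruneDecision:
    def test_fathom_left(self):
        # d(p,q) >= tau + mu: nothing within mu can beat tau.
        assert prune_decision(10, 3, 2) is PruneDecision.SEARCH_RIGHT_ONLY

    def test_fathom_right(self):
        # d(p,q) + tau <= mu: the best candidate is certainly inside mu.
        assert prune_decision(1, 5, 2) is PruneDecision.SEARCH_LEFT_ONLY

    def test_infinite_tau_searches_both(self):
        assert prune_decision(7, 3, math.inf) is PruneDecision.SEARCH_BOTH

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            prune_decision(-1, 3, 2)

    def test_search_flags(self):
        assert prune_decision(10, 3, 2).search_right
        assert not prune_decision(10, 3, 2).search_left


class TestSearchKnn:
    def test_self_match(self, rng):
        records = random_records(rng, 30, 4)
        tree = build_tree(records, EUCLIDEAN, seed=0)
        result = search_knn(tree, records["r0007"], k=1)
        assert result.hits == [("r0007", 0.0)]

    def test_k_exceeds_n_returns_all(self, rng):
        records = random_records(rng, 12, 3)
        tree = build_tree(records, EUCLIDEAN, seed=0)
        result = search_knn(tree, rng.normal(size=3), k=50)
        assert len(result) == 12
        assert result.distances == sorted(result.distances)

    def test_empty_tree(self):
        tree = build_tree({}, EUCLIDEAN, seed=0)
        result = search_knn(tree, np.zeros(3), k=5)
        assert result.hits == [] and result.n_distance_evals == 0

    def test_dimension_mismatch(self, rng):
        tree = build_tree(random_records(rng, 10, 4), EUCLIDEAN, seed=0)
        with pytest.raises(DimensionError):
            search_knn(tree, np.zeros(5), k=1)

    def test_invalid_k(self, rng):
        tree = build_tree(random_records(rng, 10, 4), EUCLIDEAN, seed=0)
        with pytest.raises(ParameterError):
            search_knn(tree, np.zeros(4), k=0)

    @pytest.mark.parametrize("n", [10, 100])
    @pytest.mark.parametrize("dim", [2, 10])
    @pytest.mark.parametrize("k", [1, 5, 10])
    def test_matches_brute_force(self, rng, n, dim, k):
        records = random_records(rng, n, dim)
        tree = build_tree(records, EUCLIDEAN, seed=n + dim + k)
        for _ in range(20):
            q = rng.normal(size=dim)
            assert (
                search_knn(tree, q, k=k).hits
                == brute_force_knn(records, EUCLIDEAN, q, k).hits
            )

    def test_matches_brute_force_under_ties(self, rng):
        # Integer grid points produce massive distance ties; the strict
        # right-side fathoming rule must keep tie-broken results exact.
        records = {
            f"p{i}_{j}": np.array([float(i), float(j)])
            for i in range(6)
            for j in range(6)
        }
        tree = build_tree(records, EUCLIDEAN, seed=2)
        for qx in range(6):
            for qy in range(6):
                q = np.array([float(qx), float(qy)])
                for k in (1, 4, 9):
                    assert (
                        search_knn(tree, q, k=k).hits
                        == brute_force_knn(records, EUCLIDEAN, q, k).hits
                    )

    def test_evals_never_exceed_n(self, rng):
        records = random_records(rng, 300, 8)
        tree = build_tree(records, EUCLIDEAN, seed=5)
        for _ in range(50):
            result = search_knn(tree, rng.normal(size=8), k=3)
            assert result.n_distance_evals <= 300

    def test_exclude_self(self, rng):
        records = random_records(rng, 40, 4)
        tree = build_tree(records, EUCLIDEAN, seed=0)
        q = records["r0001"]
        res = search_knn(tree, q, k=5, exclude_id="r0001")
        assert "r0001" not in res.sample_ids
        oracle = brute_force_knn(records, EUCLIDEAN, q, 5, exclude_id="r0001")
        assert res.hits == oracle.hits

    def test_exclude_self_keeps_nonzero_distance_matches(self, rng):
        # Only a distance-0 hit with the matching id is dropped.
        records = {"a": np.array([0.0]), "b": np.array([1.0])}
        tree = build_tree(records, EUCLIDEAN, seed=0)
        res = search_knn(tree, np.array([0.5]), k=2, exclude_id="a")
        assert "a" in res.sample_ids

    def test_tau_monotonic(self, rng):
        records = random_records(rng, 200, 6)
        tree = build_tree(records, EUCLIDEAN, seed=4)
        for _ in range(20):
            states = []
            search_knn(tree, rng.normal(size=6), k=5, state_out=states)
            trace = states[0].tau_trace
            assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_fathoming_soundness_audit(self, rng):
        records = random_records(rng, 250, 10)
        tree = build_tree(records, EUCLIDEAN, seed=6)
        total_events = 0
        for _ in range(20):
            q = rng.normal(size=10)
            events = []
            search_knn(tree, q, k=5, audit=events)
            total_events += len(events)
            for ev in events:
                for sid in ev.subtree.iter_ids():
                    d = EUCLIDEAN(q, records[sid])
                    assert d >= ev.tau * (1 - 1e-12) - 1e-12
        assert total_events > 0  # pruning actually happened

    def test_deep_tree_no_recursion_error(self):
        # Degenerate right-spine chain far beyond the interpreter recursion
        # limit; search and traversal must be stack-based.
        n = 50_000
        vectors = {f"s{i}": np.array([float(i)]) for i in range(n)}
        root = VPNode(vantage_id="s0", mu=0.5)
        node = root
        for i in range(1, n):
            child = VPNode(vantage_id=f"s{i}", mu=0.5)
            node.right = child
            node = child
        node.mu = None
        tree = VPTree(root=root, metric=EUCLIDEAN, vectors=vectors, rng_seed=0)
        result = search_knn(tree, np.array([-10.0]), k=3)
        assert result.sample_ids == ["s0", "s1", "s2"]
        assert sum(1 for _ in root.iter_ids()) == n
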
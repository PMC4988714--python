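import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungseg.clustering import (
    Chromosome,
    NeuralForest,
    build_assignment,
    cluster_assignment,
    exhaustive_best_seeds,
    fitness,
    ga_select_seeds,
    normalize_features,
    sample_distance,
    scatter,
    sgnt_insert,
)
from lungseg.stackio import StackValidationError


class TestSampleDistance:
    def test_identical_vectors(self):
        assert sample_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_one_dimensional(self):
        assert sample_distance([0.0], [3.0]) == pytest.approx(3.0)

    def test_dimension_normalisation(self):
        xi, xj = np.zeros(4), np.ones(4)
        # independent recomputation: sqrt(sum/p) without a loop
        expected = np.sqrt(np.dot(xj - xi, xj - xi) / 4)
        assert sample_distance(xi, xj, p=4) == pytest.approx(expected) == 1.0

    def test_mismatch_rejected(self):
        with pytest.raises(StackValidationError):
            sample_distance([1.0], [1.0, 2.0])


class TestForestInsertion:
    def test_hand_traced_two_seed_insertion(self):
        samples = np.array([[0.0], [10.0], [1.0]])
        forest = NeuralForest(samples, seed_ids=[0, 1])
        sgnt_insert(forest, samples[2], 2)
        # sample 2 attaches under the w=0 tree; that root becomes internal
        root = forest.nodes[0]
        assert not root.is_leaf
        assert root.w[0] == pytest.approx(0.5)
        assert forest.nodes[1].is_leaf  # other tree untouched
        assert cluster_assignment(forest) == {0: 0, 1: 1, 2: 0}

    def test_insert_duplicate_of_seed_keeps_root_weight(self):
        samples = np.array([[5.0, 5.0], [9.0, 9.0], [5.0, 5.0]])
        forest = NeuralForest(samples, seed_ids=[0, 1])
        forest.insert(samples[2], 2)
        assert forest.nodes[0].w == pytest.approx([5.0, 5.0])
        assert forest.nodes[0].leaf_count == 2

    def test_empty_forest_rejected(self):
        with pytest.raises(StackValidationError):
            NeuralForest(np.zeros((3, 2)), seed_ids=[])
        with pytest.raises(StackValidationError):
            NeuralForest(np.zeros((3, 2)), seed_ids=[0, 0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_structural_invariants_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n, p, K = 30, 3, 4
        samples = rng.normal(size=(n, p))
        forest = NeuralForest(samples, seed_ids=list(range(K)))
        for sid in range(K, n):
            before = sum(node.is_leaf for node in forest.nodes)
            forest.insert(samples[sid], sid)
            after = sum(node.is_leaf for node in forest.nodes)
            assert after == before + 1  # exactly one net new leaf
        assign = cluster_assignment(forest)
        assert sorted(assign) == list(range(n))  # partition of all samples
        assert set(assign.values()) <= set(range(K))
        # weight-consistency: every neuron's weight is its leaf average
        for idx, node in enumerate(forest.nodes):
            leaves = forest.leaves_under(idx)
            mean = np.mean([forest.nodes[i].w for i in leaves], axis=0)
            np.testing.assert_allclose(node.w, mean, atol=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_numba_kernel_matches_python_reference(self, seed):
        rng = np.random.default_rng(seed)
        n, p, K = 40, 4, 3
        samples = np.ascontiguousarray(rng.normal(size=(n, p)))
        seeds = rng.choice(n, size=K, replace=False)
        kernel = build_assignment(samples, seeds.astype(np.int64))
        forest = NeuralForest(samples, seed_ids=list(seeds))
        for sid in range(n):
            if sid not in set(int(s) for s in seeds):
                forest.insert(samples[sid], sid)
        reference = cluster_assignment(forest)
        assert {i: int(kernel[i]) for i in range(n)} == reference


class TestScatter:
    def test_zero_when_samples_equal_centers(self):
        samples = np.array([[1.0], [1.0], [5.0]])
        assign = np.array([0, 0, 1])
        centers = np.array([[1.0], [5.0]])
        assert scatter(samples, assign, centers) == 0.0

    def test_hand_computed_value(self):
        # one cluster, p=1, samples {0, 2}, centre 1 -> (1 + 1) / 2 = 1
        samples = np.array([[0.0], [2.0]])
        assert scatter(samples, np.zeros(2, int), np.array([[1.0]])) == pytest.approx(1.0)

    def test_invariant_under_cluster_relabeling(self, rng):
        samples = rng.normal(size=(12, 2))
        assign = rng.integers(0, 3, size=12)
        centers = np.array([samples[assign == i].mean(axis=0) for i in range(3)])
        base = scatter(samples, assign, centers)
        perm = np.array([2, 0, 1])
        assert scatter(samples, perm[assign], centers[np.argsort(perm)]) == pytest.approx(base)

    def test_empty_cluster_contributes_zero(self):
        samples = np.array([[0.0], [2.0]])
        assign = np.zeros(2, int)
        centers = np.array([[1.0], [99.0]])  # cluster 1 empty
        assert scatter(samples, assign, centers) == pytest.approx(1.0)


class TestFitness:
    def test_phi_mapping(self):
        # K = n: every sample its own seed, delta2 = 0, phi = 1
        samples = np.ascontiguousarray(np.arange(6, dtype=float).reshape(3, 2))
        assert fitness((0, 1, 2), samples) == pytest.approx(1.0)

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(StackValidationError):
            fitness((0, 0), np.zeros((3, 2)))

    def test_monotone_transform_of_scatter(self, rng):
        # phi strictly decreases as within-cluster scatter grows
        tight = np.ascontiguousarray(
            np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(10, 0.01, (5, 2))])
        )
        loose = np.ascontiguousarray(
            np.vstack([rng.normal(0, 2.0, (5, 2)), rng.normal(10, 2.0, (5, 2))])
        )
        assert fitness((0, 5), tight) > fitness((0, 5), loose)


def _blob_samples(rng, k=4, per=3, spread=0.3, gap=10.0):
    centers = gap * np.array([[0, 0], [1, 0], [0, 1], [1, 1]])[:k]
    pts = np.vstack([c + rng.normal(0, spread, (per, 2)) for c in centers])
    return np.ascontiguousarray(pts)


class TestGa:
    def test_recovers_blob_partition_near_exhaustive_optimum(self, rng):
        samples = _blob_samples(np.random.default_rng(5))
        oracle = exhaustive_best_seeds(samples, K=4)
        result = ga_select_seeds(samples, K=4, T=200, rng=11)
        assert result.fitness >= 0.95 * oracle.fitness
        assign = build_assignment(samples, np.asarray(result.seed_ids, np.int64))
        # induced assignment equals the blob partition
        blocks = [set(assign[i * 3:(i + 1) * 3]) for i in range(4)]
        assert all(len(b) == 1 for b in blocks)
        assert len({b.pop() for b in blocks}) == 4

    def test_best_fitness_trace_non_decreasing(self):
        samples = _blob_samples(np.random.default_rng(2))
        result = ga_select_seeds(samples, K=4, T=50, rng=3)
        trace = result.best_per_generation
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_k_equals_sample_count_gives_unit_fitness(self):
        samples = np.ascontiguousarray(np.random.default_rng(0).normal(size=(5, 2)))
        result = ga_select_seeds(samples, K=5, T=5, rng=0)
        assert result.fitness == pytest.approx(1.0)

    def test_deterministic_given_rng_seed(self):
        samples = _blob_samples(np.random.default_rng(8))
        a = ga_select_seeds(samples, K=4, T=30, rng=42)
        b = ga_select_seeds(samples, K=4, T=30, rng=42)
        assert a.seed_ids == b.seed_ids and a.fitness == b.fitness

    def test_small_population_rejected(self):
        with pytest.raises(StackValidationError):
            ga_select_seeds(np.zeros((4, 2)), K=2, pop_size=1)

    def test_chromosome_validates_distinct_ids(self):
        with pytest.raises(StackValidationError):
            Chromosome((1, 1, 2))

    def test_order_sensitivity_bounded_by_ga(self):
        # a GA-seeded forest never scatters worse than a random-order tree
        rng = np.random.default_rng(9)
        samples = _blob_samples(rng)
        result = ga_select_seeds(samples, K=4, T=100, rng=7)
        order = rng.permutation(len(samples))
        single = NeuralForest(samples[order], seed_ids=[0])
        for i in range(1, len(samples)):
            single.insert(samples[order][i], i)
        # compare within-cluster scatter via the fitness transform
        assign = np.zeros(len(samples), int)
        center = samples.mean(axis=0, keepdims=True)
        d2_single = scatter(samples, assign, center)
        assert result.fitness >= 1.0 / (1.0 + d2_single)


def test_normalize_features_unit_range(rng):
    feats = rng.normal(size=(20, 6)) * [5, 0, 0, 100, 50, 3]
    norm = normalize_features(feats)
    assert norm.min() >= 0 and norm.max() <= 1
    assert np.all(norm[:, 1] == 0)  # constant columns collapse to 0
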
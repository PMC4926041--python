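"""Tests for the rough-set harmony memory construction."""

import itertools

import numpy as np
import pytest

from harmonyseg import (
    HSParams,
    RoughParams,
    build_harmony_memory,
    init_centers,
    knn_refine,
    rough_assign,
    update_centers_rough,
)
from harmonyseg.rough import RoughPartition


def wcss(data):
    data = np.asarray(data, dtype=float)

    def objective(centers):
        return float((np.abs(data[:, None] - centers[None, :]).min(axis=1) ** 2).sum())

    return objective


def kmeans_1d_oracle(data, k):
    """Exhaustive 1-D k-means: optimal clusters are contiguous in sorted order."""
    x = np.sort(np.asarray(data, dtype=float))
    n = len(x)
    best_cost, best_centers = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        groups = [x[bounds[i]:bounds[i + 1]] for i in range(k)]
        centers = np.array([g.mean() for g in groups])
        cost = sum(((g - c) ** 2).sum() for g, c in zip(groups, centers))
        if cost < best_cost:
            best_cost, best_centers = cost, centers
    return best_centers, best_cost


class TestInitCenters:
    def test_uniform_grid_quartiles(self):
        data = np.linspace(0.0, 1.0, 101)
        np.testing.assert_allclose(init_centers(data, 2), [0.25, 0.75], atol=1e-12)

    def test_single_cluster_is_median(self):
        data = np.array([0.0, 0.1, 0.9, 1.0])
        np.testing.assert_allclose(init_centers(data, 1), [0.5])

    def test_four_point_quantiles(self):
        data = np.array([0.0, 0.1, 0.9, 1.0])
        np.testing.assert_allclose(init_centers(data, 2), [0.05, 0.95])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            init_centers(np.array([0.5]), 2)

    def test_strictly_increasing_on_distinct_data(self, rng):
        data = rng.random(40)
        centers = init_centers(data, 4)
        assert np.all(np.diff(centers) > 0)


class TestRoughAssign:
    def test_huge_threshold_makes_everything_boundary(self):
        data = np.array([0.0, 0.2, 0.5, 0.8, 1.0])
        part = rough_assign(data, np.array([0.1, 0.9]), boundary_threshold=2.0)
        assert all(len(s) == 0 for s in part.lower)
        assert len(part.boundary) == len(data)

    def test_zero_threshold_all_lower(self):
        data = np.array([0.0, 0.1, 0.8, 1.0])
        part = rough_assign(data, np.array([0.05, 0.9]), boundary_threshold=0.0)
        assert len(part.boundary) == 0
        assert sorted(np.concatenate(part.lower).tolist()) == [0, 1, 2, 3]

    def test_margin_rule_hand_case(self):
        # point 0.4: d to nearest center (0) is 0.4, to the other 0.6;
        # margin 0.2 <= 0.3 makes it a boundary point of both
        part = rough_assign(np.array([0.0, 0.4, 1.0]), np.array([0.0, 1.0]), 0.3)
        assert part.boundary.tolist() == [1]
        assert 0 in part.lower[0] and 2 in part.lower[1]
        assert 1 in part.upper[0] and 1 in part.upper[1]

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            rough_assign(np.array([0.0, 1.0]), np.array([0.5, 0.5]), 0.1)

    def test_partition_invariants(self, rng):
        data = rng.random(200)
        part = rough_assign(data, np.array([0.2, 0.5, 0.8]), 0.1)
        part.validate()  # raises on violation


class TestUpdateCentersRough:
    def test_no_boundary_is_kmeans_step(self):
        data = np.array([0.0, 0.2, 0.8, 1.0])
        part = rough_assign(data, np.array([0.1, 0.9]), 0.0)
        np.testing.assert_allclose(update_centers_rough(data, part, 0.75), [0.1, 0.9])

    def test_weighted_blend(self):
        # lower mean 0.2, boundary mean 0.8, w_low 0.75 -> 0.35
        data = np.array([0.2, 0.8])
        part = RoughPartition(
            centers=np.array([0.3, 10.0]),
            lower=[np.array([0]), np.array([], dtype=int)],
            upper=[np.array([0, 1]), np.array([1])],
            boundary=np.array([1]),
            n_points=2,
        )
        new = update_centers_rough(data, part, 0.75)
        assert new[0] == pytest.approx(0.35)

    def test_empty_cluster_keeps_center(self):
        data = np.array([0.0, 0.1])
        part = RoughPartition(
            centers=np.array([0.05, 0.9]),
            lower=[np.array([0, 1]), np.array([], dtype=int)],
            upper=[np.array([0, 1]), np.array([], dtype=int)],
            boundary=np.array([], dtype=int),
            n_points=2,
        )
        new = update_centers_rough(data, part, 0.8)
        assert new[1] == pytest.approx(0.9)


class TestKnnRefine:
    def test_single_neighbor_label(self):
        data = np.array([0.0, 0.45, 1.0])
        part = rough_assign(data, np.array([0.0, 1.0]), 0.2)
        labels = knn_refine(data, part, knn_k=1)
        assert labels[1] == 0  # nearest labeled point is 0.0

    def test_majority_vote_hand_case(self):
        # lower sets {0.0, 0.1} and {0.9, 1.0}; boundary point 0.3 with
        # k=3 sees neighbors 0.1, 0.0, 0.9 voting 2:1 for the low cluster
        data = np.array([0.0, 0.1, 0.9, 1.0, 0.3])
        part = RoughPartition(
            centers=np.array([0.05, 0.95]),
            lower=[np.array([0, 1]), np.array([2, 3])],
            upper=[np.array([0, 1, 4]), np.array([2, 3, 4])],
            boundary=np.array([4]),
            n_points=5,
        )
        labels = knn_refine(data, part, knn_k=3)
        assert labels[4] == 0

    def test_equidistant_tie_lowest_index(self):
        # boundary point exactly between two singleton lower sets: the
        # vote ties, the inverse-distance sums tie, lowest index wins
        data = np.array([0.0, 1.0, 0.5])
        part = RoughPartition(
            centers=np.array([0.0, 1.0]),
            lower=[np.array([0]), np.array([1])],
            upper=[np.array([0, 2]), np.array([1, 2])],
            boundary=np.array([2]),
            n_points=3,
        )
        labels = knn_refine(data, part, knn_k=2)
        assert labels[2] == 0

    def test_empty_lower_set_rejected(self):
        data = np.array([0.0, 1.0])
        part = RoughPartition(
            centers=np.array([0.0, 1.0]),
            lower=[np.array([0, 1]), np.array([], dtype=int)],
            upper=[np.array([0, 1]), np.array([], dtype=int)],
            boundary=np.array([], dtype=int),
            n_points=2,
        )
        with pytest.raises(ValueError, match="boundary_threshold"):
            knn_refine(data, part, knn_k=1)


class TestBuildHarmonyMemory:
    def _params(self, k, data, **rough_kw):
        hs = HSParams(n_dims=k, lower_bound=0.0, upper_bound=1.0, hms=12, seed=5)
        rough = RoughParams(k_clusters=k, seed=9, **rough_kw)
        return hs, rough

    def test_separated_spikes_recovered_exactly(self):
        data = np.repeat([0.1, 0.5, 0.9], 50)
        hs, rough = self._params(3, data, stop_threshold=0.0, boundary_threshold=0.05)
        mem = build_harmony_memory(data, rough, hs, wcss(data))
        np.testing.assert_allclose(np.sort(mem.vectors[0]), [0.1, 0.5, 0.9], atol=1e-12)
        assert mem.fitness[0] == pytest.approx(0.0, abs=1e-20)

    def test_zero_rounds_uses_quantile_centers(self):
        data = np.linspace(0.0, 1.0, 101)
        hs, rough = self._params(2, data, max_rounds=0)
        mem = build_harmony_memory(data, rough, hs, wcss(data))
        np.testing.assert_allclose(mem.vectors[0], [0.25, 0.75])

    def test_seeded_determinism(self, rng):
        data = rng.random(300)
        hs, rough = self._params(2, data)
        a = build_harmony_memory(data, rough, hs, wcss(data))
        b = build_harmony_memory(data, rough, hs, wcss(data))
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_memory_invariants(self, rng):
        data = rng.random(500)
        hs, rough = self._params(3, data)
        mem = build_harmony_memory(data, rough, hs, wcss(data))
        assert mem.vectors.shape == (hs.hms, 3)
        assert np.all(mem.vectors >= 0.0) and np.all(mem.vectors <= 1.0)
        recomputed = np.array([wcss(data)(row) for row in mem.vectors])
        np.testing.assert_allclose(mem.fitness, recomputed)

    def test_dimension_mismatch_rejected(self, rng):
        data = rng.random(50)
        hs = HSParams(n_dims=5, lower_bound=0.0, upper_bound=1.0, hms=4)
        with pytest.raises(ValueError, match="n_dims"):
            build_harmony_memory(data, RoughParams(k_clusters=2), hs, wcss(data))

    @pytest.mark.parametrize(
        "data,k",
        [
            (np.array([0.05, 0.1, 0.12, 0.8, 0.85, 0.9]), 2),
            (np.array([0.0, 0.02, 0.05, 0.45, 0.5, 0.55, 0.9, 0.95, 1.0]), 3),
            (np.array([0.1, 0.12, 0.3, 0.32, 0.7, 0.72, 0.9, 0.92, 0.5, 0.52, 0.2, 0.8]), 3),
        ],
    )
    def test_zero_threshold_matches_exhaustive_kmeans(self, data, k):
        """With no boundary region the rough iteration is Lloyd's k-means."""
        hs = HSParams(n_dims=k, lower_bound=0.0, upper_bound=1.0, hms=1, seed=1)
        rough = RoughParams(
            k_clusters=k, boundary_threshold=0.0, w_low=0.6,
            max_rounds=200, stop_threshold=0.0,
        )
        mem = build_harmony_memory(data, rough, hs, wcss(data))
        oracle_centers, oracle_cost = kmeans_1d_oracle(data, k)
        np.testing.assert_allclose(np.sort(mem.vectors[0]), oracle_centers, atol=1e-9)
        assert mem.fitness[0] == pytest.approx(oracle_cost, abs=1e-9)

    def test_built_memory_beats_random_memory(self, rng):
        """The data-driven memory starts with a better best fitness than
        the median uniformly random memory of the same size."""
        data = np.concatenate(
            [rng.normal(m, 0.05, 200) for m in (0.2, 0.5, 0.8)]
        ).clip(0, 1)
        objective = wcss(data)
        hs, rough = self._params(3, data)
        built_best = build_harmony_memory(data, rough, hs, objective).best_fitness
        random_bests = []
        for seed in range(50):
            r = np.random.default_rng(seed).random((hs.hms, 3))
            random_bests.append(min(objective(row) for row in r))
        assert built_best <= np.median(random_bests)
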
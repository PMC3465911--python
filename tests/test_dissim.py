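import numpy as np
import pytest

from sitewise import (
    DissimilarityMap,
    correlation_distance,
    euclidean_distance,
    fft_select,
    project,
    projected_distance,
    projection_quality,
    select_num_prototypes,
)
from sitewise.dissim import project_all


def first_pick(seed, n):
    return int(np.random.default_rng(seed).integers(n))


def seed_with_first(target, n):
    """Smallest seed whose uniform first draw selects `target` of n objects."""
    for seed in range(1000):
        if first_pick(seed, n) == target:
            return seed
    raise AssertionError("no such seed in range")


class TestDistances:
    def test_correlation_identical(self):
        assert correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_correlation_anticorrelated(self):
        assert correlation_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_correlation_explicit_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        r = cov / (a.std() * b.std())
        assert correlation_distance(a, b) == pytest.approx(1.0 - r, abs=1e-12)

    def test_correlation_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_euclidean_345(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_euclidean_loop_oracle(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
        assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)


def fft_oracle(objects, d, p, first, criterion="sum"):
    """Brute-force re-selection: explicit argmax loop with lowest-index ties."""
    selected = [first]
    while len(selected) < p:
        best, best_score = None, -np.inf
        for i in range(len(objects)):
            if i in selected:
                continue
            dists = [d(objects[i], objects[j]) for j in selected]
            score = sum(dists) if criterion == "sum" else min(dists)
            if score > best_score:
                best, best_score = i, score
        selected.append(best)
    return selected


class TestFFTSelect:
    def test_forced_ordering(self):
        pts = [np.array([x]) for x in (0.0, 1.0, 10.0)]
        seed = seed_with_first(0, 3)
        ps = fft_select(pts, euclidean_distance, 3, seed=seed)
        assert ps.indices == [0, 2, 1]  # 10 beats 1 (sum 10 > 1), then 1

    def test_tie_breaks_to_lowest_index(self):
        pts = [np.array([x]) for x in (0.0, 4.0, 5.0, 10.0)]
        seed = seed_with_first(2, 4)  # start from 5; 0 and 10 tie at distance 5
        ps = fft_select(pts, euclidean_distance, 2, seed=seed)
        assert ps.indices == [2, 0]

    @pytest.mark.parametrize("criterion", ["sum", "maxmin"])
    def test_matches_bruteforce_oracle(self, criterion, rng):
        pts = [rng.normal(size=2) for _ in range(12)]
        for seed in range(5):
            ps = fft_select(pts, euclidean_distance, 5, seed=seed, criterion=criterion)
            oracle = fft_oracle(pts, euclidean_distance, 5, ps.indices[0], criterion)
            assert ps.indices == oracle

    def test_reproducible(self, rng):
        pts = [rng.normal(size=3) for _ in range(10)]
        a = fft_select(pts, euclidean_distance, 4, seed=7)
        b = fft_select(pts, euclidean_distance, 4, seed=7)
        assert a.indices == b.indices

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            fft_select([np.zeros(2)], euclidean_distance, 2, seed=0)
        with pytest.raises(ValueError):
            fft_select([], euclidean_distance, 1, seed=0)


class TestProjection:
    def make_map(self, protos):
        return DissimilarityMap(
            prototypes=[np.array([p]) for p in protos], distance=euclidean_distance
        )

    def test_prototype_projects_to_zero(self):
        dmap = self.make_map([0.0, 10.0])
        assert project(np.array([0.0]), dmap)[0] == 0.0

    def test_worked_example(self):
        dmap = self.make_map([0.0, 10.0])
        np.testing.assert_allclose(project(np.array([4.0]), dmap), [4.0, 6.0])
        assert projected_distance(np.array([4.0]), np.array([7.0]), dmap) == pytest.approx(
            np.sqrt(18.0)
        )

    def test_single_prototype(self):
        dmap = self.make_map([2.0])
        assert project(np.array([5.0]), dmap).shape == (1,)

    def test_identity_with_euclidean_of_projections(self, rng):
        dmap = self.make_map([0.0, 3.0, 8.0])
        x, y = np.array([rng.normal()]), np.array([rng.normal()])
        assert projected_distance(x, y, dmap) == pytest.approx(
            euclidean_distance(project(x, dmap), project(y, dmap))
        )

    def test_constant_output_dimension(self, rng):
        dmap = self.make_map([0.0, 1.0])
        phis = project_all([np.array([v]) for v in rng.normal(size=6)], dmap)
        assert phis.shape == (6, 2)


class TestProjectionQuality:
    def test_collinear_is_isometric(self):
        pts = [np.array([float(x)]) for x in range(5)]
        dmap = DissimilarityMap(prototypes=[pts[0]], distance=euclidean_distance)
        q = projection_quality(pts, dmap)
        assert q.r == pytest.approx(1.0)
        assert q.n_pairs == 10

    def test_monotone_refinement_keeps_isometry(self):
        # appending prototypes to the isometric 1D construction keeps r = 1
        pts = [np.array([float(x)]) for x in range(5)]
        for protos in ([0.0], [0.0, -5.0], [0.0, -5.0, -9.0]):
            dmap = DissimilarityMap(
                prototypes=[np.array([p]) for p in protos], distance=euclidean_distance
            )
            assert projection_quality(pts, dmap).r == pytest.approx(1.0)

    def test_two_objects_rejected(self):
        pts = [np.array([0.0]), np.array([1.0])]
        dmap = DissimilarityMap(prototypes=[pts[0]], distance=euclidean_distance)
        with pytest.raises(ValueError, match="at least 3"):
            projection_quality(pts, dmap)

    def test_matches_pairwise_loop_oracle(self, rng):
        pts = [rng.normal(size=3) for _ in range(10)]
        dmap = DissimilarityMap(prototypes=[pts[0], pts[4]], distance=euclidean_distance)
        q = projection_quality(pts, dmap)
        orig, proj = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                orig.append(euclidean_distance(pts[i], pts[j]))
                proj.append(projected_distance(pts[i], pts[j], dmap))
        orig, proj = np.array(orig), np.array(proj)
        r = ((orig - orig.mean()) * (proj - proj.mean())).mean() / (orig.std() * proj.std())
        assert q.r == pytest.approx(r, abs=1e-12)


class TestSelectNumPrototypes:
    def test_collinear_returns_smallest(self):
        pts = [np.array([float(x)]) for x in range(6)]
        p, curve = select_num_prototypes(pts, euclidean_distance, [1, 2, 4], seed=0)
        assert p == 1
        assert curve[0] == (1, pytest.approx(1.0))

    def test_unattainable_threshold_returns_argmax(self):
        pts = [np.array([float(x)]) for x in range(6)]
        p, curve = select_num_prototypes(
            pts, euclidean_distance, [1, 2], threshold=1.01, seed=0
        )
        rs = dict(curve)
        assert rs[p] == max(rs.values())

    def test_matches_grid_oracle(self, rng):
        pts = [rng.normal(size=4) for _ in range(50)]
        grid = [5, 10, 20, 40]
        p, curve = select_num_prototypes(pts, euclidean_distance, grid, seed=3)
        # oracle: independently evaluate r at every grid point
        expected = None
        for pg in grid:
            ps = fft_select(pts, euclidean_distance, pg, seed=3)
            dmap = DissimilarityMap(
                prototypes=[pts[i] for i in ps.indices], distance=euclidean_distance
            )
            r = projection_quality(pts, dmap, seed=3).r
            if r >= 0.85:
                expected = pg
                break
        if expected is None:
            expected = max(curve, key=lambda pr: pr[1])[0]
        assert p == expected

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_num_prototypes([np.zeros(2)] * 3, euclidean_distance, [], seed=0)
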
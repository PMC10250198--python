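"""Map / Locate / NMS / Pick, each checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomopick.embedding import EmbeddingGrid, TargetEmbedding
from tomopick.localize import (Candidate, SimilarityMap, locate, map_targets,
                               nonmaxima_suppress, pick)


def _grid_from_vectors(vectors, shape, box=9, stride=2):
    counts = tuple((d - box) // stride + 1 for d in shape)
    assert np.prod(counts) == len(vectors)
    oz, oy, ox = np.meshgrid(*[np.arange(c) * stride for c in counts],
                             indexing="ij")
    positions = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], 1) + box // 2
    return EmbeddingGrid(positions=positions, vectors=np.asarray(vectors),
                         box_len=box, stride=stride, source_shape=shape)


def _smap(values, box=9, stride=2):
    values = np.asarray(values, dtype=np.float32)
    shape = tuple((c - 1) * stride + box for c in values.shape)
    return SimilarityMap("t", values, box, stride, shape)


class TestMapTargets:
    def test_target_equal_to_grid_vector_gives_one(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(12, 8)).astype(np.float32)
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        grid = _grid_from_vectors(vecs, (11, 11, 13))
        target = TargetEmbedding("t", vecs[5])
        smap = map_targets(grid, [target])[0]
        assert smap.values.ravel()[5] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_target_gives_zero_map(self):
        vecs = np.zeros((8, 4), dtype=np.float32)
        vecs[:, 0] = 1.0
        grid = _grid_from_vectors(vecs, (11, 11, 11))
        smap = map_targets(grid, [TargetEmbedding("t", np.array([0, 1, 0, 0.0]))])[0]
        assert np.allclose(smap.values, 0.0, atol=1e-7)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        vecs = rng.normal(size=(10, 6)).astype(np.float32)
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        grid = _grid_from_vectors(vecs, (9, 11, 17))
        t = rng.normal(size=6)
        t /= np.linalg.norm(t)
        smap = map_targets(grid, [TargetEmbedding("t", t.astype(np.float32))])[0]
        expected = [float(np.dot(v, t)) for v in vecs]
        assert np.allclose(smap.values.ravel(), expected, atol=1e-6)

    def test_empty_grid_errors(self):
        grid = EmbeddingGrid(positions=np.empty((0, 3), dtype=int),
                             vectors=np.empty((0, 4), dtype=np.float32),
                             box_len=9, stride=2, source_shape=(9, 9, 9))
        with pytest.raises(ValueError, match="empty"):
            map_targets(grid, [TargetEmbedding("t", np.array([1, 0, 0, 0.0]))])


# ---------------------------------------------------------------------- #
# locate: flood-fill oracle

def _oracle_locate(values, floor, tol):
    """Independent BFS implementation of the locate rule."""
    v = np.asarray(values, dtype=float)
    shape = v.shape
    nbrs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]

    def neighbors(p):
        for dz, dy, dx in nbrs:
            q = (p[0] + dz, p[1] + dy, p[2] + dx)
            if all(0 <= q[i] < shape[i] for i in range(3)):
                yield q

    maxima = []
    for p in np.ndindex(shape):
        if v[p] < floor:
            continue
        if all(v[p] >= v[q] for q in neighbors(p)):
            maxima.append(p)
    maxima.sort(key=lambda p: (-v[p], p))
    claimed = set()
    out = []
    for peak in maxima:
        if peak in claimed:
            continue
        thresh = max(v[peak] - tol, floor)
        region = {peak}
        frontier = [peak]
        while frontier:
            cur = frontier.pop()
            for q in neighbors(cur):
                if q not in region and v[q] >= thresh:
                    region.add(q)
                    frontier.append(q)
        claimed |= region
        pts = np.array(sorted(region))
        w = np.array([v[tuple(p)] for p in pts])
        centroid = (w[:, None] * pts).sum(0) / w.sum()
        out.append((tuple(np.round(centroid, 6)), float(v[peak]), len(region)))
    return sorted(out, key=lambda c: (-c[1], c[0]))


class TestLocate:
    def test_single_point_peak(self):
        values = np.zeros((6, 6, 6), dtype=np.float32)
        values[3, 3, 3] = 0.9
        cands = locate(_smap(values), floor=0.5, tolerance=0.2)
        assert len(cands) == 1
        assert cands[0].region_size == 1
        assert cands[0].similarity == pytest.approx(0.9)
        # lattice (3,3,3) -> voxel 3*2 + 4
        assert cands[0].center == (10.0, 10.0, 10.0)

    def test_two_separated_peaks(self):
        values = np.zeros((8, 8, 8), dtype=np.float32)
        values[1, 1, 1] = 0.9
        values[6, 6, 6] = 0.9
        cands = locate(_smap(values), floor=0.5, tolerance=0.2)
        assert len(cands) == 2

    def test_constant_map_below_floor_is_empty(self):
        values = np.full((6, 6, 6), 0.3, dtype=np.float32)
        assert locate(_smap(values), floor=0.5, tolerance=0.1) == []

    def test_plateau_at_floor_fuses_to_single_candidate(self):
        values = np.full((5, 5, 5), 0.8, dtype=np.float32)
        cands = locate(_smap(values), floor=0.5, tolerance=0.1)
        assert len(cands) == 1
        assert cands[0].region_size == 125

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(-0.2, 1.0, size=(12, 12, 12)).astype(np.float32)
        cands = locate(_smap(values), floor=0.4, tolerance=0.1)
        oracle = _oracle_locate(values, 0.4, 0.1)
        got = sorted(
            ((tuple(np.round((np.asarray(c.center) - 4) / 2, 6)),
              float(np.float32(c.similarity)), c.region_size) for c in cands),
            key=lambda c: (-c[1], c[0]))
        assert len(got) == len(oracle)
        for (gc, gs, gn), (oc, os_, on) in zip(got, oracle):
            assert gn == on
            assert gs == pytest.approx(os_, abs=1e-5)
            assert np.allclose(gc, oc, atol=1e-4)

    def test_parameter_validation(self):
        values = np.zeros((4, 4, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            locate(_smap(values), floor=1.0)
        with pytest.raises(ValueError):
            locate(_smap(values), tolerance=-0.1)


# ---------------------------------------------------------------------- #
# NMS

def _oracle_nms(cands, box, thr):
    def iou(a, b):
        inter = 1.0
        for x, y in zip(a, b):
            o = box - abs(x - y)
            if o <= 0:
                return 0.0
            inter *= o
        return inter / (2 * box**3 - inter)

    ordered = sorted(cands, key=lambda c: (-c.similarity, c.center))
    kept = []
    for c in ordered:
        if all(iou(c.center, k.center) < thr for k in kept):
            kept.append(c)
    return kept


def _random_candidates(rng, n=20):
    return [Candidate(center=tuple(rng.uniform(0, 40, size=3)),
                      similarity=float(rng.uniform(0, 1)),
                      region_size=int(rng.integers(1, 30)))
            for _ in range(n)]


class TestNMS:
    def test_disjoint_candidates_all_kept(self):
        cands = [Candidate((0, 0, 0), 0.9, 1), Candidate((50, 50, 50), 0.8, 1)]
        assert len(nonmaxima_suppress(cands, 10, 0.6)) == 2

    def test_identical_centers_keep_best(self):
        cands = [Candidate((5, 5, 5), 0.8, 1), Candidate((5, 5, 5), 0.9, 1)]
        kept = nonmaxima_suppress(cands, 10, 0.6)
        assert len(kept) == 1
        assert kept[0].similarity == 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cands = _random_candidates(rng)
        got = nonmaxima_suppress(cands, 12, 0.6)
        assert got == _oracle_nms(cands, 12, 0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_is_antichain(self, seed):
        from tomopick.localize import _cube_iou
        rng = np.random.default_rng(40 + seed)
        kept = nonmaxima_suppress(_random_candidates(rng), 12, 0.6)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert _cube_iou(kept[i].center, kept[j].center, 12) < 0.6

    def test_adding_dominated_candidate_changes_nothing(self):
        rng = np.random.default_rng(99)
        cands = _random_candidates(rng, 10)
        kept = nonmaxima_suppress(cands, 12, 0.6)
        loser = Candidate(center=kept[0].center,
                          similarity=kept[0].similarity - 0.05, region_size=3)
        kept2 = nonmaxima_suppress(cands + [loser], 12, 0.6)
        assert kept == kept2


# ---------------------------------------------------------------------- #
# pick

class TestPick:
    def test_identity_filter(self):
        rng = np.random.default_rng(1)
        cands = _random_candidates(rng)
        kept = pick(cands, min_similarity=-1.0, size_min=0, size_max=np.inf)
        assert sorted(kept, key=id) == sorted(cands, key=id)

    def test_threshold_above_max_empties(self):
        rng = np.random.default_rng(2)
        assert pick(_random_candidates(rng), min_similarity=1.1) == []

    def test_predicate_recount(self):
        rng = np.random.default_rng(3)
        cands = _random_candidates(rng, 50)
        kept = pick(cands, min_similarity=0.4, size_min=5, size_max=20)
        expected = sum(1 for c in cands
                       if c.similarity >= 0.4 and 5 <= c.region_size <= 20)
        assert len(kept) == expected

    @given(st.floats(min_value=-1, max_value=1),
           st.floats(min_value=-1, max_value=1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotonicity_in_similarity(self, t1, t2):
        """Raising the threshold never adds picks."""
        rng = np.random.default_rng(7)
        cands = _random_candidates(rng, 30)
        lo, hi = sorted((t1, t2))
        kept_lo = {id(c) for c in pick(cands, min_similarity=lo)}
        kept_hi = {id(c) for c in pick(cands, min_similarity=hi)}
        assert kept_hi <= kept_lo

    def test_widening_size_band_never_removes(self):
        rng = np.random.default_rng(8)
        cands = _random_candidates(rng, 30)
        narrow = {id(c) for c in pick(cands, -1, size_min=10, size_max=15)}
        wide = {id(c) for c in pick(cands, -1, size_min=5, size_max=25)}
        assert narrow <= wide

    def test_invalid_size_band(self):
        with pytest.raises(ValueError):
            pick([], size_min=5, size_max=2)
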
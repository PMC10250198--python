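"""From embeddings to particle coordinates: Map, Locate, Pick.

Map computes, for each target embedding, the cosine similarity to every
window embedding, arranged on the stride lattice (a :class:`SimilarityMap`).
Locate finds 26-connected local maxima above a floor and grows each into a
tolerance-bounded region (flood fill); maxima whose regions merge are fused,
keeping the higher peak, and each candidate's center is the
similarity-weighted centroid of its region mapped back to tomogram voxels.
Candidates then pass greedy box-IoU non-maxima suppression and final
similarity / region-size thresholding into a :class:`PickTable`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .embedding import EmbeddingGrid, TargetEmbedding

__all__ = [
    "SimilarityMap",
    "Candidate",
    "map_targets",
    "locate",
    "nonmaxima_suppress",
    "pick",
    "picks_to_table",
]


@dataclass
class SimilarityMap:
    """Cosine similarities of one target against the window lattice."""

    target_label: str
    values: np.ndarray                    # lattice-shaped, in [-1, 1]
    box_len: int
    stride: int
    source_shape: tuple[int, int, int]

    def lattice_to_voxel(self, lattice_points: np.ndarray) -> np.ndarray:
        """Map (fractional) lattice coordinates to tomogram voxel coords."""
        return np.asarray(lattice_points, dtype=float) * self.stride + self.box_len // 2


@dataclass
class Candidate:
    center: tuple[float, float, float]    # (z, y, x) tomogram voxels
    similarity: float
    region_size: int                      # lattice points in the grown region

    def region_voxels(self, stride: int) -> int:
        """Region size rescaled from lattice points to voxels."""
        return self.region_size * stride**3


def map_targets(grid: EmbeddingGrid,
                targets: list[TargetEmbedding]) -> list[SimilarityMap]:
    """One similarity map per target; value = cos(target, window vector)."""
    if len(grid) == 0:
        raise ValueError("embedding grid is empty")
    lattice = grid.lattice_shape
    maps = []
    for target in targets:
        sims = grid.vectors @ np.asarray(target.vector, dtype=np.float32)
        maps.append(SimilarityMap(
            target_label=target.label,
            values=sims.reshape(lattice).astype(np.float32),
            box_len=grid.box_len, stride=grid.stride,
            source_shape=tuple(grid.source_shape)))
    return maps


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def locate(smap: SimilarityMap, floor: float = 0.5,
           tolerance: float = 0.2) -> list[Candidate]:
    """Region-growing maximum detection on a similarity map.

    1. Local maxima: lattice points >= all 26 neighbors and >= ``floor``.
    2. Maxima are visited in descending (value, -z, -y, -x) order; each
       grows the 26-connected region of points with value >=
       ``max(peak - tolerance, floor)``.  Any weaker maxima inside an
       already-grown region are absorbed into it (fusion keeps the higher
       peak).
    3. Candidate center = similarity-weighted centroid of the region,
       mapped to tomogram voxels; ``region_size`` is the region's lattice
       point count.
    """
    if not -1.0 <= floor < 1.0:
        raise ValueError("floor must be in [-1, 1)")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    v = smap.values
    is_max = (v == ndimage.maximum_filter(v, footprint=_CONN26,
                                          mode="constant", cval=-np.inf))
    is_max &= v >= floor
    peaks = np.argwhere(is_max)
    if len(peaks) == 0:
        return []
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0],
                        -v[tuple(peaks.T)]))
    peaks = peaks[order]

    claimed = np.zeros(v.shape, dtype=bool)
    candidates: list[Candidate] = []
    for pz, py, px in peaks:
        if claimed[pz, py, px]:
            continue  # absorbed into an earlier (higher) region
        peak_val = v[pz, py, px]
        thresh = max(peak_val - tolerance, floor)
        region_mask = _flood(v >= thresh, (pz, py, px))
        claimed |= region_mask
        pts = np.argwhere(region_mask)
        weights = v[tuple(pts.T)]
        wsum = float(weights.sum())
        centroid_lattice = (weights[:, None] * pts).sum(axis=0) / wsum
        center = smap.lattice_to_voxel(centroid_lattice)
        candidates.append(Candidate(center=tuple(float(c) for c in center),
                                    similarity=float(peak_val),
                                    region_size=int(len(pts))))
    return candidates


def _flood(mask: np.ndarray, seed) -> np.ndarray:
    """26-connected component of ``mask`` containing ``seed``."""
    labels, _ = ndimage.label(mask, structure=_CONN26)
    return labels == labels[seed]


def _cube_iou(center_a, center_b, box_len: int) -> float:
    inter = 1.0
    for a, b in zip(center_a, center_b):
        overlap = box_len - abs(a - b)
        if overlap <= 0:
            return 0.0
        inter *= overlap
    union = 2.0 * box_len**3 - inter
    return inter / union


def nonmaxima_suppress(candidates: list[Candidate], box_len: int,
                       iou_threshold: float = 0.6) -> list[Candidate]:
    """Greedy suppression: accept by descending similarity (ties broken by
    (z, y, x) lexicographic order) unless the candidate's cube overlaps an
    accepted cube with IoU >= threshold."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    ordered = sorted(candidates, key=lambda c: (-c.similarity, c.center))
    kept: list[Candidate] = []
    for cand in ordered:
        if all(_cube_iou(cand.center, k.center, box_len) < iou_threshold
               for k in kept):
            kept.append(cand)
    return kept


def pick(candidates: list[Candidate], min_similarity: float = 0.5,
         size_min: int = 1, size_max: float = np.inf) -> list[Candidate]:
    """Final confidence and size thresholding, sorted by similarity."""
    if size_min > size_max:
        raise ValueError("size_min must be <= size_max")
    kept = [c for c in candidates
            if c.similarity >= min_similarity and size_min <= c.region_size <= size_max]
    return sorted(kept, key=lambda c: (-c.similarity, c.center))


def picks_to_table(picks: list[Candidate], label: str) -> pd.DataFrame:
    """PickTable rows: label, x, y, z, similarity, region size (lattice)."""
    rows = [{"target_label": label,
             "x": c.center[2], "y": c.center[1], "z": c.center[0],
             "similarity": c.similarity, "region_size": c.region_size}
            for c in picks]
    return pd.DataFrame(rows, columns=["target_label", "x", "y", "z",
                                       "similarity", "region_size"])
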
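"""Sliding-window tomogram embedding.

A tomogram is subdivided into overlapping cubic subvolumes on a regular
stride lattice; each subvolume is z-score normalized and embedded by the
network, yielding one unit vector per lattice point (an
:class:`EmbeddingGrid`).  Reference particles are embedded the same way to
produce :class:`TargetEmbedding` vectors.

Coordinate conventions: arrays are indexed (z, y, x), 0-based,
voxel-centered.  Window *origins* are the low corner; window *centers* are
``origin + box_len // 2`` per axis.  Windows must fit entirely inside the
volume — the outer shell of voxels that cannot host a full window is never
embedded and therefore unpickable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingGrid",
    "TargetEmbedding",
    "iter_windows",
    "window_counts",
    "normalize_subvolume",
    "embed_tomogram",
    "embed_reference",
]


@dataclass
class EmbeddingGrid:
    """One unit vector per sliding-window lattice point."""

    positions: np.ndarray        # (n, 3) window-center (z, y, x) voxels
    vectors: np.ndarray          # (n, out_dim) unit rows, iterator order
    box_len: int
    stride: int
    source_shape: tuple[int, int, int]

    def __post_init__(self):
        if len(self.positions) != len(self.vectors):
            raise ValueError("positions and vectors disagree in length")

    def __len__(self):
        return len(self.positions)

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        return window_counts(self.source_shape, self.box_len, self.stride)


@dataclass(frozen=True)
class TargetEmbedding:
    """A labeled unit vector marking one macromolecule's region of
    embedding space; provenance records whether it came from a reference
    coordinate or a selected cluster."""

    label: str
    vector: np.ndarray
    provenance: str = "reference"

    def __post_init__(self):
        norm = float(np.linalg.norm(self.vector))
        if abs(norm - 1.0) > 1e-4:
            raise ValueError(f"target embedding is not unit norm ({norm:.6f})")


def window_counts(shape, box_len: int, stride: int) -> tuple[int, int, int]:
    """Per-axis window counts: floor((dim - box) / stride) + 1."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    for dim in shape:
        if dim < box_len:
            raise ValueError(f"volume dim {dim} smaller than box_len {box_len}")
    return tuple((dim - box_len) // stride + 1 for dim in shape)


def iter_windows(shape, box_len: int, stride: int) -> np.ndarray:
    """All window origins in raster order (z-major), as an (n, 3) array."""
    counts = window_counts(shape, box_len, stride)
    oz = np.arange(counts[0]) * stride
    oy = np.arange(counts[1]) * stride
    ox = np.arange(counts[2]) * stride
    zz, yy, xx = np.meshgrid(oz, oy, ox, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def normalize_subvolume(cube: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-subvolume z-score; returns ``(normalized, degenerate)``.

    A constant cube (for example an empty-ice window) cannot be z-scored;
    it is returned as all zeros with ``degenerate=True``.  Normalization is
    invariant to positive affine intensity maps, which makes downstream
    picking robust to linear intensity scaling between tomograms.
    """
    cube = np.asarray(cube, dtype=np.float32)
    std = float(cube.std())
    # relative threshold: float32 summation noise on a constant cube leaves
    # a residual std of order eps * |mean|
    if std <= 1e-6 * (1.0 + abs(float(cube.mean()))):
        return np.zeros_like(cube), True
    return (cube - cube.mean()) / std, False


def embed_tomogram(tomogram, model, box_len: int | None = None,
                   stride: int = 4, batch_size: int = 64) -> EmbeddingGrid:
    """Extract -> normalize -> embed every sliding window of a tomogram.

    ``tomogram`` may be a raw 3D array or a :class:`~tomopick.synthetic.Tomogram`.
    Vectors are stored in iterator (raster) order; results are independent
    of ``batch_size``.
    """
    grid = np.asarray(getattr(tomogram, "grid", tomogram), dtype=np.float32)
    box_len = box_len or model.config.in_box
    if box_len != model.config.in_box:
        raise ValueError(
            f"box_len {box_len} does not match the model in_box {model.config.in_box}")
    origins = iter_windows(grid.shape, box_len, stride)
    vectors = np.empty((len(origins), model.config.out_dim), dtype=np.float32)
    batch = np.empty((batch_size, box_len, box_len, box_len), dtype=np.float32)
    for start in range(0, len(origins), batch_size):
        chunk = origins[start:start + batch_size]
        for i, (z, y, x) in enumerate(chunk):
            cube = grid[z:z + box_len, y:y + box_len, x:x + box_len]
            batch[i], _ = normalize_subvolume(cube)
        vectors[start:start + len(chunk)] = model.embed(
            batch[:len(chunk)], batch_size=batch_size)
    centers = origins + box_len // 2
    return EmbeddingGrid(positions=centers, vectors=vectors, box_len=box_len,
                         stride=stride, source_shape=grid.shape)


def embed_reference(tomogram, center_xyz, model, box_len: int | None = None,
                    label: str = "reference") -> TargetEmbedding:
    """Embed the subvolume centered on one picked particle.

    ``center_xyz`` follows the on-disk convention (x, y, z) in voxels.
    """
    grid = np.asarray(getattr(tomogram, "grid", tomogram), dtype=np.float32)
    box_len = box_len or model.config.in_box
    if box_len != model.config.in_box:
        raise ValueError(
            f"box_len {box_len} does not match the model in_box {model.config.in_box}")
    x, y, z = (int(round(v)) for v in center_xyz)
    r = box_len // 2
    lo = (r, r, r)
    hi = tuple(d - 1 - r for d in grid.shape)
    if not (lo[0] <= z <= hi[0] and lo[1] <= y <= hi[1] and lo[2] <= x <= hi[2]):
        raise ValueError(
            f"reference center (x={x}, y={y}, z={z}) too close to the edge; "
            f"admissible centers are x in [{lo[2]}, {hi[2]}], "
            f"y in [{lo[1]}, {hi[1]}], z in [{lo[0]}, {hi[0]}]")
    cube = grid[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1]
    normalized, degenerate = normalize_subvolume(cube)
    if degenerate:
        raise ValueError("reference subvolume is constant; cannot embed")
    vec = model.embed(normalized[None])[0]
    return TargetEmbedding(label=label, vector=vec, provenance="reference")
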
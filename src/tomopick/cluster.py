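"""De novo (clustering) workflow support.

Tomogram embeddings are subsampled, projected to a 2D manifold (UMAP by
default), and a cluster of interest is selected by a closed polygon in the
2D plane.  The selected points are traced back to their original
high-dimensional embeddings, whose mean (re-normalized to unit length)
becomes a target embedding used exactly like a reference target.

Polygon membership uses the even-odd (ray-crossing) rule, with boundary
points counted as inside; self-intersecting polygons are accepted and
interpreted under the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingGrid, TargetEmbedding

__all__ = [
    "ManifoldProjection",
    "PolygonSelection",
    "subsample_embeddings",
    "fit_manifold_2d",
    "select_polygon",
    "cluster_target",
]


@dataclass
class ManifoldProjection:
    coords2d: np.ndarray          # (n, 2)
    row_index: np.ndarray         # (n,) rows into the source EmbeddingGrid
    method: str = "umap"
    seed: int = 0
    transform: object = None      # fitted reducer for out-of-sample rows

    def __post_init__(self):
        if len(self.coords2d) != len(self.row_index):
            raise ValueError("coords2d and row_index disagree in length")


@dataclass
class PolygonSelection:
    vertices: np.ndarray          # (k >= 3, 2) ordered (u, v)
    selected_rows: np.ndarray     # grid row indices inside the polygon


def subsample_embeddings(grid: EmbeddingGrid, n: int = 400_000,
                         seed: int = 0) -> np.ndarray:
    """min(n, len(grid)) distinct row indices, uniform without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = min(n, len(grid))
    return np.sort(rng.choice(len(grid), size=k, replace=False))


def fit_manifold_2d(vectors: np.ndarray, row_index=None, seed: int = 0,
                    method: str = "umap", **method_params) -> ManifoldProjection:
    """Fit a 2D manifold projection (UMAP) of embedding vectors.

    The fitted reducer is kept on the projection so remaining grid rows can
    be transformed into the same plane.  Reproducible per seed (the UMAP
    random state is pinned, which also forces its single-threaded exact
    path).
    """
    vectors = np.asarray(vectors, dtype=np.float32)
    if len(vectors) < 10:
        raise ValueError("need at least 10 vectors to fit a 2D manifold")
    if row_index is None:
        row_index = np.arange(len(vectors))
    if method != "umap":
        raise ValueError(f"unknown manifold method {method!r}")
    import umap  # deferred: heavy import

    params = {"n_components": 2, "n_neighbors": 15, "min_dist": 0.1,
              "random_state": seed}
    params.update(method_params)
    reducer = umap.UMAP(**params)
    coords = reducer.fit_transform(vectors)
    return ManifoldProjection(coords2d=np.asarray(coords, dtype=np.float64),
                              row_index=np.asarray(row_index),
                              method=method, seed=seed, transform=reducer)


def points_in_polygon(points: np.ndarray, vertices: np.ndarray,
                      eps: float = 1e-9) -> np.ndarray:
    """Even-odd ray-crossing membership test; boundary counts as inside."""
    points = np.asarray(points, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    u, v = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    k = len(verts)
    for i in range(k):
        (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % k]
        # boundary test: point on segment
        dx, dy = x2 - x1, y2 - y1
        cross = (u - x1) * dy - (v - y1) * dx
        seg2 = dx * dx + dy * dy
        t = ((u - x1) * dx + (v - y1) * dy) / seg2 if seg2 > 0 else np.zeros_like(u)
        on_edge |= (np.abs(cross) <= eps * max(1.0, np.sqrt(seg2))) & \
                   (t >= -eps) & (t <= 1 + eps)
        # crossing test (half-open edge rule avoids double-counting vertices)
        crosses = ((y1 > v) != (y2 > v)) & \
                  (u < x1 + (v - y1) * dx / np.where(dy == 0, np.inf, dy))
        inside ^= crosses
    return inside | on_edge


def select_polygon(projection: ManifoldProjection,
                   vertices: np.ndarray) -> PolygonSelection:
    """Rows of the projection whose 2D points fall inside the polygon."""
    vertices = np.asarray(vertices, dtype=float)
    mask = points_in_polygon(projection.coords2d, vertices)
    return PolygonSelection(vertices=vertices,
                            selected_rows=projection.row_index[mask])


def cluster_target(grid: EmbeddingGrid, selected_rows, label: str
                   ) -> TargetEmbedding:
    """Mean of the selected high-dimensional embeddings, re-normalized.

    Re-normalization restores the unit-norm invariant; because picking uses
    cosine similarity it changes no ranking.  Nearly antipodal selections
    whose mean cancels out are rejected.
    """
    selected_rows = np.asarray(selected_rows)
    if len(selected_rows) == 0:
        raise ValueError("no rows selected for the cluster target")
    mean = grid.vectors[selected_rows].mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < 1e-6:
        raise ValueError(
            "selected embeddings cancel out (mean norm ~ 0); "
            "draw a tighter selection")
    return TargetEmbedding(label=label, vector=(mean / norm).astype(np.float32),
                           provenance="cluster")
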
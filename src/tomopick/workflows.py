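"""The two end-to-end picking workflows.

Reference-based: embed the tomogram, embed one example particle per species,
map cosine similarity, locate candidate maxima, suppress overlaps, threshold
into a pick table.

Clustering (de novo): embed the tomogram, subsample, fit a 2D manifold,
select clusters by polygon, average each selection into a target embedding,
then map/locate/suppress/threshold exactly as above.

Both workflows can be restarted from a precomputed embedding grid (the
costly stage) and write a machine-readable run manifest when given an
output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (ManifoldProjection, cluster_target, fit_manifold_2d,
                      select_polygon, subsample_embeddings)
from .embedding import EmbeddingGrid, embed_reference, embed_tomogram
from .localize import locate, map_targets, nonmaxima_suppress, pick, picks_to_table

__all__ = ["PickingParams", "run_reference_workflow", "run_clustering_workflow"]


@dataclass(frozen=True)
class PickingParams:
    """Thresholds shared by both workflows (all CLI-exposed).

    ``auto_size_band``, when set to ``(lo, hi)``, derives each target's
    size window from its best-matching candidate's region size S as
    ``[lo * S, hi * S]`` (intersected with ``size_min``/``size_max``) — the
    headless analogue of tuning the size threshold per species from an
    example particle.  ``exclusive`` assigns contested locations (pick
    cubes overlapping across labels with IoU >= ``exclusive_iou``) to the
    higher-similarity label.
    """

    stride: int = 4
    floor: float = 0.5
    tolerance: float = 0.2
    nms_iou: float = 0.6
    min_similarity: float = 0.5
    size_min: int = 1
    size_max: float = float("inf")
    auto_size_band: tuple[float, float] | None = None
    batch_size: int = 64
    exclusive: bool = False
    exclusive_iou: float = 0.15


def _pick_one(smap, box_len: int, params: PickingParams):
    candidates = locate(smap, floor=params.floor, tolerance=params.tolerance)
    candidates = nonmaxima_suppress(candidates, box_len, params.nms_iou)
    size_min, size_max = params.size_min, params.size_max
    if params.auto_size_band and candidates:
        anchor = max(candidates, key=lambda c: c.similarity)
        lo, hi = params.auto_size_band
        size_min = max(size_min, int(np.floor(lo * anchor.region_size)))
        size_max = min(size_max, int(np.ceil(hi * anchor.region_size)))
    return pick(candidates, params.min_similarity, size_min, size_max)


def _exclusive_filter(tables: dict[str, pd.DataFrame], box_len: int,
                      exclusive_iou: float) -> dict[str, pd.DataFrame]:
    """Assign contested locations (overlapping across labels) to the
    higher-similarity label.

    The contest criterion is deliberately looser than same-label NMS:
    different targets localize the same particle with slightly different
    centroids, so even modest cube overlap marks a contested location.
    """
    combined = pd.concat(tables.values(), ignore_index=True)
    combined = combined.sort_values(["similarity", "z", "y", "x"],
                                    ascending=[False, True, True, True])
    kept_centers: list[tuple[float, float, float]] = []
    keep_mask = []
    from .localize import _cube_iou
    for _, row in combined.iterrows():
        c = (row["z"], row["y"], row["x"])
        ok = all(_cube_iou(c, kc, box_len) < exclusive_iou
                 for kc in kept_centers)
        keep_mask.append(ok)
        if ok:
            kept_centers.append(c)
    combined = combined[np.asarray(keep_mask)]
    return {label: combined[combined["target_label"] == label]
            .reset_index(drop=True) for label in tables}


def _manifest(out_dir, stage_timings: dict, seed, params, inputs: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tomopick_version": __version__,
        "seed": seed,
        "params": {k: (v if np.isfinite(v) else "inf") if isinstance(v, float) else v
                   for k, v in vars(params).items()} if hasattr(params, "__dict__")
                  else {k: str(v) for k, v in params.__dataclass_fields__.items()},
        "stage_seconds": {k: round(v, 3) for k, v in stage_timings.items()},
        "inputs": inputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))


def run_reference_workflow(tomogram, model, reference_coords: dict,
                           params: PickingParams = PickingParams(),
                           grid: EmbeddingGrid | None = None,
                           out_dir=None, seed: int = 0
                           ) -> dict[str, pd.DataFrame]:
    """Pick particles from one reference coordinate per species.

    ``reference_coords`` maps label -> (x, y, z) voxel coordinate of one
    example particle.  Returns a PickTable per label.
    """
    timings = {}
    t0 = time.perf_counter()
    if grid is None:
        grid = embed_tomogram(tomogram, model, stride=params.stride,
                              batch_size=params.batch_size)
    timings["embed"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    targets = [embed_reference(tomogram, xyz, model, label=label)
               for label, xyz in reference_coords.items()]
    timings["embed_ref"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    maps = map_targets(grid, targets)
    tables = {}
    for smap in maps:
        picks = _pick_one(smap, grid.box_len, params)
        tables[smap.target_label] = picks_to_table(picks, smap.target_label)
    timings["map_locate_pick"] = time.perf_counter() - t0
    if params.exclusive and len(tables) > 1:
        tables = _exclusive_filter(tables, grid.box_len, params.exclusive_iou)

    if out_dir is not None:
        _write_outputs(out_dir, tables, timings, seed, params,
                       {"workflow": "reference",
                        "references": {k: list(map(int, v))
                                       for k, v in reference_coords.items()}})
    return tables


def run_clustering_workflow(tomogram, model, polygons: dict,
                            params: PickingParams = PickingParams(),
                            grid: EmbeddingGrid | None = None,
                            projection: ManifoldProjection | None = None,
                            subsample_n: int = 400_000, seed: int = 0,
                            out_dir=None,
                            ) -> tuple[dict[str, pd.DataFrame], ManifoldProjection]:
    """De novo picking from 2D-manifold polygon selections.

    ``polygons`` maps label -> (k, 2) vertex array in the projection plane.
    Returns (PickTable per label, the fitted projection).
    """
    timings = {}
    t0 = time.perf_counter()
    if grid is None:
        grid = embed_tomogram(tomogram, model, stride=params.stride,
                              batch_size=params.batch_size)
    timings["embed"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if projection is None:
        rows = subsample_embeddings(grid, n=subsample_n, seed=seed)
        projection = fit_manifold_2d(grid.vectors[rows], row_index=rows,
                                     seed=seed)
    timings["manifold"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables = {}
    for label, vertices in polygons.items():
        selection = select_polygon(projection, vertices)
        if len(selection.selected_rows) == 0:
            raise ValueError(f"polygon {label!r} selects no points")
        target = cluster_target(grid, selection.selected_rows, label)
        smap = map_targets(grid, [target])[0]
        picks = _pick_one(smap, grid.box_len, params)
        tables[label] = picks_to_table(picks, label)
    timings["select_map_pick"] = time.perf_counter() - t0
    if params.exclusive and len(tables) > 1:
        tables = _exclusive_filter(tables, grid.box_len, params.exclusive_iou)

    if out_dir is not None:
        _write_outputs(out_dir, tables, timings, seed, params,
                       {"workflow": "clustering",
                        "polygons": {k: np.asarray(v).tolist()
                                     for k, v in polygons.items()}})
    return tables, projection


def _write_outputs(out_dir, tables, timings, seed, params, inputs):
    from .io import write_picks
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combined = (pd.concat(tables.values(), ignore_index=True)
                if tables else pd.DataFrame())
    write_picks(out_dir / "picks_combined.coords", combined)
    for label, table in tables.items():
        write_picks(out_dir / f"picks_{label}.coords", table)
    _manifest(out_dir, timings, seed, params, inputs)
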
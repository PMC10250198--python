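"""Shared fixtures.

The expensive session fixture (`trained_pipeline`) trains the reduced
profile network on scene-derived subvolume pools and runs both picking
workflows on a held-out synthetic tomogram; it is computed once and shared
by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tomopick.network import EmbeddingNetwork, NetworkConfig, desk_config
from tomopick.synthetic import (SceneConfig, make_shape_library,
                                make_scene_pools, simulate_scene)

# fixture study conditions: 6 procedural species in a 17-voxel box spanning
# a wide size ladder, a 60 degree wedge, noise sigma 0.2 (within the
# U(0, 0.3) range the augmentation recipe treats as realistic); classes 1-5
# trained (plus the background class 0), class 6 held out for the
# generalization check; 150 scene-extracted subvolumes per class split
# 120/30; rotation-only augmentation, wide margins; 35 epochs.  The
# held-out picking scene contains the five trained species.
FIXTURE = {
    "n_classes": 6, "shape_box": 17, "shape_seed": 11,
    "subvolume_box": 17, "pool_scene_dims": (72, 72, 72),
    "noise_sigma": 0.2, "pool_seed": 5,
    "n_per_class": 150, "n_train": 120, "n_val": 30,
    "epochs": 35, "train_seed": 3, "lr": 1e-3, "margin": 0.8,
    "scene_dims": (96, 96, 96), "scene_counts": 8, "scene_seed": 42,
    "min_separation": 16.0, "stride": 3, "scene_edge_margin": 4,
    "umap_subsample": 8000,
}


@pytest.fixture(scope="session")
def shape_library():
    return make_shape_library(FIXTURE["n_classes"], FIXTURE["shape_box"],
                              seed=FIXTURE["shape_seed"])


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network for shape/round-trip tests."""
    cfg = NetworkConfig(in_box=9, base_channels=2, n_blocks=2, groups=2,
                        dropout_rate=0.0, out_dim=8, head_widths=(16,))
    return EmbeddingNetwork(cfg, seed=1)


@pytest.fixture(scope="session")
def desk_model():
    """Untrained desk-profile network (in_box 17)."""
    return EmbeddingNetwork(desk_config(), seed=1)


@pytest.fixture(scope="session")
def small_scene(shape_library):
    """A 64-cube scene with 3 classes x 4 particles, fixed seed."""
    config = SceneConfig(dims=(64, 64, 64), counts={1: 4, 2: 4, 3: 4},
                         min_separation=15.0,
                         noise_sigma=FIXTURE["noise_sigma"], seed=21)
    tomo, clean, occupancy, records = simulate_scene(config, shape_library)
    return {"config": config, "tomogram": tomo, "clean": clean,
            "occupancy": occupancy, "records": records}


def _train_fixture_model(shape_library):
    from tomopick.metric import (AugmentationConfig, TrainConfig,
                                 split_dataset, train)
    pools = make_scene_pools(shape_library, FIXTURE["n_per_class"],
                             FIXTURE["subvolume_box"],
                             scene_dims=FIXTURE["pool_scene_dims"],
                             noise_sigma=FIXTURE["noise_sigma"],
                             seed=FIXTURE["pool_seed"])
    train_pools = {c: pools[c] for c in range(0, 6)}   # 0 = background
    dataset = split_dataset(train_pools, FIXTURE["n_train"],
                            FIXTURE["n_val"], seed=FIXTURE["pool_seed"])
    aug = AugmentationConfig(rotate_xy=True, use_dropout=False,
                             use_shift=False, use_noise=False)
    tcfg = TrainConfig(epochs=FIXTURE["epochs"],
                       learning_rate=FIXTURE["lr"],
                       margin_alpha=FIXTURE["margin"],
                       margin_miner=FIXTURE["margin"],
                       seed=FIXTURE["train_seed"], augmentation=aug)
    model, history = train(dataset, desk_config(), tcfg)
    return model, history, pools, dataset


#: picking parameters of the fixture runs: similarity floor 0.8, size band
#: derived per target from its best candidate, contested locations assigned
#: exclusively to the best label
def _fixture_params():
    from tomopick.workflows import PickingParams
    return PickingParams(stride=FIXTURE["stride"], min_similarity=0.75,
                         auto_size_band=(0.3, 3.0), exclusive=True)


@pytest.fixture(scope="session")
def trained_pipeline(shape_library):
    """Desk-scale parameter-recovery fixture: train on classes 1-5 (+
    background), then run both workflows on a held-out 96-cube tomogram
    containing the five trained species."""
    from scipy.spatial import ConvexHull

    from tomopick.cluster import fit_manifold_2d
    from tomopick.embedding import embed_tomogram
    from tomopick.evaluate import evaluate_classes, match_picks
    from tomopick.workflows import (run_clustering_workflow,
                                    run_reference_workflow)

    model, history, pools, dataset = _train_fixture_model(shape_library)

    # held-out 6th class separability, measured on pool subvolumes
    emb6 = model.embed(np.stack(pools[6][:30]))
    within = float((emb6 @ emb6.T)[~np.eye(len(emb6), dtype=bool)].mean())
    cross = float(np.mean([
        (emb6 @ model.embed(np.stack(pools[c][120:150])).T).mean()
        for c in range(1, 6)]))

    # particles are kept a few voxels inside the sliding-window lattice's
    # reach: the outer shell of a tomogram is unpickable by construction
    scene = SceneConfig(dims=FIXTURE["scene_dims"],
                        counts={c: FIXTURE["scene_counts"]
                                for c in range(1, 6)},
                        min_separation=FIXTURE["min_separation"],
                        noise_sigma=FIXTURE["noise_sigma"],
                        seed=FIXTURE["scene_seed"],
                        edge_margin=FIXTURE["scene_edge_margin"])
    tomo, clean, occupancy, records = simulate_scene(scene, shape_library)
    params = _fixture_params()
    grid = embed_tomogram(tomo, model, stride=params.stride)

    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.class_id, []).append(rec.center)

    # reference workflow: one admissible example particle per species
    box = grid.box_len
    margin = box // 2
    hi = np.asarray(scene.dims) - 1 - margin
    reference_coords = {}
    for c in range(1, 6):
        for ctr in by_class[c]:
            if all(margin <= v <= h for v, h in zip(ctr, hi)):
                reference_coords[str(c)] = (ctr[2], ctr[1], ctr[0])
                break
    tables = run_reference_workflow(tomo, model, reference_coords,
                                    params=params, grid=grid)
    picks_by = {int(c): t[["z", "y", "x"]].to_numpy() for c, t in tables.items()}
    sims_by = {int(c): t["similarity"].to_numpy() for c, t in tables.items()}
    reference_scores = evaluate_classes(
        picks_by, {c: by_class[c] for c in range(1, 6)}, box_len=box,
        similarities_by_class=sims_by)

    # clustering workflow for class 1: polygon = expanded convex hull of
    # the projected true class-1 windows (stands in for the lasso); the
    # manifold is fit on a seeded subsample, as in the full-scale recipe
    from tomopick.cluster import subsample_embeddings
    sub = subsample_embeddings(grid, n=FIXTURE["umap_subsample"], seed=7)
    projection = fit_manifold_2d(grid.vectors[sub], row_index=sub, seed=7)
    def _true_rows(radius):
        return [k for k, i in enumerate(projection.row_index)
                if any(np.abs(grid.positions[i] - np.asarray(ctr)).max()
                       <= radius for ctr in by_class[1])]
    sel = _true_rows(2)
    if len(sel) < 8:
        sel = _true_rows(3)
    pts = projection.coords2d[sel]
    hull = ConvexHull(pts)
    centroid = pts.mean(axis=0)
    vertices = centroid + 1.15 * (pts[hull.vertices] - centroid)
    cluster_tables, _ = run_clustering_workflow(
        tomo, model, {"cluster1": vertices}, params=params, grid=grid,
        projection=projection, seed=7)
    ct = cluster_tables["cluster1"]
    cc = ct[["z", "y", "x"]].to_numpy()
    ss = ct["similarity"].to_numpy()
    m = match_picks(cc, picks_by[1], box_len=box, similarities=ss)
    denom = len(cc) + len(picks_by[1]) - m.true_positive
    jaccard = m.true_positive / denom if denom else 0.0

    return {"model": model, "history": history, "library": shape_library,
            "scene": scene, "tomogram": tomo, "records": records,
            "grid": grid, "separability": {"within": within, "cross": cross},
            "reference_scores": reference_scores, "reference_picks": tables,
            "cluster_picks": ct, "jaccard": jaccard,
            "projection": projection, "by_class": by_class}


@pytest.fixture(scope="session")
def determinism_runs(shape_library, tmp_path_factory):
    """Two reduced end-to-end runs with the same master seed: a short
    training, an embedding table, and a pick table, each written to disk."""
    from tomopick.embedding import embed_reference, embed_tomogram
    from tomopick.io import write_embeddings, write_picks
    from tomopick.localize import (locate, map_targets, nonmaxima_suppress,
                                   pick, picks_to_table)
    from tomopick.metric import (AugmentationConfig, TrainConfig,
                                 split_dataset, train)

    pools = make_scene_pools(shape_library[:3], 16, 17,
                             noise_sigma=FIXTURE["noise_sigma"], seed=2)
    dataset = split_dataset({c: pools[c] for c in (0, 1, 2, 3)}, 12, 4,
                            seed=2)
    scene = SceneConfig(dims=(48, 48, 48), counts={1: 3, 2: 3},
                        min_separation=15.0,
                        noise_sigma=FIXTURE["noise_sigma"], seed=9)
    tomo, _, _, records = simulate_scene(scene, shape_library)

    runs = []
    for run in ("a", "b"):
        out = tmp_path_factory.mktemp(f"det_{run}")
        aug = AugmentationConfig(rotate_xy=True, use_dropout=False,
                                 use_shift=False, use_noise=False)
        model, history = train(dataset, desk_config(),
                               TrainConfig(epochs=2, seed=4, augmentation=aug))
        history.to_csv(out / "history.csv", index=False)
        grid = embed_tomogram(tomo, model, stride=4)
        write_embeddings(out / "emb.tsv", grid)
        z, y, x = next(r.center for r in records
                       if all(8 <= v <= 39 for v in r.center))
        target = embed_reference(tomo, (x, y, z), model, label="r")
        smap = map_targets(grid, [target])[0]
        cands = nonmaxima_suppress(locate(smap, 0.0, 0.2), grid.box_len, 0.6)
        table = picks_to_table(pick(cands, 0.0, 1, np.inf), "r")
        write_picks(out / "picks.coords", table)
        runs.append({
            "history_bytes": (out / "history.csv").read_bytes(),
            "embedding_bytes": (out / "emb.tsv").read_bytes(),
            "picks_bytes": (out / "picks.coords").read_bytes()})
    return tuple(runs)
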
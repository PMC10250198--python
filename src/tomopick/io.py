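"""On-disk formats: MRC volumes, coordinate tables, embedding tables.

All coordinate tables use columns ``x y z`` in voxels (the common
picking-tool convention); internal arrays are (z, y, x).  MRC volumes are
written as MRC2014 mode-2 float with the voxel size in the header, via
gemmi's CCP4/MRC map support.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .embedding import EmbeddingGrid
from .synthetic import GroundTruthRecord, Tomogram

__all__ = [
    "write_mrc", "read_mrc",
    "write_ground_truth", "read_ground_truth",
    "write_picks", "read_picks",
    "write_embeddings", "read_embeddings",
    "file_sha256",
]


# ---------------------------------------------------------------------- #
# MRC volumes

def write_mrc(path, volume: np.ndarray, voxel_size: float = 10.0) -> None:
    """Write a (z, y, x) volume as an MRC2014 mode-2 float map."""
    vol = np.ascontiguousarray(np.asarray(volume, dtype=np.float32))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(vol)
    m.grid.unit_cell = gemmi.UnitCell(
        vol.shape[0] * voxel_size, vol.shape[1] * voxel_size,
        vol.shape[2] * voxel_size, 90.0, 90.0, 90.0)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> Tomogram:
    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True)
    return Tomogram(grid.astype(np.float64), voxel_size=float(m.grid.spacing[0]))


# ---------------------------------------------------------------------- #
# ground truth

_GT_COLUMNS = ["X", "Y", "Z", "class", "width", "height", "depth"]


def write_ground_truth(path, records: list[GroundTruthRecord]) -> None:
    """Tab-separated ``X Y Z class width height depth`` with a '#' header."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GT_COLUMNS) + "\n")
        for r in records:
            z, y, x = r.center
            fh.write(f"{x}\t{y}\t{z}\t{r.class_id}\t"
                     f"{r.box_len}\t{r.box_len}\t{r.box_len}\n")


def read_ground_truth(path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1,
                     names=_GT_COLUMNS)
    return [GroundTruthRecord(int(r["class"]),
                              (int(r["Z"]), int(r["Y"]), int(r["X"])),
                              int(r["width"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------- #
# picks

def write_picks(path, table: pd.DataFrame) -> None:
    """Combined PickTable as a tab-separated ``.coords`` file.

    Floats are written with fixed precision so identical runs produce
    byte-identical files.
    """
    out = table.copy()
    for col in ("x", "y", "z", "similarity"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_picks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------- #
# embeddings

def write_embeddings(path, grid: EmbeddingGrid, extra_meta: dict | None = None) -> None:
    """One row per window: X Y Z then the vector; '#key: value' metadata."""
    meta = {"box_len": grid.box_len, "stride": grid.stride,
            "source_shape": ",".join(map(str, grid.source_shape))}
    meta.update(extra_meta or {})
    dim = grid.vectors.shape[1]
    cols = ["X", "Y", "Z"] + [f"e{i:02d}" for i in range(dim)]
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}: {v}\n")
        fh.write("\t".join(cols) + "\n")
        for pos, vec in zip(grid.positions, grid.vectors):
            z, y, x = pos
            fh.write(f"{x}\t{y}\t{z}\t" +
                     "\t".join(f"{v:.6f}" for v in vec) + "\n")


def read_embeddings(path) -> EmbeddingGrid:
    meta = {}
    with open(path) as fh:
        while True:
            offset = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        fh.seek(offset)
        df = pd.read_csv(fh, sep="\t")
    positions = df[["Z", "Y", "X"]].to_numpy(dtype=int)
    vec_cols = [c for c in df.columns if c.startswith("e")]
    vectors = df[vec_cols].to_numpy(dtype=np.float32)
    return EmbeddingGrid(
        positions=positions, vectors=vectors,
        box_len=int(meta["box_len"]), stride=int(meta["stride"]),
        source_shape=tuple(int(v) for v in meta["source_shape"].split(",")))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
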
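"""The 3D convolutional embedding network.

Maps a single-channel cubic subvolume to a unit vector on a 32-dimensional
hypersphere.  The trunk is a stack of convolutional blocks — each block is
two 3x3x3 convolutions (the first doubles the channel count, the second
preserves it), every convolution followed by group normalization and a leaky
rectifier — with 2x2x2 max pooling after the first block and adaptive max
pooling to 2x2x2 after the last.  With the default configuration (five
blocks, 64 base channels) a 37x37x37 input becomes a 2x2x2x1024 feature
tensor.  The head flattens that tensor, applies dropout and a stack of fully
connected layers down to ``out_dim``, and L2-normalizes the result.

Two ready-made profiles are provided:

``default_config``
    The full-size architecture (in_box 37, 5 blocks, base 64, head
    2048-512-32).
``desk_config``
    A reduced CPU-friendly profile (in_box 17, 3 blocks, base 8, head
    128-64-32) used by the shipped training fixtures and tests.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "NetworkConfig",
    "EmbeddingNetwork",
    "default_config",
    "desk_config",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the output width of the first block; each later
    block doubles it, so the trunk emits ``base_channels * 2**(n_blocks-1)``
    channels.  ``groups`` is the group-normalization group count, clamped to
    the channel count of each layer.
    """

    in_box: int = 37
    base_channels: int = 64
    n_blocks: int = 5
    norm: str = "group"
    groups: int = 64
    dropout_rate: float = 0.2
    out_dim: int = 32
    negative_slope: float = 0.1
    head_widths: tuple[int, ...] = (2048, 512)

    def __post_init__(self):
        if self.out_dim < 2:
            raise ValueError("out_dim must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.norm != "group":
            raise ValueError(f"unsupported normalization kind: {self.norm!r}")
        # after the single stride-2 pool the grid must still support the
        # 2x2x2 adaptive pool and the 3^3 receptive fields of the deep blocks
        if self.in_box < 9 or self.in_box // 2 < 2:
            raise ValueError(
                f"in_box={self.in_box} too small for {self.n_blocks} blocks; "
                "need in_box >= 9")

    @property
    def trunk_channels(self) -> int:
        return self.base_channels * 2 ** (self.n_blocks - 1)


def default_config() -> NetworkConfig:
    """The full-size architecture: 37^3 input -> 2x2x2x1024 -> 32-vector."""
    return NetworkConfig()


def desk_config() -> NetworkConfig:
    """Reduced profile for CPU-scale training and tests."""
    return NetworkConfig(in_box=17, base_channels=8, n_blocks=3, groups=8,
                         dropout_rate=0.1, head_widths=(128, 64))


class EmbeddingNetwork:
    """Trunk + head network with manual backprop (see :mod:`tomopick.nn`)."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or default_config()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = self.config

        blocks = []
        c_in = 1
        for b in range(cfg.n_blocks):
            c_out = cfg.base_channels * 2**b
            blocks += [
                nn.Conv3d(c_in, c_out, rng, cfg.negative_slope),
                nn.GroupNorm(c_out, cfg.groups),
                nn.LeakyReLU(cfg.negative_slope),
                nn.Conv3d(c_out, c_out, rng, cfg.negative_slope),
                nn.GroupNorm(c_out, cfg.groups),
                nn.LeakyReLU(cfg.negative_slope),
            ]
            if b == 0:
                blocks.append(nn.MaxPool3d())
            c_in = c_out
        blocks.append(nn.AdaptiveMaxPool3d())
        self.trunk = nn.Sequential(*blocks)

        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(1)[0])
        head = [nn.Flatten(), nn.Dropout(cfg.dropout_rate, self._dropout_rng)]
        n_in = cfg.trunk_channels * 8
        for width in cfg.head_widths:
            head += [nn.Linear(n_in, width, rng, cfg.negative_slope),
                     nn.LeakyReLU(cfg.negative_slope)]
            n_in = width
        head += [nn.Linear(n_in, cfg.out_dim, rng, cfg.negative_slope),
                 nn.L2Normalize()]
        self.head = nn.Sequential(*head)

    # ------------------------------------------------------------------ #

    def params(self) -> list[nn.Param]:
        return self.trunk.params() + self.head.params()

    def _as_batch(self, subvolumes: np.ndarray) -> np.ndarray:
        x = np.asarray(subvolumes, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim == 4:
            x = x[:, None]
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("expected (N, box, box, box) single-channel batch")
        b = self.config.in_box
        if x.shape[2:] != (b, b, b):
            raise ValueError(
                f"subvolume shape {x.shape[2:]} does not match in_box={b}")
        return x

    def trunk_forward(self, subvolumes: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of cubes -> (N, C, 2, 2, 2) feature tensors."""
        return self.trunk.forward(self._as_batch(subvolumes), train=train)

    def head_forward(self, features: np.ndarray, train: bool = False) -> np.ndarray:
        """Feature tensors -> (N, out_dim) unit vectors."""
        return self.head.forward(features, train=train)

    def forward(self, subvolumes: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head_forward(self.trunk_forward(subvolumes, train=train),
                                 train=train)

    def backward(self, grad_embeddings: np.ndarray) -> np.ndarray:
        """Backprop a gradient w.r.t. the embeddings through head and trunk."""
        return self.trunk.backward(self.head.backward(grad_embeddings))

    def embed(self, subvolumes: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode embedding of a batch; order preserved, unit norm."""
        x = self._as_batch(subvolumes)
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0) if outs else np.empty(
            (0, self.config.out_dim), dtype=np.float32)


# ---------------------------------------------------------------------- #
# checkpointing

def save_checkpoint(model: EmbeddingNetwork, path) -> None:
    """Write weights + config + seed to a single ``.npz`` archive."""
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.params())}
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> EmbeddingNetwork:
    """Restore a model for bit-identical inference."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = dict(meta["config"])
        cfg["head_widths"] = tuple(cfg["head_widths"])
        model = EmbeddingNetwork(NetworkConfig(**cfg), seed=meta["seed"])
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i:04d}"]
    return model


def checkpoint_bytes(model: EmbeddingNetwork) -> bytes:
    """Serialized checkpoint as bytes (for hashing into run manifests)."""
    buf = io.BytesIO()
    save_checkpoint(model, buf)
    return buf.getvalue()
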
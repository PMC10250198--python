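"""Deep metric learning: triplet loss, online semihard mining, augmentation
and the training loop.

The loss operates on cosine *distance* d = 1 - cos between L2-normalized
embeddings:  L(a, p, n) = max(d(a,p) - d(a,n) + alpha, 0).  Negatives are
mined online per batch under the semihard rule
``d(a,p) < d(a,n) < d(a,p) + alpha_miner`` — hard enough to be informative,
not so hard as to destabilize training.  Each epoch shuffles, builds
class-balanced batches, augments, embeds, mines, steps Adam, and evaluates
retrieval on the validation split; the checkpoint with the best validation
macro-F1 (ties -> earliest epoch) is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import f1_score

from .network import EmbeddingNetwork, NetworkConfig, checkpoint_bytes, load_checkpoint

__all__ = [
    "cosine_similarity",
    "cosine_distance",
    "triplet_loss",
    "mine_semihard",
    "AugmentationConfig",
    "augment",
    "SubvolumeDataset",
    "split_dataset",
    "validate_retrieval",
    "TrainConfig",
    "train",
]


# ---------------------------------------------------------------------- #
# similarity metrics

def cosine_similarity(q: np.ndarray, p: np.ndarray) -> float:
    """Q.P / (|Q| |P|); errors on a zero vector."""
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    nq, np_ = np.linalg.norm(q), np.linalg.norm(p)
    if nq < 1e-12 or np_ < 1e-12:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(q, p) / (nq * np_))


def cosine_distance(q: np.ndarray, p: np.ndarray) -> float:
    """1 - cosine_similarity; 0 for parallel, 2 for antiparallel."""
    return 1.0 - cosine_similarity(q, p)


def _pairwise_cosine_distance(embeddings: np.ndarray) -> np.ndarray:
    e = np.asarray(embeddings, dtype=np.float64)
    e = e / np.linalg.norm(e, axis=1, keepdims=True)
    return np.clip(1.0 - e @ e.T, 0.0, 2.0)


def triplet_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray,
                 margin_alpha: float = 0.2) -> float:
    """max(d(a,p) - d(a,n) + alpha, 0) for one triplet of embeddings."""
    d_ap = cosine_distance(a, p)
    d_an = cosine_distance(a, n)
    return max(d_ap - d_an + margin_alpha, 0.0)


def batch_triplet_loss(embeddings: np.ndarray, triples: list[tuple[int, int, int]],
                       margin_alpha: float = 0.2) -> tuple[float, np.ndarray]:
    """Mean loss over mined triples plus its gradient w.r.t. embeddings.

    Embeddings are assumed unit-norm (network output), so
    d(a,p) = 1 - a.p and the gradients are linear in the vectors.
    """
    grad = np.zeros_like(embeddings, dtype=np.float32)
    if not triples:
        return 0.0, grad
    e = embeddings
    total = 0.0
    scale = 1.0 / len(triples)
    for ai, pi, ni in triples:
        d_ap = 1.0 - float(e[ai] @ e[pi])
        d_an = 1.0 - float(e[ai] @ e[ni])
        loss = d_ap - d_an + margin_alpha
        if loss > 0:
            total += loss
            grad[ai] += scale * (e[ni] - e[pi])
            grad[pi] += -scale * e[ai]
            grad[ni] += scale * e[ai]
    return total * scale, grad


def mine_semihard(embeddings: np.ndarray, labels, margin_miner: float = 0.2
                  ) -> list[tuple[int, int, int]]:
    """Online semihard triplets: d(a,p) < d(a,n) < d(a,p) + margin.

    For each ordered same-class (anchor, positive) pair, at most one
    negative is emitted — the hardest qualifying one (minimal d(a,n), ties
    broken by the smallest index).  A single-class batch yields no triplets.
    """
    labels = np.asarray(labels)
    d = _pairwise_cosine_distance(embeddings)
    n = len(labels)
    triples: list[tuple[int, int, int]] = []
    for a in range(n):
        same = labels == labels[a]
        neg_idx = np.flatnonzero(~same)
        if len(neg_idx) == 0:
            continue
        d_an = d[a, neg_idx]
        for p in np.flatnonzero(same):
            if p == a:
                continue
            d_ap = d[a, p]
            qualifying = (d_an > d_ap) & (d_an < d_ap + margin_miner)
            if not qualifying.any():
                continue
            cand = neg_idx[qualifying]
            best = cand[np.argmin(d[a, cand])]
            triples.append((a, int(p), int(best)))
    return triples


# ---------------------------------------------------------------------- #
# augmentation

@dataclass(frozen=True)
class AugmentationConfig:
    """All four augmentations, each optional.

    Fractions/ranges follow the training recipe: dropout replaces 5-20% of
    voxels with the subvolume mean; shifts are 1-2 voxels per axis; noise
    sigma is drawn uniformly from [0, 0.3]; rotation is confined to the xy
    plane so the missing wedge keeps its orientation.
    """

    rotate_xy: bool = True
    use_dropout: bool = True
    dropout_frac_range: tuple[float, float] = (0.05, 0.20)
    use_shift: bool = True
    shift_range: tuple[int, int] = (1, 2)
    use_noise: bool = True
    noise_sigma_range: tuple[float, float] = (0.0, 0.3)


def augment(subvolume: np.ndarray, config: AugmentationConfig,
            rng: np.random.Generator, force_angle: float | None = None
            ) -> np.ndarray:
    """Apply the configured augmentations; shape is always preserved."""
    out = np.asarray(subvolume, dtype=np.float32).copy()
    if config.rotate_xy:
        angle = force_angle if force_angle is not None else rng.uniform(0, 360)
        if angle % 360 == 90:
            out = np.rot90(out, k=1, axes=(1, 2)).copy()
        elif angle % 360 != 0:
            out = ndimage.rotate(out, angle, axes=(1, 2), reshape=False,
                                 order=1, mode="nearest")
    if config.use_dropout:
        frac = rng.uniform(*config.dropout_frac_range)
        mask = rng.random(out.shape) < frac
        out[mask] = out.mean()
    if config.use_shift:
        lo, hi = config.shift_range
        shifts = rng.integers(lo, hi + 1, size=3) * rng.choice([-1, 1], size=3)
        fill = float(out.mean())
        shifted = np.full_like(out, fill)
        src = [slice(max(0, -s), out.shape[i] - max(0, s)) for i, s in enumerate(shifts)]
        dst = [slice(max(0, s), out.shape[i] - max(0, -s)) for i, s in enumerate(shifts)]
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    if config.use_noise:
        sigma = rng.uniform(*config.noise_sigma_range)
        if sigma > 0:
            out = out + rng.normal(0.0, sigma, size=out.shape).astype(np.float32)
    return out.astype(np.float32)


# ---------------------------------------------------------------------- #
# dataset

@dataclass
class SubvolumeDataset:
    """Labeled subvolumes with a train/validation split."""

    subvolumes: list
    labels: np.ndarray
    split: np.ndarray          # "train" / "val" per item

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.split = np.asarray(self.split)
        if not (len(self.subvolumes) == len(self.labels) == len(self.split)):
            raise ValueError("subvolumes, labels and split disagree in length")
        train_classes = set(self.labels[self.split == "train"])
        val_classes = set(self.labels[self.split == "val"])
        if train_classes != val_classes:
            raise ValueError("every class must appear in both splits")

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.split == which)


def split_dataset(per_class_pools: dict, n_train: int, n_val: int,
                  seed: int = 0) -> SubvolumeDataset:
    """Seeded disjoint train/validation split with exact per-class counts."""
    subvolumes, labels, split = [], [], []
    rng = np.random.default_rng(seed)
    for label in sorted(per_class_pools, key=str):
        pool = per_class_pools[label]
        if len(pool) < n_train + n_val:
            raise ValueError(
                f"class {label!r} pool has {len(pool)} subvolumes; "
                f"needs {n_train + n_val}")
        order = rng.permutation(len(pool))
        for i in order[:n_train]:
            subvolumes.append(pool[i]); labels.append(label); split.append("train")
        for i in order[n_train:n_train + n_val]:
            subvolumes.append(pool[i]); labels.append(label); split.append("val")
    return SubvolumeDataset(subvolumes, np.asarray(labels), np.asarray(split))


# ---------------------------------------------------------------------- #
# validation retrieval

def _class_medoids(embeddings: np.ndarray, labels) -> tuple[np.ndarray, list]:
    """Per-class medoid on the hypersphere: the member embedding with
    minimal summed cosine distance to its classmates."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=str)
    medoids = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        sub = embeddings[idx]
        d = _pairwise_cosine_distance(sub)
        medoids.append(sub[int(np.argmin(d.sum(axis=1)))])
    return np.asarray(medoids), classes


def validate_retrieval(model: EmbeddingNetwork, dataset: SubvolumeDataset,
                       batch_size: int = 64, medoid_cap: int = 32,
                       train_embeddings: np.ndarray | None = None) -> float:
    """Macro-F1 of nearest-class-medoid classification of the validation split.

    Medoids are computed from the training split (the first ``medoid_cap``
    members per class, a deterministic subset, to bound the per-epoch cost);
    each validation embedding is assigned the class of its most
    cosine-similar medoid.
    """
    tr = dataset.indices("train")
    va = dataset.indices("val")
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("dataset must contain both splits")
    labels_tr = dataset.labels[tr]
    if medoid_cap is not None:
        keep = []
        seen: dict = {}
        for pos, lab in enumerate(labels_tr):
            if seen.setdefault(lab, 0) < medoid_cap:
                seen[lab] += 1
                keep.append(pos)
        tr = tr[keep]
        labels_tr = labels_tr[keep]
        train_embeddings = None if train_embeddings is None else \
            train_embeddings[keep]
    if train_embeddings is None:
        train_embeddings = model.embed(
            np.stack([dataset.subvolumes[i] for i in tr]), batch_size=batch_size)
    medoids, classes = _class_medoids(train_embeddings, labels_tr)
    val_emb = model.embed(np.stack([dataset.subvolumes[i] for i in va]),
                          batch_size=batch_size)
    sims = val_emb @ medoids.T
    predicted = np.asarray(classes, dtype=object)[sims.argmax(axis=1)]
    truth = dataset.labels[va]
    return float(f1_score(truth.astype(str), predicted.astype(str),
                          average="macro", zero_division=0))


# ---------------------------------------------------------------------- #
# training

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 600
    batch_classes: int = 5           # classes per batch ...
    batch_instances: int = 5         # ... x instances per class
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    margin_alpha: float = 0.2
    margin_miner: float = 0.2
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.margin_alpha <= 0 or self.margin_miner <= 0:
            raise ValueError("margins must be > 0")


def train(dataset: SubvolumeDataset, net_config: NetworkConfig,
          train_config: TrainConfig) -> tuple[EmbeddingNetwork, pd.DataFrame]:
    """Train an embedding network; returns (best model, history).

    One master seed fans out to weight init, augmentation and shuffling
    streams.  History rows: (epoch, loss, val_f1); epoch 0 records the
    untrained model.  The returned model carries the weights of the epoch
    with the highest validation macro-F1 (earliest epoch on ties).
    """
    from . import nn as _nn

    root = np.random.SeedSequence(train_config.seed)
    init_seed, aug_stream, shuffle_stream = root.spawn(3)
    model = EmbeddingNetwork(net_config,
                             seed=int(init_seed.generate_state(1)[0] % 2**31))
    aug_rng = np.random.default_rng(aug_stream)
    shuffle_rng = np.random.default_rng(shuffle_stream)
    optimizer = _nn.Adam(model.params(), lr=train_config.learning_rate,
                         weight_decay=train_config.weight_decay)

    tr_idx = dataset.indices("train")
    labels = dataset.labels
    classes = sorted(set(labels[tr_idx].tolist()), key=str)
    by_class = {c: tr_idx[labels[tr_idx] == c] for c in classes}

    _center_embedding_init(model, dataset, tr_idx)

    history = []
    best = {"f1": -1.0, "epoch": -1, "ckpt": checkpoint_bytes(model)}
    val0 = validate_retrieval(model, dataset)
    history.append({"epoch": 0, "loss": np.nan, "val_f1": val0})
    if val0 > best["f1"]:
        best = {"f1": val0, "epoch": 0, "ckpt": checkpoint_bytes(model)}

    for epoch in range(1, train_config.epochs + 1):
        batches = _balanced_batches(by_class, train_config.batch_classes,
                                    train_config.batch_instances, shuffle_rng)
        losses = []
        mined_any = False
        for batch_idx in batches:
            cubes = np.stack([
                augment(dataset.subvolumes[i], train_config.augmentation, aug_rng)
                for i in batch_idx])
            emb = model.forward(cubes, train=True)
            triples = mine_semihard(emb, labels[batch_idx],
                                    train_config.margin_miner)
            loss, grad = batch_triplet_loss(emb, triples,
                                            train_config.margin_alpha)
            mined_any = mined_any or bool(triples)
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        if not mined_any:
            warnings.warn(f"epoch {epoch}: no triplets mined; loss-0 epoch")
        val = validate_retrieval(model, dataset)
        history.append({"epoch": epoch,
                        "loss": float(np.mean(losses)) if losses else 0.0,
                        "val_f1": val})
        if val > best["f1"]:
            best = {"f1": val, "epoch": epoch, "ckpt": checkpoint_bytes(model)}

    import io as _io
    best_model = load_checkpoint(_io.BytesIO(best["ckpt"]))
    hist = pd.DataFrame(history, columns=["epoch", "loss", "val_f1"])
    if train_config.epochs == 0:
        hist = hist.iloc[0:0]
    return best_model, hist


def _center_embedding_init(model: EmbeddingNetwork, dataset: SubvolumeDataset,
                           tr_idx: np.ndarray, probe_size: int = 128) -> None:
    """Data-dependent initialization: center the final pre-normalization
    layer's output over a probe batch.

    Freshly initialized networks emit embeddings clustered in a tight cap of
    the hypersphere (a large shared mean component dominates the
    feature-dependent part), which starves the triplet loss of gradient
    signal.  Subtracting the probe-batch mean from the final layer's bias
    spreads the initial embeddings over the sphere without changing the
    architecture.
    """
    probe = np.stack([dataset.subvolumes[i] for i in tr_idx[:probe_size]])
    h = model.trunk_forward(probe).reshape(len(probe), -1)
    for layer in model.head.layers[1:-2]:     # after Flatten, up to final Linear
        h = layer.forward(h)
    final = model.head.layers[-2]
    z = final.forward(h)
    final.b.value[...] -= z.mean(axis=0)


def _balanced_batches(by_class: dict, p: int, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced batches: p classes x k instances, covering each
    class's pool once per epoch (remainders dropped)."""
    classes = sorted(by_class, key=str)
    shuffled = {c: rng.permutation(by_class[c]) for c in classes}
    cursors = {c: 0 for c in classes}
    batches = []
    while True:
        avail = [c for c in classes if cursors[c] + k <= len(shuffled[c])]
        if len(avail) < min(p, len(classes)):
            break
        chosen = list(rng.permutation(avail))[:min(p, len(avail))]
        batch = np.concatenate([
            shuffled[c][cursors[c]:cursors[c] + k] for c in chosen])
        for c in chosen:
            cursors[c] += k
        batches.append(batch)
    return batches
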
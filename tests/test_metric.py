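"""Metric-learning components: similarity, loss, miner, augmentation,
splitting, retrieval validation and the training loop."""

import numpy as np
import pytest

from tomopick.metric import (AugmentationConfig, TrainConfig, augment,
                             batch_triplet_loss, cosine_distance,
                             cosine_similarity, mine_semihard, split_dataset,
                             train, triplet_loss, validate_retrieval)
from tomopick.network import NetworkConfig


# ---------------------------------------------------------------------- #
# similarity metrics

@pytest.mark.parametrize("q,p,expected", [
    ([1, 0, 0], [1, 0, 0], 1.0),
    ([1, 0, 0], [0, 1, 0], 0.0),
    ([1, 1, 0], [1, 0, 0], 1 / np.sqrt(2)),
    ([1, 0], [-1, 0], -1.0),
])
def test_cosine_similarity_closed_forms(q, p, expected):
    assert cosine_similarity(q, p) == pytest.approx(expected, abs=1e-12)
    assert cosine_similarity(p, q) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("q,p,expected", [
    ([0, 2, 0], [0, 2, 0], 0.0),
    ([1, 0], [0, 3], 1.0),
    ([1, 0], [-2, 0], 2.0),
])
def test_cosine_distance_closed_forms(q, p, expected):
    assert cosine_distance(q, p) == pytest.approx(expected, abs=1e-12)


def test_zero_vector_errors():
    with pytest.raises(ValueError, match="zero"):
        cosine_similarity([0, 0, 0], [1, 0, 0])


# ---------------------------------------------------------------------- #
# triplet loss

def test_triplet_loss_zero_when_negative_far():
    a = np.array([1.0, 0, 0])
    n = np.array([0, 1.0, 0])           # d_an = 1
    assert triplet_loss(a, a, n, 0.2) == 0.0


def test_triplet_loss_closed_form():
    a = np.array([1.0, 0, 0])
    p = np.array([0, 1.0, 0])           # d_ap = 1
    assert triplet_loss(a, p, a, 0.2) == pytest.approx(1.2)


def test_zero_at_margin_boundary():
    """Loss is 0 exactly when d(a,n) >= d(a,p) + alpha."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        v = rng.normal(size=(3, 8))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        a, p, n = v
        alpha = rng.uniform(0.05, 0.5)
        loss = triplet_loss(a, p, n, alpha)
        d_ap, d_an = cosine_distance(a, p), cosine_distance(a, n)
        assert loss >= 0
        if d_an >= d_ap + alpha:
            assert loss == 0
        else:
            assert loss > 0


def test_batch_loss_matches_enumeration_oracle():
    """Mean batch loss equals a direct per-triplet recomputation."""
    rng = np.random.default_rng(1)
    emb = rng.normal(size=(20, 8)).astype(np.float32)
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    labels = rng.integers(0, 4, size=20)
    triples = mine_semihard(emb, labels, 0.3)
    loss, _ = batch_triplet_loss(emb, triples, 0.2)
    expected = np.mean([triplet_loss(emb[a], emb[p], emb[n], 0.2)
                        for a, p, n in triples])
    assert loss == pytest.approx(float(expected), rel=1e-5)


def test_batch_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    emb = rng.normal(size=(10, 6)).astype(np.float64)
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
    triples = mine_semihard(emb, labels, 0.4)
    assert triples
    _, grad = batch_triplet_loss(emb.astype(np.float32), triples, 0.2)

    # finite differences of the *unnormalized-input* loss surface
    def f(e):
        return np.mean([max((1 - e[a] @ e[p]) - (1 - e[a] @ e[n]) + 0.2, 0)
                        for a, p, n in triples])
    eps = 1e-6
    for idx in [(0, 0), (3, 2), (9, 5)]:
        e2 = emb.copy()
        e2[idx] += eps
        num = (f(e2) - f(emb)) / eps
        assert grad[idx] == pytest.approx(num, abs=1e-4)


# ---------------------------------------------------------------------- #
# semihard miner

def _oracle_miner(emb, labels, margin):
    """Independent brute-force triple enumeration."""
    e = emb / np.linalg.norm(emb, axis=1, keepdims=True)
    d = np.clip(1.0 - e @ e.T, 0.0, 2.0)
    out = []
    n = len(labels)
    for a in range(n):
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            best, best_d = None, np.inf
            for neg in range(n):
                if labels[neg] == labels[a]:
                    continue
                if d[a, p] < d[a, neg] < d[a, p] + margin:
                    if d[a, neg] < best_d:
                        best, best_d = neg, d[a, neg]
            if best is not None:
                out.append((a, p, best))
    return out


def test_miner_empty_when_negatives_too_easy():
    emb = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]], dtype=float)
    # same-class distances 0; cross-class distance 1 > 0 + 0.2
    assert mine_semihard(emb, [0, 0, 1, 1], 0.2) == []


def test_miner_single_class_batch_is_empty():
    emb = np.random.default_rng(3).normal(size=(6, 4))
    assert mine_semihard(emb, [1] * 6, 0.2) == []


@pytest.mark.parametrize("seed", range(12))
def test_miner_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 28))
    emb = rng.normal(size=(n, 8))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    labels = rng.integers(0, 4, size=n)
    margin = float(rng.uniform(0.1, 0.8))
    assert sorted(mine_semihard(emb, labels, margin)) == \
        sorted(_oracle_miner(emb, labels, margin))


@pytest.mark.parametrize("seed", range(5))
def test_miner_postcondition_audit(seed):
    rng = np.random.default_rng(100 + seed)
    emb = rng.normal(size=(20, 8))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    labels = rng.integers(0, 3, size=20)
    d = np.clip(1 - emb @ emb.T, 0, 2)
    for a, p, n in mine_semihard(emb, labels, 0.3):
        assert labels[a] == labels[p] != labels[n]
        assert d[a, p] < d[a, n] < d[a, p] + 0.3


# ---------------------------------------------------------------------- #
# augmentation

def _norm_cube(seed=0, n=12):
    rng = np.random.default_rng(seed)
    cube = rng.normal(size=(n, n, n)).astype(np.float32)
    return (cube - cube.mean()) / cube.std()


def test_augment_all_disabled_is_identity():
    cfg = AugmentationConfig(rotate_xy=False, use_dropout=False,
                             use_shift=False, use_noise=False)
    cube = _norm_cube()
    out = augment(cube, cfg, np.random.default_rng(0))
    assert np.array_equal(out, cube)


def test_augment_preserves_shape():
    cube = _norm_cube(1)
    out = augment(cube, AugmentationConfig(), np.random.default_rng(1))
    assert out.shape == cube.shape


def test_dropout_fraction_recount():
    """Voxels set to the mean fall within the configured 5-20% range."""
    cfg = AugmentationConfig(rotate_xy=False, use_shift=False, use_noise=False)
    cube = _norm_cube(2, n=16)
    pre_existing = int((cube == cube.mean()).sum())
    for seed in range(5):
        out = augment(cube, cfg, np.random.default_rng(seed))
        frac = (np.isclose(out, cube.mean())).sum() / cube.size
        assert 0.05 - 0.01 <= frac <= 0.20 + pre_existing / cube.size + 0.01


def test_rotation_90_degrees_exact():
    cfg = AugmentationConfig(use_dropout=False, use_shift=False,
                             use_noise=False)
    cube = _norm_cube(3)
    out = augment(cube, cfg, np.random.default_rng(0), force_angle=90.0)
    for z in range(cube.shape[0]):
        assert np.array_equal(out[z], np.rot90(cube[z]))


def test_shift_magnitude():
    cfg = AugmentationConfig(rotate_xy=False, use_dropout=False,
                             use_noise=False)
    cube = _norm_cube(4)
    out = augment(cube, cfg, np.random.default_rng(7))
    # some integer shift (1-2 voxels per axis) reproduces the output core
    found = False
    for sz in (-2, -1, 1, 2):
        for sy in (-2, -1, 1, 2):
            for sx in (-2, -1, 1, 2):
                shifted = np.roll(cube, (sz, sy, sx), axis=(0, 1, 2))
                core = (slice(2, -2),) * 3
                if np.allclose(out[core], shifted[core]):
                    found = True
    assert found


# ---------------------------------------------------------------------- #
# dataset splitting

def test_split_counts_match_printed_totals():
    """123 classes at 800/200 per class: 98,400 train / 24,600 validation."""
    stub = np.zeros((1, 1, 1), dtype=np.float32)
    pools = {c: [stub] * 1000 for c in range(123)}
    ds = split_dataset(pools, n_train=800, n_val=200, seed=0)
    assert int((ds.split == "train").sum()) == 98_400
    assert int((ds.split == "val").sum()) == 24_600


def test_split_disjoint():
    pool = [np.full((1, 1, 1), float(i)) for i in range(2)]
    ds = split_dataset({"a": pool}, 1, 1, seed=3)
    train_vol = ds.subvolumes[ds.indices("train")[0]]
    val_vol = ds.subvolumes[ds.indices("val")[0]]
    assert train_vol[0, 0, 0] != val_vol[0, 0, 0]


def test_split_pool_too_small_names_class():
    with pytest.raises(ValueError, match="tiny"):
        split_dataset({"tiny": [np.zeros((1, 1, 1))]}, 1, 1)


# ---------------------------------------------------------------------- #
# retrieval validation

class _StubModel:
    """Maps 1-voxel 'subvolumes' directly to fixed embeddings."""

    def __init__(self, table):
        self.table = table

    def embed(self, cubes, batch_size=64):
        keys = np.asarray(cubes).reshape(len(cubes)).astype(int)
        return np.stack([self.table[k] for k in keys])


def _stub_dataset(labels, split):
    from tomopick.metric import SubvolumeDataset
    subs = [np.full((1, 1, 1), float(i)) for i in range(len(labels))]
    return SubvolumeDataset(subs, np.asarray(labels), np.asarray(split))


def test_retrieval_perfect_separation_gives_f1_one():
    table = {0: [1, 0], 1: [1, 0], 2: [0, 1], 3: [0, 1],
             4: [0.9, 0.1], 5: [0.1, 0.9]}
    table = {k: np.asarray(v) / np.linalg.norm(v) for k, v in table.items()}
    ds = _stub_dataset(["a", "a", "b", "b", "a", "b"],
                       ["train", "train", "train", "train", "val", "val"])
    assert validate_retrieval(_StubModel(table), ds) == 1.0


def test_retrieval_matches_confusion_matrix_oracle():
    """3-class toy set scored against a hand-coded confusion matrix."""
    vecs = {"a": [1, 0, 0], "b": [0, 1, 0], "c": [0, 0, 1]}
    table = {}
    labels, split = [], []
    idx = 0
    for cls in "abc":
        table[idx] = np.asarray(vecs[cls], dtype=float)
        labels.append(cls)
        split.append("train")
        idx += 1
    # validation: a->a, a->b (miss), b->b, c->c
    for cls, target in [("a", "a"), ("a", "b"), ("b", "b"), ("c", "c")]:
        table[idx] = np.asarray(vecs[target], dtype=float)
        labels.append(cls)
        split.append("val")
        idx += 1
    ds = _stub_dataset(labels, split)
    got = validate_retrieval(_StubModel(table), ds)
    # confusion: a: TP1 FN1; b: TP1 FP1; c: TP1.
    f1_a = 2 * (1 / 1) * (1 / 2) / (1 / 1 + 1 / 2)
    f1_b = 2 * (1 / 2) * (1 / 1) / (1 / 2 + 1 / 1)
    f1_c = 1.0
    assert got == pytest.approx((f1_a + f1_b + f1_c) / 3)


def test_retrieval_shuffled_labels_near_chance():
    """Uniformly shuffled labels over k classes give macro-F1 ~ 1/k."""
    rng = np.random.default_rng(11)
    k, n = 4, 400
    table = {}
    labels, split = [], []
    for i in range(n):
        v = rng.normal(size=6)
        table[i] = v / np.linalg.norm(v)
        labels.append(rng.integers(0, k))
        split.append("train" if i < n // 2 else "val")
    for c in range(k):   # ensure both splits contain every class
        labels[c] = c
        labels[n - 1 - c] = c
    ds = _stub_dataset(labels, split)
    got = validate_retrieval(_StubModel(table), ds)
    assert abs(got - 1 / k) < 0.12


# ---------------------------------------------------------------------- #
# training loop

_TINY_NET = NetworkConfig(in_box=9, base_channels=2, n_blocks=2, groups=2,
                          dropout_rate=0.0, out_dim=8, head_widths=(16,))


def _tiny_dataset(seed=0, n_per=8):
    rng = np.random.default_rng(seed)
    pools = {}
    for cls, level in [("a", -1.0), ("b", 1.0)]:
        pool = []
        for _ in range(n_per):
            cube = rng.normal(level, 1.0, size=(9, 9, 9)).astype(np.float32)
            cube[2:7, 2:7, 2:7] += level * 2
            pool.append((cube - cube.mean()) / cube.std())
        pools[cls] = pool
    return split_dataset(pools, n_train=6, n_val=2, seed=seed)


def test_train_epochs_zero_returns_init_and_empty_history():
    ds = _tiny_dataset()
    cfg = TrainConfig(epochs=0, batch_classes=2, batch_instances=3, seed=0)
    model, history = train(ds, _TINY_NET, cfg)
    assert len(history) == 0
    assert model.config == _TINY_NET


def test_train_deterministic_history():
    ds = _tiny_dataset()
    cfg = TrainConfig(epochs=2, batch_classes=2, batch_instances=3, seed=5)
    _, h1 = train(ds, _TINY_NET, cfg)
    _, h2 = train(ds, _TINY_NET, cfg)
    assert h1.equals(h2)


def test_train_margin_validation():
    with pytest.raises(ValueError):
        TrainConfig(margin_alpha=0.0)
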
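"""Contrastive graph-mask alignment: loss oracle, negative sampling,
mask-embedding projection, and the image-codec firewall."""

import numpy as np
import pytest

from sgdiff.codec import LatentGrid
from sgdiff.nn import Tensor
from sgdiff.pretrain_global import (MaskProjectionHead, global_loss,
                                    project_mask_embedding, sample_negatives)


def test_global_loss_no_negatives_is_exactly_zero(rng):
    z = rng.normal(size=8)
    pos = rng.normal(size=8)
    assert float(global_loss(z, pos, []).data) == 0.0


def test_global_loss_equal_logits_is_log_k_plus_one(rng):
    """All dot products equal with k=3 -> uniform softmax -> ln 4."""
    z = rng.normal(size=6)
    pos = rng.normal(size=6)
    s = float(z @ pos)
    # craft negatives with the same dot product against z
    negs = []
    for _ in range(3):
        v = rng.normal(size=6)
        v = v + (s - z @ v) / (z @ z) * z
        negs.append(v)
    loss = float(global_loss(z, pos, negs).data)
    assert loss == pytest.approx(np.log(4.0), abs=1e-9)
    assert loss == pytest.approx(1.386294, abs=1e-5)


def test_global_loss_matches_high_precision_formula(rng):
    """Random vectors, k=8: agreement with a long-double evaluation of the
    printed softmax-ratio expression."""
    for _ in range(20):
        z = rng.normal(size=12)
        pos = rng.normal(size=12)
        negs = [rng.normal(size=12) for _ in range(8)]
        got = float(global_loss(z, pos, negs).data)
        zl = np.asarray(z, dtype=np.longdouble)
        e_pos = np.exp(np.dot(zl, np.asarray(pos, dtype=np.longdouble)))
        e_negs = [np.exp(np.dot(zl, np.asarray(v, dtype=np.longdouble)))
                  for v in negs]
        expected = float(-np.log(e_pos / (e_pos + sum(e_negs))))
        assert got == pytest.approx(expected, rel=1e-10)


def test_global_loss_large_logits_stable():
    z = np.full(4, 100.0)
    pos = np.full(4, 10.0)
    negs = [np.full(4, -10.0)]
    loss = float(global_loss(z, pos, negs).data)
    assert np.isfinite(loss)
    assert loss == pytest.approx(0.0, abs=1e-12)  # pos dominates


def test_global_loss_monotone_in_positive_alignment(rng):
    z = rng.normal(size=8)
    negs = [rng.normal(size=8) for _ in range(4)]
    base = rng.normal(size=8)
    losses = [float(global_loss(z, base * s, negs).data) for s in (0.5, 2, 8)]
    scale_sign = np.sign(z @ base)
    if scale_sign > 0:  # increasing pos dot product must decrease the loss
        assert losses[0] > losses[1] > losses[2]


def test_global_loss_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        global_loss(rng.normal(size=4), rng.normal(size=5), [])


def test_sample_negatives_exhaustive_case(rng):
    masks = [np.full((4, 4), i) for i in range(6)]
    out = sample_negatives(masks, 2, 5, rng)
    assert sorted(out) == [0, 1, 3, 4, 5]


def test_sample_negatives_never_returns_positive(rng):
    masks = [np.full((2, 2), i % 7) for i in range(30)]
    for _ in range(2000):
        assert 3 not in sample_negatives(masks, 3, 4, rng)


def test_sample_negatives_rejects_identical_masks(rng):
    masks = [np.zeros((3, 3)), np.zeros((3, 3)), np.ones((3, 3)),
             np.full((3, 3), 2.0), np.full((3, 3), 3.0)]
    for _ in range(200):
        out = sample_negatives(masks, 0, 3, rng)
        assert 1 not in out  # pixel-identical to the positive


def test_sample_negatives_uniform_inclusion():
    """Each eligible index included with uniform frequency +- 2%."""
    masks = [np.full((2, 2), i) for i in range(100)]
    rng = np.random.default_rng(0)
    counts = np.zeros(100)
    n = 50_000
    for _ in range(n):
        for i in sample_negatives(masks, 0, 4, rng):
            counts[i] += 1
    freq = counts[1:] / n
    assert np.abs(freq - 4 / 99).max() < 0.02


def test_sample_negatives_dataset_too_small(rng):
    with pytest.raises(ValueError):
        sample_negatives([np.zeros((2, 2))] * 3, 0, 3, rng)


def test_projection_constant_grid_pools_to_constant(rng):
    head = MaskProjectionHead(4, 6, np.random.default_rng(0))
    const = rng.normal(size=4)
    grid = LatentGrid(values=np.tile(const, (5, 5, 1)), codes=None,
                      source_kind="mask")
    pooled = grid.values.mean(axis=(0, 1))
    assert np.allclose(pooled, const)
    out = project_mask_embedding(grid, head, normalize=False)
    with_head = head(Tensor(const[None])).data[0]
    assert np.allclose(out, with_head)


def test_projection_matches_bruteforce_average(rng):
    head = MaskProjectionHead(4, 6, np.random.default_rng(1))
    values = rng.normal(size=(3, 7, 4))
    grid = LatentGrid(values=values, codes=None, source_kind="mask")
    brute = np.zeros(4)
    for i in range(3):
        for j in range(7):
            brute += values[i, j]
    brute /= 21
    out = project_mask_embedding(grid, head, normalize=False)
    assert np.allclose(out, head(Tensor(brute[None])).data[0])


def test_projection_identical_masks_identical_embeddings(rng):
    head = MaskProjectionHead(4, 6, np.random.default_rng(2))
    values = rng.normal(size=(4, 4, 4))
    a = project_mask_embedding(LatentGrid(values, None, "mask"), head)
    b = project_mask_embedding(LatentGrid(values.copy(), None, "mask"), head)
    assert np.array_equal(a, b)


def test_global_training_never_touches_image_codec(small_scenes, class_table):
    """The alignment target is the MASK embedding space: a spying image
    codec must see zero calls during global pre-training."""
    from sgdiff.codec import CodecConfig, train_codec
    from sgdiff.encoder import GraphEncoderConfig
    from sgdiff.pretrain_global import train_global

    calls = {"n": 0}

    class SpyImageCodec:
        def encode_tensor(self, *a, **k):
            calls["n"] += 1
            raise AssertionError("image codec used during global pre-training")

    mcfg = CodecConfig(input_kind="mask", n_channels=10, codebook_size=32,
                       code_dim=8, hidden_dim=32, epochs=2, batch_size=16)
    codec_m = train_codec(small_scenes[:30], mcfg, seed=0)
    _ = SpyImageCodec()  # exists; train_global has no parameter to accept it
    result = train_global(small_scenes[:30], codec_m,
                          GraphEncoderConfig(n_classes=10, num_layers=1,
                                             hidden_dim=16, out_dim=8,
                                             relation_embed_dim=4),
                          k=2, seed=1, epochs=1, class_table=class_table)
    assert calls["n"] == 0
    assert len(result.history["train"]) == 1
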
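"""Global pre-training: contrastive graph-mask embedding alignment.

The global graph encoder is trained so that a graph's embedding is close
(by dot product) to the embedding of its own ("compliant") segmentation
mask and far from the embeddings of k masks sampled from other frames:

    L_global = -log  exp(z_G . z_m+) / (exp(z_G . z_m+) + sum_i exp(z_G . z_mi-))

Alignment is deliberately to MASK embeddings, not image embeddings: frames
with similar anatomy but different instruments sit close together in an
image embedding space, whereas mask embeddings expose exactly the layout
the graph describes. Nothing in this module touches the image codec.

Mask embeddings are the spatial mean-pool of the frozen mask codec's latent
grid followed by a learned linear projection head. The loss is applied to
the raw (unnormalised) dot products by default — with L2-normalised
embeddings the logits are confined to [-1, 1] and the softmax gradient is
too flat to train without a temperature, which the formula does not have;
free norms let the model learn its own effective temperature. Set
``normalize=True`` to L2-normalise both sides inside the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .codec import Codec, one_hot_mask, vq_quantize
from .encoder import GraphEncoder, GraphEncoderConfig
from .graphs import graph_to_features, mask_to_graph
from .scenes import ClassTable, RenderedScene

__all__ = [
    "project_mask_embedding",
    "global_loss",
    "sample_negatives",
    "train_global",
    "GlobalPretrainResult",
    "MaskProjectionHead",
]


class MaskProjectionHead(nn.Module):
    """Spatial mean-pool of a mask latent grid + linear head."""

    def __init__(self, code_dim: int, out_dim: int, rng: np.random.Generator):
        self.proj = nn.Linear(code_dim, out_dim, rng)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.proj(pooled)


def _l2norm(v: Tensor, eps: float = 1e-9) -> Tensor:
    return v / (((v**2).sum(axis=-1, keepdims=True)) + eps).sqrt()


def project_mask_embedding(z_m, head: MaskProjectionHead,
                           normalize: bool = True) -> np.ndarray:
    """Project a mask latent grid (h, w, d) to the graph-embedding space."""
    values = getattr(z_m, "values", z_m)
    pooled = np.asarray(values, dtype=np.float64).mean(axis=(0, 1))
    with nn.no_grad():
        out = head(Tensor(pooled[None, :])).reshape(-1)
        if normalize:
            out = _l2norm(out)
    return out.data


def global_loss(z_g: Tensor | np.ndarray, pos: Tensor | np.ndarray,
                negs, normalize: bool = False) -> Tensor:
    """The contrastive loss, exactly as written: softmax-style negative log
    ratio over raw dot products (no temperature). k = 0 gives exactly 0.

    Numerical stability comes from max-subtraction inside logsumexp, which
    is algebraically equivalent to the direct expression.
    """
    def as_t(v):
        return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))

    z_g, pos = as_t(z_g), as_t(pos)
    negs = [as_t(v) for v in negs]
    if any(v.shape != z_g.shape for v in [pos, *negs]):
        raise ValueError("all vectors must share the graph-embedding dimension")
    if normalize:
        z_g, pos = _l2norm(z_g), _l2norm(pos)
        negs = [_l2norm(v) for v in negs]
    if not negs:
        return (z_g * pos).sum() * 0.0
    logits = nn.concatenate(
        [(z_g * v).sum().reshape(1) for v in [pos, *negs]], axis=0)
    return logits.logsumexp(axis=0) - logits[0]


def sample_negatives(masks: list[np.ndarray], positive_index: int, k: int,
                     rng: np.random.Generator) -> list[int]:
    """k indices != positive_index, uniform without replacement; candidates
    whose mask is pixel-identical to the positive are rejected and redrawn."""
    n = len(masks)
    if n <= k:
        raise ValueError(f"dataset of size {n} cannot provide {k} negatives")
    pos = masks[positive_index]
    candidates = [i for i in range(n) if i != positive_index]
    rng.shuffle(candidates)
    out: list[int] = []
    for i in candidates:
        if np.array_equal(masks[i], pos):
            continue
        out.append(i)
        if len(out) == k:
            return out
    raise ValueError("not enough non-compliant masks to sample negatives")


@dataclass
class GlobalPretrainResult:
    encoder: GraphEncoder
    head: MaskProjectionHead
    history: dict[str, list[float]]
    normalize: bool


def _pooled_mask_latents(codec_m: Codec, dataset: list[RenderedScene]) -> np.ndarray:
    """(N, code_dim) spatial mean-pools of quantised mask latents."""
    xs = np.stack([one_hot_mask(s.mask, codec_m.config.n_channels)
                   for s in dataset])
    with nn.no_grad():
        z = codec_m.encode_tensor(xs)
    z_q, _, _ = vq_quantize(codec_m.codebook, z.data)
    return z_q.mean(axis=(1, 2))


def train_global(dataset: list[RenderedScene], codec_m: Codec,
                 encoder_config: GraphEncoderConfig, k: int = 8,
                 seed: int = 0, epochs: int = 30, batch_size: int = 32,
                 lr: float = 3e-3, heldout_frac: float = 0.15,
                 normalize: bool = False,
                 class_table: ClassTable | None = None) -> GlobalPretrainResult:
    """Train the global graph encoder and the mask projection head.

    ``history['heldout']`` records the mean contrastive loss on a held-out
    split per epoch (before any training, then after each epoch).
    """
    if class_table is None:
        from .scenes import default_class_table
        class_table = default_class_table()
    rng = np.random.default_rng(seed)
    encoder = GraphEncoder(encoder_config, rng, scope="global")
    head = MaskProjectionHead(codec_m.config.code_dim, encoder_config.out_dim, rng)

    graphs = [mask_to_graph(s.mask, class_table) for s in dataset]
    feats = [graph_to_features(g, encoder_config.n_classes) for g in graphs]
    masks = [s.mask for s in dataset]
    pooled = _pooled_mask_latents(codec_m, dataset)  # (N, d)

    n_hold = max(1, int(round(heldout_frac * len(dataset))))
    train_idx = list(range(len(dataset) - n_hold))
    hold_idx = list(range(len(dataset) - n_hold, len(dataset)))

    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=lr)
    history = {"train": [], "heldout": []}

    def epoch_lr(e: int) -> float:
        # cosine decay to lr/20 refines the embedding once the easy
        # negatives are separated
        return lr / 20 + 0.5 * (lr - lr / 20) * (1 + np.cos(np.pi * e / max(1, epochs)))

    def batch_loss(idx, rng_local: np.random.Generator) -> Tensor:
        # one block-diagonal GNN pass for the whole minibatch
        z_gs = encoder.forward_batch([feats[i][0] for i in idx],
                                     [feats[i][1] for i in idx],
                                     [feats[i][2] for i in idx])
        pools = np.array([[i] + sample_negatives(masks, int(i), k, rng_local)
                          for i in idx])
        emb = head(Tensor(pooled[pools.reshape(-1)])).reshape(
            len(idx), k + 1, -1)
        if normalize:
            z_gs = _l2norm(z_gs)
            emb = _l2norm(emb)
        logits = (emb * z_gs.reshape(len(idx), 1, -1)).sum(axis=2)
        lse = logits.logsumexp(axis=-1)
        return (lse - logits[:, 0]).mean()

    def heldout_loss() -> float:
        r = np.random.default_rng(seed + 1)
        with nn.no_grad():
            return float(batch_loss(hold_idx, r).data)

    history["heldout"].append(heldout_loss())
    for epoch in range(epochs):
        opt.lr = epoch_lr(epoch)
        order = rng.permutation(train_idx)
        ep = []
        for s in range(0, len(order), batch_size):
            idx = order[s:s + batch_size]
            loss = batch_loss(idx, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        history["train"].append(float(np.mean(ep)))
        history["heldout"].append(heldout_loss())
    return GlobalPretrainResult(encoder=encoder, head=head, history=history,
                                normalize=normalize)


def retrieval_top1(result: GlobalPretrainResult, dataset: list[RenderedScene],
                   codec_m: Codec, indices: list[int], n_negatives: int = 15,
                   seed: int = 0,
                   class_table: ClassTable | None = None) -> float:
    """Fraction of probes whose compliant mask embedding is ranked first by
    dot product against `n_negatives` random other-frame mask embeddings."""
    if class_table is None:
        from .scenes import default_class_table
        class_table = default_class_table()
    rng = np.random.default_rng(seed)
    pooled = _pooled_mask_latents(codec_m, dataset)
    masks = [s.mask for s in dataset]
    hits = 0
    for i in indices:
        graph = mask_to_graph(dataset[i].mask, class_table)
        with nn.no_grad():
            z_g = result.encoder.forward_graph(graph)
            if result.normalize:
                z_g = _l2norm(z_g)
        negs = sample_negatives(masks, i, n_negatives, rng)
        with nn.no_grad():
            emb = result.head(Tensor(pooled[[i] + negs]))
            if result.normalize:
                emb = _l2norm(emb)
        scores = emb.data @ z_g.data
        if np.argmax(scores) == 0:
            hits += 1
    return hits / len(indices)
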
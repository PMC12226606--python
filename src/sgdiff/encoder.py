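"""Stacked message-passing graph encoder with mean-pooling readout.

Each layer updates node states as

    h_v' = relu(W [h_v ; agg_{u in N(v)} msg(h_u, r_{u->v})] + b)

where msg is an MLP over the sender state concatenated with a learned
embedding of the edge relation, and agg is a permutation-invariant
aggregation (sum, mean or max) over in-edges; a node with no in-neighbours
aggregates the zero message. Final node states are mean-pooled and projected
to the embedding dimension. The same architecture is instantiated twice in
the pipeline: once pre-trained for local detail (masked-latent
reconstruction) and once for global layout (contrastive mask alignment).

The empty graph maps to the all-zero embedding — the natural null
conditioning for "remove everything" edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .graphs import RELATIONS, SceneGraph, graph_to_features

__all__ = ["GraphEncoderConfig", "GraphEmbedding", "GNNLayer", "GraphEncoder",
           "encode_graph"]


@dataclass(frozen=True)
class GraphEncoderConfig:
    n_classes: int = 10
    num_layers: int = 3
    hidden_dim: int = 128
    out_dim: int = 128
    aggregation: str = "mean"   # sum | mean | max
    relation_embed_dim: int = 16

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("need at least one GNN layer")
        if self.aggregation not in ("sum", "mean", "max"):
            raise ValueError("aggregation must be sum, mean or max")

    @property
    def feature_dim(self) -> int:
        return self.n_classes + 5


@dataclass
class GraphEmbedding:
    values: np.ndarray   # (out_dim,)
    scope: str           # local | global


class GNNLayer(nn.Module):
    def __init__(self, dim: int, rel_dim: int, aggregation: str,
                 rng: np.random.Generator):
        self.msg = nn.MLP([dim + rel_dim, dim, dim], rng)
        self.update = nn.Linear(2 * dim, dim, rng)
        self.rel_emb = nn.Embedding(len(RELATIONS), rel_dim, rng)
        self.aggregation = aggregation

    def __call__(self, h: Tensor, edge_index: np.ndarray,
                 edge_type: np.ndarray) -> Tensor:
        n = h.shape[0]
        if len(edge_index):
            src, dst = edge_index[:, 0], edge_index[:, 1]
            m = self.msg(nn.concatenate([h[src], self.rel_emb(edge_type)], axis=1))
            if self.aggregation == "max":
                agg = nn.segment_max(m, dst, n)
            else:
                agg = nn.segment_sum(m, dst, n)
                if self.aggregation == "mean":
                    counts = np.maximum(np.bincount(dst, minlength=n), 1)
                    agg = agg / Tensor(counts[:, None].astype(np.float64))
        else:
            agg = Tensor(np.zeros_like(h.data))
        return self.update(nn.concatenate([h, agg], axis=1)).relu()


class GraphEncoder(nn.Module):
    def __init__(self, config: GraphEncoderConfig, rng: np.random.Generator,
                 scope: str = "local"):
        self.config = config
        self.scope = scope
        self.input_proj = nn.Linear(config.feature_dim, config.hidden_dim, rng)
        self.layers = [GNNLayer(config.hidden_dim, config.relation_embed_dim,
                                config.aggregation, rng)
                       for _ in range(config.num_layers)]
        self.readout = nn.Linear(config.hidden_dim, config.out_dim, rng)

    def forward_features(self, feats: np.ndarray, edge_index: np.ndarray,
                         edge_type: np.ndarray) -> Tensor:
        """Graph-level embedding Tensor (for training); zero for empty graphs."""
        if len(feats) == 0:
            return Tensor(np.zeros(self.config.out_dim))
        h = self.input_proj(Tensor(np.asarray(feats, dtype=np.float64))).relu()
        for layer in self.layers:
            h = layer(h, edge_index, edge_type)
        pooled = h.mean(axis=0)
        return self.readout(pooled.reshape(1, -1)).reshape(-1)

    def forward_graph(self, graph: SceneGraph) -> Tensor:
        feats, ei, et = graph_to_features(graph, self.config.n_classes)
        return self.forward_features(feats, ei, et)

    def forward_batch(self, feats_list, ei_list, et_list) -> Tensor:
        """Batched graph embeddings, (B, out_dim).

        Graphs are merged into one block-diagonal graph (node features
        stacked, edge indices offset), run through the layers once, and
        mean-pooled per graph — identical numerics to per-graph forwards,
        one pass instead of B. Empty graphs yield zero rows.
        """
        B = len(feats_list)
        sizes = np.array([len(f) for f in feats_list])
        if sizes.sum() == 0:
            return Tensor(np.zeros((B, self.config.out_dim)))
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        feats = np.concatenate([np.atleast_2d(f).reshape(-1, self.config.feature_dim)
                                for f in feats_list])
        edges = [np.asarray(ei).reshape(-1, 2) + off
                 for ei, off in zip(ei_list, offsets)]
        ei = np.concatenate(edges) if edges else np.zeros((0, 2), dtype=np.intp)
        et = (np.concatenate([np.asarray(e, dtype=np.intp) for e in et_list])
              if et_list else np.zeros(0, dtype=np.intp))
        graph_id = np.repeat(np.arange(B), sizes)
        h = self.input_proj(Tensor(np.asarray(feats, dtype=np.float64))).relu()
        for layer in self.layers:
            h = layer(h, ei.astype(np.intp), et)
        pooled = nn.segment_sum(h, graph_id, B) / Tensor(
            np.maximum(sizes, 1)[:, None].astype(np.float64))
        out = self.readout(pooled)
        if np.any(sizes == 0):
            out = out * Tensor((sizes > 0)[:, None].astype(np.float64))
        return out


def encode_graph(encoder: GraphEncoder, graph: SceneGraph) -> GraphEmbedding:
    with nn.no_grad():
        z = encoder.forward_graph(graph)
    return GraphEmbedding(values=z.data.copy(), scope=encoder.scope)
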
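"""Network building blocks on top of the autograd engine.

Initialisation is explicit about its RNG: every module takes a
``numpy.random.Generator`` so a pipeline seed fully determines the weights.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "LayerNorm",
    "Embedding",
    "SelfAttention",
    "TransformerBlock",
    "FiLM",
    "timestep_embedding",
]


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.W = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Stack of Linear layers with a chosen hidden activation."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu"):
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = getattr(x, self.activation)()
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.02, size=(num, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W[np.asarray(idx, dtype=np.intp)]


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention over (T, D) tokens."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.scale = 1.0 / np.sqrt(dim)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.q(x), self.k(x), self.v(x)
        att = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * self.scale
        att = att.softmax(axis=-1)
        return self.proj(att @ v)


class TransformerBlock(Module):
    """Pre-LN transformer block (attention + MLP, residual connections)."""

    def __init__(self, dim: int, mlp_ratio: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP([dim, mlp_ratio * dim, dim], rng, activation="gelu")

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.mlp(self.ln2(x))
        return x


class FiLM(Module):
    """Feature-wise affine modulation from a conditioning vector.

    Emits per-feature (scale, shift); scale is parameterised as (1 + ds)
    so a zero conditioning vector leaves activations untouched.
    """

    def __init__(self, cond_dim: int, feat_dim: int, rng: np.random.Generator):
        self.net = Linear(cond_dim, 2 * feat_dim, rng)
        self.feat_dim = feat_dim

    def __call__(self, h: Tensor, cond: Tensor) -> Tensor:
        out = self.net(cond)
        ds = out[..., : self.feat_dim]
        shift = out[..., self.feat_dim:]
        return h * (1.0 + ds) + shift


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (len(t), dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb
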
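"""Discrete latent autoencoders for images and masks.

Two separately trained vector-quantised autoencoders provide the latent
spaces the rest of the pipeline works in: E_x embeds RGB images and E_m
embeds one-hot segmentation masks. Each maps an (H, W, C) raster to an
(H/f, W/f, d) grid of codebook vectors (f the downsample factor) through a
per-patch encoder MLP, a nearest-neighbour codebook lookup with a
straight-through gradient, and a per-patch decoder MLP. The codebook is
maintained by exponential-moving-average updates with dead-code re-seeding.

An optional patch discriminator (``use_adversarial``) adds a lightweight
adversarial term for sharper image reconstructions; it is off by default,
where the codecs only need to be faithful embedding providers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .scenes import RenderedScene

__all__ = [
    "CodecConfig",
    "LatentGrid",
    "Codec",
    "vq_quantize",
    "train_codec",
    "encode",
    "decode",
    "one_hot_mask",
]


@dataclass(frozen=True)
class CodecConfig:
    input_kind: str = "image"          # image | mask
    n_channels: int = 3                # 3 for images, |classes| for masks
    downsample_factor: int = 4
    codebook_size: int = 256
    code_dim: int = 32
    hidden_dim: int = 128
    latent_size: int | None = None     # latent grid side; enables positional
                                       # embeddings so codes are layout-aware
    commit_weight: float = 0.25
    use_adversarial: bool = False
    adv_weight: float = 0.1
    epochs: int = 20
    batch_size: int = 32
    lr: float = 3e-3
    ema_decay: float = 0.99
    dead_code_steps: int = 100

    def __post_init__(self):
        if self.downsample_factor not in (2, 4, 8):
            raise ValueError("downsample_factor must be one of {2, 4, 8}")
        if self.codebook_size < 2:
            raise ValueError("codebook_size must be >= 2")
        if self.input_kind not in ("image", "mask"):
            raise ValueError("input_kind must be 'image' or 'mask'")


@dataclass
class LatentGrid:
    values: np.ndarray            # (h, w, d)
    codes: np.ndarray | None      # (h, w) codebook indices, None if unquantised
    source_kind: str              # image | mask | masked_image


def vq_quantize(codebook: np.ndarray, z: np.ndarray):
    """Nearest-codebook-entry quantisation.

    codes[...] = argmin_k ||z[...] - codebook[k]||_2, ties broken toward the
    lowest index (np.argmin convention). Returns (z_q, codes,
    commitment_loss) with commitment_loss = mean ||z - z_q||^2 over entries.
    """
    codebook = np.asarray(codebook)
    z = np.asarray(z)
    if codebook.size == 0:
        raise ValueError("codebook is empty")
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite values in latent input")
    flat = z.reshape(-1, z.shape[-1])
    # ||z - e||^2 = ||z||^2 - 2 z.e + ||e||^2
    d2 = (
        (flat**2).sum(axis=1, keepdims=True)
        - 2.0 * flat @ codebook.T
        + (codebook**2).sum(axis=1)[None, :]
    )
    codes = np.argmin(d2, axis=1)
    z_q = codebook[codes].reshape(z.shape)
    commit = float(((z - z_q) ** 2).mean())
    return z_q, codes.reshape(z.shape[:-1]), commit


def one_hot_mask(mask: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros(mask.shape + (n_classes,))
    ys, xs = np.meshgrid(*(np.arange(s) for s in mask.shape), indexing="ij")
    out[ys, xs, mask] = 1.0
    return out


class Codec(nn.Module):
    """Per-patch VQ autoencoder; see module docstring."""

    def __init__(self, config: CodecConfig, rng: np.random.Generator):
        self.config = config
        f, c = config.downsample_factor, config.n_channels
        patch = f * f * c
        self.enc = nn.MLP([patch, config.hidden_dim, config.code_dim], rng)
        self.dec = nn.MLP([config.code_dim, config.hidden_dim, patch], rng)
        # positional embeddings make the latent codes layout-aware, so even
        # spatially pooled latents retain where content sits (a stand-in for
        # the wide receptive field of a convolutional codec)
        self.enc_pos = self.dec_pos = None
        if config.latent_size is not None:
            s = config.latent_size
            self.enc_pos = Tensor(rng.normal(0.0, 0.1, (s, s, config.hidden_dim)),
                                  requires_grad=True)
            self.dec_pos = Tensor(rng.normal(0.0, 0.1, (s, s, config.hidden_dim)),
                                  requires_grad=True)
        self.codebook = rng.normal(0.0, 0.5, size=(config.codebook_size,
                                                   config.code_dim))
        # EMA state; codebook is (re-)seeded from encoder outputs on the
        # first update so codes start inside the data distribution
        self._ema_size = np.ones(config.codebook_size)
        self._ema_sum = self.codebook.copy()
        self._unused = np.zeros(config.codebook_size, dtype=np.int64)
        self._initialized = False
        self.history: dict[str, list[float]] = {"train": [], "heldout": []}
        if config.use_adversarial:
            self.disc = nn.MLP([patch, config.hidden_dim, 1], rng)

    # -- patch plumbing ------------------------------------------------
    def _patchify(self, x: np.ndarray) -> np.ndarray:
        f = self.config.downsample_factor
        B, H, W, C = x.shape
        x = x.reshape(B, H // f, f, W // f, f, C).transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(B, H // f, W // f, f * f * C)

    def _unpatchify(self, p: np.ndarray, H: int, W: int) -> np.ndarray:
        f = self.config.downsample_factor
        B, h, w, _ = p.shape
        p = p.reshape(B, h, w, f, f, -1).transpose(0, 1, 3, 2, 4, 5)
        return p.reshape(B, H, W, -1)

    def encode_tensor(self, x: np.ndarray) -> Tensor:
        """Continuous (pre-quantisation) latents with gradient tracking."""
        h = self.enc.layers[0](Tensor(self._patchify(x))).relu()
        if self.enc_pos is not None:
            if h.shape[1:3] != self.enc_pos.shape[:2]:
                raise ValueError(f"latent grid {h.shape[1:3]} does not match "
                                 f"configured latent_size {self.config.latent_size}")
            h = h + self.enc_pos
        return self.enc.layers[1](h)

    def decode_tensor(self, z: Tensor, H: int, W: int) -> Tensor:
        h = self.dec.layers[0](z).relu()
        if self.dec_pos is not None:
            h = h + self.dec_pos
        p = self.dec.layers[1](h)
        f = self.config.downsample_factor
        B, h, w, _ = p.shape
        p = p.reshape(B, h, w, f, f, self.config.n_channels)
        p = p.transpose(0, 1, 3, 2, 4, 5)
        return p.reshape(B, H, W, self.config.n_channels)

    # -- EMA codebook maintenance -------------------------------------
    def _update_codebook(self, z_flat: np.ndarray, codes: np.ndarray,
                         rng: np.random.Generator) -> None:
        cfg = self.config
        K = cfg.codebook_size
        if not self._initialized:
            picks = rng.integers(0, len(z_flat), size=K)
            self.codebook = z_flat[picks] + 1e-4 * rng.standard_normal((K, z_flat.shape[1]))
            self._ema_sum = self.codebook.copy()
            self._ema_size[:] = 1.0
            self._initialized = True
            _, codes, _ = vq_quantize(self.codebook, z_flat)
        onehot_sum = np.bincount(codes, minlength=K).astype(np.float64)
        vec_sum = np.zeros_like(self._ema_sum)
        np.add.at(vec_sum, codes, z_flat)
        d = cfg.ema_decay
        self._ema_size = d * self._ema_size + (1 - d) * onehot_sum
        self._ema_sum = d * self._ema_sum + (1 - d) * vec_sum
        self.codebook = self._ema_sum / np.maximum(self._ema_size, 1e-6)[:, None]
        # dead-code re-seeding: codes unseen for `dead_code_steps` updates
        used = onehot_sum > 0
        self._unused = np.where(used, 0, self._unused + 1)
        dead = np.nonzero(self._unused >= cfg.dead_code_steps)[0]
        if len(dead) and len(z_flat):
            picks = rng.integers(0, len(z_flat), size=len(dead))
            self.codebook[dead] = z_flat[picks]
            self._ema_sum[dead] = z_flat[picks]
            self._ema_size[dead] = 1.0
            self._unused[dead] = 0

    # -- losses --------------------------------------------------------
    def _recon_loss(self, recon: Tensor, target: np.ndarray) -> Tensor:
        if self.config.input_kind == "mask":
            # softmax cross-entropy against the one-hot target
            logp = recon - recon.logsumexp(axis=-1, keepdims=True)
            return -(logp * target).sum(axis=-1).mean()
        return ((recon - Tensor(target)) ** 2).mean()

    def training_losses(self, x: np.ndarray, rng: np.random.Generator,
                        update_codebook: bool = True):
        """One training forward pass; returns (total_loss, recon_mse_float)."""
        B, H, W, _ = x.shape
        z = self.encode_tensor(x)
        z_q, codes, _ = vq_quantize(self.codebook, z.data)
        if update_codebook:
            self._update_codebook(z.data.reshape(-1, self.config.code_dim),
                                  codes.reshape(-1), rng)
        # straight-through: decoder sees z_q, gradient flows into z
        z_st = z + Tensor(z_q - z.data)
        recon = self.decode_tensor(z_st, H, W)
        loss = self._recon_loss(recon, x)
        commit = ((z - Tensor(z_q)) ** 2).mean()
        total = loss + self.config.commit_weight * commit
        return total, float(loss.data)


def encode(codec: Codec, raster: np.ndarray, source_kind: str | None = None) -> LatentGrid:
    """Quantised latent grid of a single (H, W, C) raster (eval mode)."""
    raster = np.asarray(raster, dtype=np.float64)
    cfg = codec.config
    if raster.ndim != 3 or raster.shape[2] != cfg.n_channels:
        raise ValueError(f"expected (H, W, {cfg.n_channels}) input, got {raster.shape}")
    if raster.shape[0] % cfg.downsample_factor or raster.shape[1] % cfg.downsample_factor:
        raise ValueError("spatial dims must be divisible by the downsample factor")
    with nn.no_grad():
        z = codec.encode_tensor(raster[None])
    z_q, codes, _ = vq_quantize(codec.codebook, z.data)
    return LatentGrid(values=z_q[0], codes=codes[0],
                      source_kind=source_kind or cfg.input_kind)


def decode(codec: Codec, latent: LatentGrid) -> np.ndarray:
    """Decode a latent grid back to raster space.

    Images come back as (H, W, 3) reals (unclipped); masks as (H, W,
    n_classes) class logits — take argmax for a hard mask.
    """
    f = codec.config.downsample_factor
    h, w, _ = latent.values.shape
    with nn.no_grad():
        out = codec.decode_tensor(Tensor(latent.values[None]), h * f, w * f)
    return out.data[0]


def _to_array(scene, kind: str, n_classes: int) -> np.ndarray:
    if isinstance(scene, RenderedScene):
        return scene.image if kind == "image" else one_hot_mask(scene.mask, n_classes)
    return np.asarray(scene, dtype=np.float64)


def train_codec(dataset, config: CodecConfig, seed: int,
                heldout_frac: float = 0.1) -> Codec:
    """Train a codec on rendered scenes (or raw rasters).

    The last ``heldout_frac`` of the dataset is never trained on; its
    reconstruction loss is recorded per epoch in ``codec.history``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    codec = Codec(config, rng)
    arrays = np.stack([_to_array(s, config.input_kind, config.n_channels)
                       for s in dataset])
    if arrays.shape[-1] != config.n_channels:
        raise ValueError(f"input has {arrays.shape[-1]} channels, "
                         f"config expects {config.n_channels}")
    n_hold = max(1, int(round(heldout_frac * len(arrays)))) if len(arrays) > 1 else 0
    train, hold = arrays[: len(arrays) - n_hold], arrays[len(arrays) - n_hold:]
    params = codec.enc.parameters() + codec.dec.parameters()
    if codec.enc_pos is not None:
        params += [codec.enc_pos, codec.dec_pos]
    opt = nn.Adam(params, lr=config.lr)
    d_opt = None
    if config.use_adversarial:
        d_opt = nn.Adam(codec.disc.parameters(), lr=config.lr)
    for _ in range(config.epochs):
        order = rng.permutation(len(train))
        ep_losses = []
        for start in range(0, len(train), config.batch_size):
            batch = train[order[start:start + config.batch_size]]
            total, recon_mse = codec.training_losses(batch, rng)
            if config.use_adversarial and config.input_kind == "image":
                total = total + _adversarial_terms(codec, batch, d_opt)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_losses.append(recon_mse)
        codec.history["train"].append(float(np.mean(ep_losses)))
        if len(hold):
            with nn.no_grad():
                _, hold_mse = codec.training_losses(hold, rng, update_codebook=False)
            codec.history["heldout"].append(hold_mse)
    return codec


def _adversarial_terms(codec: Codec, batch: np.ndarray, d_opt: nn.Adam) -> Tensor:
    """Least-squares patch-GAN terms; updates the discriminator in place and
    returns the generator's adversarial loss contribution."""
    B, H, W, _ = batch.shape
    real_p = Tensor(codec._patchify(batch).reshape(-1, codec.enc.layers[0].W.shape[0]))
    with nn.no_grad():
        z = codec.encode_tensor(batch)
        z_q, _, _ = vq_quantize(codec.codebook, z.data)
        fake = codec.decode_tensor(Tensor(z_q), H, W).data
    fake_p_d = Tensor(codec._patchify(fake).reshape(real_p.shape))
    d_loss = (((codec.disc(real_p) - 1.0) ** 2).mean()
              + (codec.disc(fake_p_d) ** 2).mean())
    d_opt.zero_grad()
    d_loss.backward()
    d_opt.step()
    # generator term: fool the (frozen) discriminator on a fresh decode
    z = codec.encode_tensor(batch)
    z_q, _, _ = vq_quantize(codec.codebook, z.data)
    z_st = z + Tensor(z_q - z.data)
    recon = codec.decode_tensor(z_st, H, W)
    f = codec.config.downsample_factor
    rp = recon.reshape(B, H // f, f, W // f, f, codec.config.n_channels)
    rp = rp.transpose(0, 1, 3, 2, 4, 5).reshape(-1, real_p.shape[-1])
    for p in codec.disc.parameters():
        p.requires_grad = False
    g_loss = ((codec.disc(rp) - 1.0) ** 2).mean()
    for p in codec.disc.parameters():
        p.requires_grad = True
    return codec.config.adv_weight * g_loss
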
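"""Conditional denoising diffusion (DDPM) with classifier-free guidance.

Forward process: x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps with a linear
beta schedule. Training minimises E ||eps - eps_theta(x_t, t, c)||^2 where
the conditioning c — the concatenation of the local and global graph
embeddings — is replaced by the null (all-zero) conditioning with
probability ``cond_drop_prob`` (default 0.2), so a single network serves
both guidance branches. Sampling is DDPM ancestral with the guided noise

    eps' = (1 + omega) eps_theta(x_t, t, c) - omega eps_theta(x_t, t)

(omega defaults to 2.0) and posterior variance beta-tilde; the final t=1
step adds no noise.

The denoiser is an MLP over the flattened state with sinusoidal time
embeddings and adaptive layer-norm (FiLM) conditioning per hidden block —
adequate at the package's working sizes, where diffusion runs either in the
image codec's latent grid (default) or directly in pixel/feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NoiseSchedule",
    "Conditioning",
    "DiffusionConfig",
    "make_schedule",
    "q_sample",
    "DenoiserMLP",
    "DenoiserTransformer",
    "build_denoiser",
    "ddm_loss",
    "cfg_predict",
    "p_sample_step",
    "sample",
    "train_diffusion",
    "DiffusionModel",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Tables beta_t, alpha_t = 1 - beta_t and abar_t = prod alpha, t = 1..T
    (stored 0-based: beta[t-1] is the step-t coefficient)."""

    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    @property
    def T(self) -> int:
        return len(self.beta)

    def abar(self, t) -> np.ndarray:
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"t must lie in 1..{self.T}")
        return self.alpha_bar[t - 1]


def make_schedule(T: int, beta_min: float = 1e-4, beta_max: float = 0.02) -> NoiseSchedule:
    """Linear beta schedule from beta_min to beta_max over T steps."""
    if T < 1 or not (0 <= beta_min <= beta_max < 1):
        raise ValueError("need T >= 1 and 0 <= beta_min <= beta_max < 1")
    beta = np.linspace(beta_min, beta_max, T)
    alpha = 1.0 - beta
    return NoiseSchedule(beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


def q_sample(x0: np.ndarray, t, epsilon: np.ndarray,
             schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward marginal x_t = sqrt(abar) x0 + sqrt(1-abar) eps.

    `t` may be a scalar or a per-sample vector matching x0's leading axis.
    """
    abar = schedule.abar(t)
    abar = np.reshape(abar, (-1,) + (1,) * (x0.ndim - 1)) if np.ndim(t) else abar
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * epsilon


@dataclass(frozen=True)
class Conditioning:
    values: np.ndarray
    is_null: bool = False

    @staticmethod
    def null(dim: int) -> "Conditioning":
        return Conditioning(values=np.zeros(dim), is_null=True)

    @staticmethod
    def fuse(local_emb, global_emb) -> "Conditioning":
        """c = concat(z_G_local, z_G_global)."""
        a = getattr(local_emb, "values", local_emb)
        b = getattr(global_emb, "values", global_emb)
        return Conditioning(values=np.concatenate([np.asarray(a), np.asarray(b)]))


@dataclass(frozen=True)
class DiffusionConfig:
    T: int = 200
    beta_min: float = 1e-4
    beta_max: float = 0.02
    space: str = "latent"            # latent | pixel
    omega: float = 2.0
    cond_drop_prob: float = 0.2
    denoiser: str = "mlp"            # mlp | transformer
    hidden_dim: int = 256
    depth: int = 3
    time_embed_dim: int = 64
    # transformer denoiser: latent grid is grouped into token_patch x
    # token_patch tokens; width is the token embedding dimension
    token_patch: int = 2
    width: int = 96
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    # standardise each latent dimension separately before diffusion; this
    # puts rare, small-amplitude structure (thin instruments) on the same
    # footing as the dominant anatomy variation
    per_dim_standardize: bool = False

    def __post_init__(self):
        if not (0 <= self.cond_drop_prob < 1):
            raise ValueError("cond_drop_prob must be in [0, 1)")
        if self.omega < -1:
            raise ValueError("omega must be >= -1")
        if self.space not in ("latent", "pixel"):
            raise ValueError("space must be 'latent' or 'pixel'")


class _CondMixin:
    """Conditioning pre-processing shared by the denoisers.

    Graph embeddings arrive with arbitrary per-dimension offsets and scales
    (the contrastive stage in particular grows large norms), which destroys
    adaptive-norm conditioning; each dimension is standardised with
    statistics fixed at training time. Rows that are exactly zero mark the
    dropped/unconditional branch and are replaced by a learned null token.
    """

    def _init_cond(self, cond_dim: int):
        self.cond_mu = np.zeros(cond_dim)
        self.cond_scale = np.ones(cond_dim)
        self.null_cond = Tensor(np.zeros(cond_dim), requires_grad=True)

    def set_cond_stats(self, conds: np.ndarray) -> None:
        self.cond_mu = conds.mean(axis=0)
        std = conds.std(axis=0)
        self.cond_scale = np.where(std < 1e-8, 1.0, std)

    def _prep_cond(self, c: Tensor, B: int) -> Tensor:
        if c.ndim == 1:
            c = c.reshape(1, -1)
        if c.shape[0] == 1 and B > 1:
            c = nn.concatenate([c] * B, axis=0)
        null_rows = (np.abs(c.data).max(axis=1) == 0.0)[:, None]
        c_std = (c - Tensor(self.cond_mu)) / Tensor(self.cond_scale)
        return (c_std * Tensor(1.0 - null_rows)
                + self.null_cond.reshape(1, -1) * Tensor(null_rows * 1.0))


class DenoiserMLP(_CondMixin, nn.Module):
    """eps_theta(x_t, t, c): MLP with FiLM conditioning on (time, c)."""

    def __init__(self, data_dim: int, cond_dim: int, config: DiffusionConfig,
                 rng: np.random.Generator):
        self.data_dim = data_dim
        self.cond_dim = cond_dim
        self.config = config
        ctx = config.time_embed_dim + cond_dim
        self.time_mlp = nn.MLP([config.time_embed_dim, config.time_embed_dim], rng)
        self.input = nn.Linear(data_dim, config.hidden_dim, rng)
        self.hidden = [nn.Linear(config.hidden_dim, config.hidden_dim, rng)
                       for _ in range(config.depth)]
        self.norms = [nn.LayerNorm(config.hidden_dim) for _ in range(config.depth)]
        self.films = [nn.FiLM(ctx, config.hidden_dim, rng)
                      for _ in range(config.depth)]
        self.output = nn.Linear(config.hidden_dim, data_dim, rng)
        # conditioned per-dimension input skip: the identity-like component
        # of eps-prediction (eps ~ sqrt(1-abar_t) x_t at high noise) must not
        # squeeze through the hidden bottleneck — same role as UNet skips
        self.skip = nn.Linear(ctx, data_dim, rng)
        self._init_cond(cond_dim)

    def __call__(self, x_t: np.ndarray | Tensor, t, cond: np.ndarray | Tensor) -> Tensor:
        """x_t (B, D); t scalar or (B,); cond (B, cond_dim) (zeros = null)."""
        x = x_t if isinstance(x_t, Tensor) else Tensor(np.asarray(x_t, dtype=np.float64))
        c = cond if isinstance(cond, Tensor) else Tensor(np.asarray(cond, dtype=np.float64))
        B = x.shape[0]
        t_arr = np.full(B, t) if np.ndim(t) == 0 else np.asarray(t)
        temb = self.time_mlp(Tensor(
            nn.timestep_embedding(t_arr, self.config.time_embed_dim))).relu()
        c = self._prep_cond(c, B)
        ctx = nn.concatenate([temb, c], axis=1)
        h = self.input(x).relu()
        for lin, norm, film in zip(self.hidden, self.norms, self.films):
            h = h + film(norm(lin(h)), ctx).relu()
        return self.output(h) + self.skip(ctx) * x


class DenoiserTransformer(_CondMixin, nn.Module):
    """eps_theta over a latent grid, as a transformer on spatial tokens.

    The (h, w, d) grid is grouped into token_patch x token_patch tokens;
    each pre-LN block applies FiLM (adaptive layer-norm) conditioning on
    (time, c) before attention and before the MLP. Weight sharing across
    tokens gives the spatial inductive bias an MLP over the flattened grid
    lacks: sharp, localised structures (thin instruments) survive sampling
    instead of being regressed into the conditional mean.
    """

    def __init__(self, latent_shape: tuple[int, int, int], cond_dim: int,
                 config: DiffusionConfig, rng: np.random.Generator):
        h, w, d = latent_shape
        p = config.token_patch
        if h % p or w % p:
            raise ValueError("latent grid not divisible by token_patch")
        self.latent_shape = tuple(latent_shape)
        self.data_dim = h * w * d
        self.cond_dim = cond_dim
        self.config = config
        self._tok = (h // p, w // p, p * p * d)
        n_tokens = self._tok[0] * self._tok[1]
        width = config.width
        ctx = config.time_embed_dim + cond_dim
        self.time_mlp = nn.MLP([config.time_embed_dim, config.time_embed_dim], rng)
        self.token_in = nn.Linear(self._tok[2], width, rng)
        self.pos = Tensor(rng.normal(0.0, 0.02, (n_tokens, width)),
                          requires_grad=True)
        # conditioning enters twice: FiLM modulation per block (global
        # style) and a learned projection onto per-token features (spatial
        # layout), so "paint class k at position p" is directly expressible
        self.cond_spatial = nn.Linear(config.time_embed_dim + cond_dim,
                                      n_tokens * width, rng)
        self.ln1 = [nn.LayerNorm(width) for _ in range(config.depth)]
        self.attn = [nn.SelfAttention(width, rng) for _ in range(config.depth)]
        self.film1 = [nn.FiLM(ctx, width, rng) for _ in range(config.depth)]
        self.ln2 = [nn.LayerNorm(width) for _ in range(config.depth)]
        self.mlps = [nn.MLP([width, 2 * width, width], rng, activation="gelu")
                     for _ in range(config.depth)]
        self.film2 = [nn.FiLM(ctx, width, rng) for _ in range(config.depth)]
        self.out_ln = nn.LayerNorm(width)
        self.token_out = nn.Linear(width, self._tok[2], rng)
        self.skip = nn.Linear(ctx, 1, rng)  # conditioned scalar input gate
        self._init_cond(cond_dim)

    def _to_tokens(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        h, w, d = self.latent_shape
        p = self.config.token_patch
        g = x.reshape(B, h // p, p, w // p, p, d).transpose(0, 1, 3, 2, 4, 5)
        return g.reshape(B, self._tok[0] * self._tok[1], self._tok[2])

    def _from_tokens(self, t: Tensor, B: int) -> Tensor:
        h, w, d = self.latent_shape
        p = self.config.token_patch
        g = t.reshape(B, h // p, w // p, p, p, d).transpose(0, 1, 3, 2, 4, 5)
        return g.reshape(B, h * w * d)

    def __call__(self, x_t, t, cond) -> Tensor:
        x = np.asarray(x_t.data if isinstance(x_t, Tensor) else x_t,
                       dtype=np.float64)
        c = cond if isinstance(cond, Tensor) else Tensor(
            np.asarray(cond, dtype=np.float64))
        B = x.shape[0]
        t_arr = np.full(B, t) if np.ndim(t) == 0 else np.asarray(t)
        temb = self.time_mlp(Tensor(
            nn.timestep_embedding(t_arr, self.config.time_embed_dim))).relu()
        c = self._prep_cond(c, B)
        ctx = nn.concatenate([temb, c], axis=1)
        ctx3 = ctx.reshape(B, 1, ctx.shape[1])
        n_tokens = self.pos.shape[0]
        spatial = self.cond_spatial(ctx).reshape(B, n_tokens, -1)
        tok = self.token_in(Tensor(self._to_tokens(x))) + self.pos + spatial
        for ln1, att, f1, ln2, mlp, f2 in zip(self.ln1, self.attn, self.film1,
                                              self.ln2, self.mlps, self.film2):
            tok = tok + att(f1(ln1(tok), ctx3))
            tok = tok + mlp(f2(ln2(tok), ctx3))
        out = self.token_out(self.out_ln(tok))
        flat = self._from_tokens(out, B)
        return flat + self.skip(ctx) * Tensor(x)


def build_denoiser(latent_shape, cond_dim: int, config: DiffusionConfig,
                   rng: np.random.Generator):
    if config.denoiser == "transformer":
        return DenoiserTransformer(tuple(latent_shape), cond_dim, config, rng)
    dim = int(np.prod(latent_shape))
    return DenoiserMLP(dim, cond_dim, config, rng)


def _cond_values(c, dim: int) -> np.ndarray:
    if c is None:
        return np.zeros(dim)
    return np.asarray(getattr(c, "values", c), dtype=np.float64)


def ddm_loss(model: DenoiserMLP, x0: np.ndarray, cond, schedule: NoiseSchedule,
             rng: np.random.Generator, cond_drop_prob: float = 0.2,
             return_info: bool = False):
    """Denoising score-matching loss on a batch.

    Per sample: t ~ U{1..T}, eps ~ N(0, I), x_t from the closed form; the
    conditioning row is zeroed with probability ``cond_drop_prob``. Returns
    the mean squared error between eps and the model's prediction (mean over
    batch and coordinates).
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=np.float64))
    B = x0.shape[0]
    cvals = np.atleast_2d(_cond_values(cond, model.cond_dim))
    if cvals.shape[0] == 1 and B > 1:
        cvals = np.repeat(cvals, B, axis=0)
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(x0.shape)
    x_t = q_sample(x0, t, eps, schedule)
    dropped = rng.random(B) < cond_drop_prob
    cvals = np.where(dropped[:, None], 0.0, cvals)
    pred = model(x_t, t, cvals)
    loss = ((pred - Tensor(eps)) ** 2).mean()
    if return_info:
        return loss, {"dropped": dropped, "t": t}
    return loss


def cfg_predict(model: DenoiserMLP, x_t: np.ndarray, t, cond,
                omega: float) -> np.ndarray:
    """Classifier-free-guided noise: (1+w) eps(x,t,c) - w eps(x,t)."""
    cvals = np.atleast_2d(_cond_values(cond, model.cond_dim))
    x2 = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    with nn.no_grad():
        eps_c = model(x2, t, cvals).data
        if omega == 0.0:
            out = eps_c
        else:
            eps_u = model(x2, t, np.zeros_like(cvals)).data
            out = (1.0 + omega) * eps_c - omega * eps_u
    return out.reshape(np.shape(x_t))


def p_sample_step(model: DenoiserMLP, x_t: np.ndarray, t: int, cond,
                  omega: float, schedule: NoiseSchedule,
                  rng: np.random.Generator) -> np.ndarray:
    """One DDPM ancestral step x_t -> x_{t-1} using the guided noise.

    Posterior mean (x_t - beta_t/sqrt(1-abar_t) eps') / sqrt(alpha_t) plus
    sigma_t z with sigma_t^2 = beta-tilde_t; the t=1 step is deterministic.
    """
    if t < 1 or t > schedule.T:
        raise ValueError(f"t must lie in 1..{schedule.T}")
    eps = cfg_predict(model, x_t, t, cond, omega)
    beta_t = schedule.beta[t - 1]
    alpha_t = schedule.alpha[t - 1]
    abar_t = schedule.alpha_bar[t - 1]
    mean = (x_t - beta_t / np.sqrt(1.0 - abar_t) * eps) / np.sqrt(alpha_t)
    if t == 1:
        return mean
    abar_prev = schedule.alpha_bar[t - 2]
    sigma2 = (1.0 - abar_prev) / (1.0 - abar_t) * beta_t
    return mean + np.sqrt(sigma2) * rng.standard_normal(np.shape(x_t))


def sample(model: DenoiserMLP, cond, omega: float, schedule: NoiseSchedule,
           n: int, rng: np.random.Generator | int,
           data_dim: int | None = None) -> np.ndarray:
    """Draw n samples by iterating the ancestral step from t = T to 1.

    `cond` may be a single Conditioning/vector (shared across samples) or an
    (n, cond_dim) array of per-sample conditionings.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    dim = data_dim or model.data_dim
    cvals = np.atleast_2d(_cond_values(cond, model.cond_dim))
    if cvals.shape[0] == 1 and n > 1:
        cvals = np.repeat(cvals, n, axis=0)
    x = rng.standard_normal((n, dim))
    for t in range(schedule.T, 0, -1):
        x = p_sample_step(model, x, t, cvals, omega, schedule, rng)
    return x


# ---- trained-model wrapper ----------------------------------------------

@dataclass
class DiffusionModel:
    """A trained denoiser plus everything needed to sample from it:
    schedule, data shape, and the standardisation applied to the data."""

    denoiser: DenoiserMLP
    schedule: NoiseSchedule
    config: DiffusionConfig
    data_shape: tuple          # shape of one un-flattened sample
    mu: np.ndarray             # per-dim standardisation
    sigma: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)

    def sample_arrays(self, cond, n: int, rng, omega: float | None = None) -> np.ndarray:
        omega = self.config.omega if omega is None else omega
        flat = sample(self.denoiser, cond, omega, self.schedule, n, rng)
        flat = flat * self.sigma + self.mu
        return flat.reshape((n,) + tuple(self.data_shape))


def train_diffusion(data: np.ndarray, conds: np.ndarray | None,
                    config: DiffusionConfig, seed: int,
                    heldout_frac: float = 0.1) -> DiffusionModel:
    """Train a denoiser on (N, ...) arrays with per-sample conditionings.

    Data is standardised to zero mean / unit scale (global scalars) before
    training; the returned model undoes this at sampling time.
    ``conds=None`` trains an unconditional model (cond_dim 1, always null).
    """
    data = np.asarray(data, dtype=np.float64)
    N = data.shape[0]
    data_shape = data.shape[1:]
    flat = data.reshape(N, -1)
    if config.per_dim_standardize:
        mu = flat.mean(axis=0)
        sigma = flat.std(axis=0) + 1e-3
    else:
        mu = flat.mean()
        sigma = flat.std() + 1e-8
    flat = (flat - mu) / sigma
    if conds is None:
        conds = np.zeros((N, 1))
        cond_dim = 1
    else:
        conds = np.asarray(conds, dtype=np.float64)
        cond_dim = conds.shape[1]
    rng = np.random.default_rng(seed)
    if config.denoiser == "transformer" and len(data_shape) != 3:
        raise ValueError("transformer denoiser needs (h, w, d) samples")
    model = build_denoiser(data_shape if len(data_shape) == 3 else (flat.shape[1],),
                           cond_dim, config, rng)
    model.set_cond_stats(conds)
    schedule = make_schedule(config.T, config.beta_min, config.beta_max)
    n_hold = max(1, int(round(heldout_frac * N))) if N > 4 else 0
    train_x, hold_x = flat[: N - n_hold], flat[N - n_hold:]
    train_c, hold_c = conds[: N - n_hold], conds[N - n_hold:]
    opt = nn.Adam(model.parameters(), lr=config.lr)
    history = {"train": [], "heldout": []}
    for epoch in range(config.epochs):
        # cosine decay to lr/20: late-stage refinement recovers the
        # small-magnitude (thin-structure) components of the score
        opt.lr = (config.lr / 20 + 0.5 * (config.lr - config.lr / 20)
                  * (1 + np.cos(np.pi * epoch / max(1, config.epochs))))
        order = rng.permutation(len(train_x))
        ep = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            loss = ddm_loss(model, train_x[idx], train_c[idx], schedule, rng,
                            config.cond_drop_prob)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        history["train"].append(float(np.mean(ep)))
        if n_hold:
            hrng = np.random.default_rng(seed + 1)
            with nn.no_grad():
                hl = ddm_loss(model, hold_x, hold_c, schedule, hrng,
                              cond_drop_prob=0.0)
            history["heldout"].append(float(hl.data))
    return DiffusionModel(denoiser=model, schedule=schedule, config=config,
                          data_shape=data_shape, mu=np.asarray(mu),
                          sigma=np.asarray(sigma), history=history)
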
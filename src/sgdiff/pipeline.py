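"""End-to-end experiment orchestration.

Stages, in dependency order: scene generation -> image & mask codecs ->
local (masked-reconstruction) and global (contrastive) graph-encoder
pre-training -> conditional diffusion training -> graph-conditioned
sampling -> reverse-workflow coherence evaluation. A single seed drives
every stage through named substreams, so a (config, seed) pair determines
the whole experiment.

When an output root is given, each stage persists a checkpoint and is
skipped (loaded) on re-runs if its checkpoint already exists; structured
JSON-lines events record per-stage seeds and durations.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .codec import Codec, CodecConfig, decode, train_codec, vq_quantize
from .diffusion import (Conditioning, DiffusionConfig, DiffusionModel,
                        build_denoiser, make_schedule, train_diffusion)
from .encoder import GraphEncoder, GraphEncoderConfig
from .evaluate import (RuleBasedDetector, coherence_score, codec_features,
                       fid_kid, pairwise_diversity)
from .graphs import SceneGraph, edit_graph, graph_to_json, mask_to_graph
from .pretrain_global import (GlobalPretrainResult, MaskProjectionHead,
                              train_global)
from .pretrain_local import (LocalDecoder, LocalDecoderConfig,
                             LocalPretrainResult, train_local)
from .scenes import (GeneratorConfig, RenderedScene, default_class_table,
                     generate_dataset, load_dataset, sample_scenes,
                     save_image_png)

__all__ = [
    "PipelineConfig",
    "PipelineArtifacts",
    "fit_pipeline",
    "run_pipeline",
    "conditioning_for_graph",
    "generate_images",
    "evaluate_conditioning",
    "demo_edit_and_sample",
    "toy_config",
]

_STAGES = ("data", "codec_image", "codec_mask", "pretrain_local",
           "pretrain_global", "diffusion", "samples", "report")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    canvas: int = 32
    n_scenes: int = 512
    n_eval: int = 50
    tool_count_range: tuple[int, int] = (0, 3)
    noise_sigma: float = 0.03
    # codecs; the image codec is the diffusion state, and it must preserve
    # thin instruments, hence the finer patch factor and compact codes
    code_dim: int = 8
    codebook_size: int = 256
    downsample_factor: int = 2
    mask_code_dim: int = 32
    mask_codebook_size: int = 256
    mask_downsample_factor: int = 4
    codec_hidden: int = 96
    codec_epochs: int = 14
    # graph encoders (compact embeddings condition the denoiser better
    # than wide ones at this scale)
    encoder_layers: int = 3
    encoder_hidden: int = 64
    encoder_out: int = 32
    relation_embed_dim: int = 8
    # pre-training
    local_epochs: int = 30
    local_model_dim: int = 64
    local_depth: int = 2
    global_epochs: int = 110
    global_k: int = 12
    # diffusion (transformer denoiser over grouped latent tokens)
    T: int = 200
    diffusion_width: int = 96
    diffusion_token_patch: int = 4
    diffusion_depth: int = 3
    diffusion_epochs: int = 100
    diffusion_batch: int = 64
    cond_drop_prob: float = 0.2
    omega: float = 2.0

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(canvas=self.canvas,
                               tool_count_range=self.tool_count_range,
                               noise_sigma=self.noise_sigma)

    def encoder_config(self, n_classes: int) -> GraphEncoderConfig:
        return GraphEncoderConfig(
            n_classes=n_classes, num_layers=self.encoder_layers,
            hidden_dim=self.encoder_hidden, out_dim=self.encoder_out,
            relation_embed_dim=self.relation_embed_dim)

    def diffusion_config(self) -> DiffusionConfig:
        return DiffusionConfig(
            T=self.T, denoiser="transformer", width=self.diffusion_width,
            token_patch=self.diffusion_token_patch, lr=2e-3,
            depth=self.diffusion_depth, epochs=self.diffusion_epochs,
            batch_size=self.diffusion_batch,
            cond_drop_prob=self.cond_drop_prob, omega=self.omega)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return PipelineConfig(**doc)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


def toy_config(**overrides) -> PipelineConfig:
    """The package's desk-scale defaults (32x32 canvas, 512 scenes)."""
    return replace(PipelineConfig(), **overrides)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (kept below 2**31).

    Stage names hash through crc32, which is stable across processes
    (unlike builtin str hashing).
    """
    idx = (_STAGES.index(stage) if stage in _STAGES
           else zlib.crc32(stage.encode()) % 1000 + 100)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class PipelineArtifacts:
    config: PipelineConfig
    class_table: object
    scenes_train: list[RenderedScene]
    scenes_eval: list[RenderedScene]
    codec_x: Codec
    codec_m: Codec
    local: LocalPretrainResult
    global_: GlobalPretrainResult
    diffusion: DiffusionModel

    @property
    def cond_dim(self) -> int:
        return 2 * self.config.encoder_out

    def eval_graphs(self) -> list[SceneGraph]:
        return [mask_to_graph(s.mask, self.class_table) for s in self.scenes_eval]


# ---- checkpoint I/O ------------------------------------------------------

def _save_module(path: Path, module: nn.Module, meta: dict,
                 extra: dict[str, np.ndarray] | None = None) -> None:
    state = {f"param_{k}": v for k, v in module.state_dict().items()}
    if extra:
        state.update({f"extra_{k}": np.asarray(v) for k, v in extra.items()})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def _load_npz(path: Path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        params = {k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")}
        extra = {k[len("extra_"):]: z[k] for k in z.files if k.startswith("extra_")}
    return meta, params, extra


class _Log:
    def __init__(self, out_root: Path | None):
        self.path = (out_root / "events.jsonl") if out_root else None

    def event(self, **kw) -> None:
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(kw) + "\n")


def _stage(log: _Log, name: str, seed: int, ckpt: Path | None, load_fn, run_fn,
           save_fn):
    t0 = time.time()
    if ckpt is not None and ckpt.exists():
        out = load_fn()
        log.event(stage=name, seed=seed, skipped=True,
                  duration_s=round(time.time() - t0, 3))
        return out
    out = run_fn()
    if ckpt is not None:
        save_fn(out)
    log.event(stage=name, seed=seed, skipped=False,
              duration_s=round(time.time() - t0, 3))
    return out


# ---- stage runners -------------------------------------------------------

def _fit_codec(scenes, kind: str, cfg: PipelineConfig, seed: int,
               n_classes: int) -> Codec:
    image = kind == "image"
    f = cfg.downsample_factor if image else cfg.mask_downsample_factor
    ccfg = CodecConfig(
        input_kind=kind, n_channels=3 if image else n_classes,
        downsample_factor=f,
        codebook_size=cfg.codebook_size if image else cfg.mask_codebook_size,
        code_dim=cfg.code_dim if image else cfg.mask_code_dim,
        hidden_dim=cfg.codec_hidden, epochs=cfg.codec_epochs,
        latent_size=cfg.canvas // f)
    return train_codec(scenes, ccfg, seed)


def _codec_ckpt(codec: Codec, path: Path) -> None:
    _save_module(path, codec, meta=asdict(codec.config),
                 extra={"codebook": codec.codebook})


def _codec_load(path: Path) -> Codec:
    meta, params, extra = _load_npz(path)
    codec = Codec(CodecConfig(**meta), np.random.default_rng(0))
    codec.load_state_dict(params)
    codec.codebook = extra["codebook"]
    return codec


def fit_pipeline(config: PipelineConfig, out_root: str | Path | None = None
                 ) -> PipelineArtifacts:
    """Run (or resume) every training stage and return the artifacts."""
    root = Path(out_root) if out_root else None
    if root:
        root.mkdir(parents=True, exist_ok=True)
    log = _Log(root)
    table = default_class_table()
    n_classes = len(table)
    gen_cfg = config.generator_config()

    # -- data
    s_data = stage_seed(config.seed, "data")

    def gen_scenes():
        return sample_scenes(config.n_scenes + config.n_eval, gen_cfg, s_data)

    if root:
        data_dir = root / "dataset"
        scenes = _stage(log, "data", s_data, data_dir / "index.json",
                        lambda: load_dataset(data_dir),
                        gen_scenes,
                        lambda sc: generate_dataset(len(sc), gen_cfg, s_data,
                                                    data_dir))
        # persisted images are 8-bit quantised; reload for bit-identical resume
        scenes = load_dataset(data_dir)
    else:
        scenes = gen_scenes()
    train_scenes = scenes[: config.n_scenes]
    eval_scenes = scenes[config.n_scenes:]

    # -- codecs
    s_cx = stage_seed(config.seed, "codec_image")
    codec_x = _stage(
        log, "codec_image", s_cx, root / "codec_image.npz" if root else None,
        (lambda: _codec_load(root / "codec_image.npz")) if root else None,
        lambda: _fit_codec(train_scenes, "image", config, s_cx, n_classes),
        lambda c: _codec_ckpt(c, root / "codec_image.npz"))
    s_cm = stage_seed(config.seed, "codec_mask")
    codec_m = _stage(
        log, "codec_mask", s_cm, root / "codec_mask.npz" if root else None,
        (lambda: _codec_load(root / "codec_mask.npz")) if root else None,
        lambda: _fit_codec(train_scenes, "mask", config, s_cm, n_classes),
        lambda c: _codec_ckpt(c, root / "codec_mask.npz"))

    enc_cfg = config.encoder_config(n_classes)

    # -- local pre-training
    s_loc = stage_seed(config.seed, "pretrain_local")
    f = config.downsample_factor
    n_tok = (config.canvas // f) ** 2
    dec_cfg = LocalDecoderConfig(
        code_dim=config.code_dim, n_tokens=n_tok,
        model_dim=config.local_model_dim, depth=config.local_depth,
        graph_dim=config.encoder_out,
        token_group=max(1, int(round(np.sqrt(n_tok) / 8))))

    def load_local() -> LocalPretrainResult:
        meta, params, extra = _load_npz(root / "pretrain_local.npz")
        rng = np.random.default_rng(0)
        enc = GraphEncoder(enc_cfg, rng, scope="local")
        dec = LocalDecoder(dec_cfg, rng)
        holder = nn.Module()
        holder.enc, holder.dec = enc, dec
        holder.load_state_dict(params)
        return LocalPretrainResult(encoder=enc, decoder=dec,
                                   history=meta["history"],
                                   fill=extra["fill"])

    def save_local(res: LocalPretrainResult) -> None:
        holder = nn.Module()
        holder.enc, holder.dec = res.encoder, res.decoder
        _save_module(root / "pretrain_local.npz", holder,
                     meta={"history": res.history}, extra={"fill": res.fill})

    local = _stage(
        log, "pretrain_local", s_loc,
        root / "pretrain_local.npz" if root else None,
        load_local if root else None,
        lambda: train_local(train_scenes, codec_x, enc_cfg, dec_cfg,
                            seed=s_loc, epochs=config.local_epochs,
                            class_table=table),
        save_local)

    # -- global pre-training
    s_glob = stage_seed(config.seed, "pretrain_global")

    def load_global() -> GlobalPretrainResult:
        meta, params, extra = _load_npz(root / "pretrain_global.npz")
        rng = np.random.default_rng(0)
        enc = GraphEncoder(enc_cfg, rng, scope="global")
        head = MaskProjectionHead(config.mask_code_dim, config.encoder_out, rng)
        holder = nn.Module()
        holder.enc, holder.head = enc, head
        holder.load_state_dict(params)
        return GlobalPretrainResult(encoder=enc, head=head,
                                    history=meta["history"],
                                    normalize=meta["normalize"])

    def save_global(res: GlobalPretrainResult) -> None:
        holder = nn.Module()
        holder.enc, holder.head = res.encoder, res.head
        _save_module(root / "pretrain_global.npz", holder,
                     meta={"history": res.history, "normalize": res.normalize})

    global_ = _stage(
        log, "pretrain_global", s_glob,
        root / "pretrain_global.npz" if root else None,
        load_global if root else None,
        lambda: train_global(train_scenes, codec_m, enc_cfg, k=config.global_k,
                             seed=s_glob, epochs=config.global_epochs,
                             class_table=table),
        save_global)

    # -- diffusion (frozen encoders supply the conditioning)
    s_diff = stage_seed(config.seed, "diffusion")
    latent_shape = (config.canvas // f, config.canvas // f, config.code_dim)

    def build_artifacts(diff: DiffusionModel) -> PipelineArtifacts:
        return PipelineArtifacts(
            config=config, class_table=table, scenes_train=train_scenes,
            scenes_eval=eval_scenes, codec_x=codec_x, codec_m=codec_m,
            local=local, global_=global_, diffusion=diff)

    def run_diffusion() -> DiffusionModel:
        latents = _scene_latents(codec_x, train_scenes)
        conds = np.stack([
            _fused_condition(local.encoder, global_.encoder,
                             mask_to_graph(s.mask, table))
            for s in train_scenes])
        return train_diffusion(latents, conds, config.diffusion_config(),
                               s_diff)

    def load_diffusion() -> DiffusionModel:
        meta, params, extra = _load_npz(root / "diffusion.npz")
        dcfg = DiffusionConfig(**meta["config"])
        den = build_denoiser(tuple(meta["data_shape"]), meta["cond_dim"], dcfg,
                             np.random.default_rng(0))
        den.load_state_dict(params)
        den.cond_mu = extra["cond_mu"]
        den.cond_scale = extra["cond_scale"]
        return DiffusionModel(
            denoiser=den, schedule=make_schedule(dcfg.T, dcfg.beta_min,
                                                 dcfg.beta_max),
            config=dcfg, data_shape=tuple(meta["data_shape"]),
            mu=extra["mu"], sigma=extra["sigma"], history=meta["history"])

    def save_diffusion(model: DiffusionModel) -> None:
        _save_module(root / "diffusion.npz", model.denoiser,
                     meta={"config": asdict(model.config),
                           "data_dim": model.denoiser.data_dim,
                           "cond_dim": model.denoiser.cond_dim,
                           "data_shape": list(model.data_shape),
                           "history": model.history},
                     extra={"mu": model.mu, "sigma": model.sigma,
                            "cond_mu": model.denoiser.cond_mu,
                            "cond_scale": model.denoiser.cond_scale})

    diffusion = _stage(
        log, "diffusion", s_diff, root / "diffusion.npz" if root else None,
        load_diffusion if root else None, run_diffusion, save_diffusion)
    assert tuple(diffusion.data_shape) == latent_shape
    return build_artifacts(diffusion)


def _scene_latents(codec_x: Codec, scenes) -> np.ndarray:
    images = np.stack([s.image for s in scenes])
    with nn.no_grad():
        z = codec_x.encode_tensor(images)
    z_q, _, _ = vq_quantize(codec_x.codebook, z.data)
    return z_q


def _fused_condition(enc_loc: GraphEncoder, enc_glob: GraphEncoder,
                     graph: SceneGraph) -> np.ndarray:
    with nn.no_grad():
        zl = enc_loc.forward_graph(graph).data
        zg = enc_glob.forward_graph(graph).data
    return np.concatenate([zl, zg])


def conditioning_for_graph(artifacts: PipelineArtifacts,
                           graph: SceneGraph) -> Conditioning:
    return Conditioning(values=_fused_condition(
        artifacts.local.encoder, artifacts.global_.encoder, graph))


def generate_images(artifacts: PipelineArtifacts, graphs: list[SceneGraph],
                    omega: float, seed: int,
                    conds: np.ndarray | None = None) -> np.ndarray:
    """Sample one image per conditioning graph and decode to pixel space."""
    if conds is None:
        conds = np.stack([conditioning_for_graph(artifacts, g).values
                          for g in graphs])
    latents = artifacts.diffusion.sample_arrays(
        conds, len(graphs), np.random.default_rng(seed), omega=omega)
    h, w, d = artifacts.diffusion.data_shape
    images = []
    from .codec import LatentGrid

    for lat in latents:
        img = decode(artifacts.codec_x,
                     LatentGrid(values=lat, codes=None, source_kind="image"))
        images.append(np.clip(img, 0.0, 1.0))
    return np.stack(images)


def evaluate_conditioning(artifacts: PipelineArtifacts,
                          graphs: list[SceneGraph] | None = None,
                          omega: float | None = None, seed: int = 0,
                          conds: np.ndarray | None = None):
    """Coherence of generated images with their conditioning graphs,
    plus the shuffled-condition null (same images, graphs rotated by one).

    Returns (matched_report, shuffled_report, images).
    """
    graphs = graphs if graphs is not None else artifacts.eval_graphs()
    omega = artifacts.config.omega if omega is None else omega
    images = generate_images(artifacts, graphs, omega, seed, conds=conds)
    detector = RuleBasedDetector(artifacts.class_table)
    dets = [detector(im) for im in images]
    matched = coherence_score(dets, graphs)
    shuffled_graphs = graphs[1:] + graphs[:1]  # derangement for n >= 2
    shuffled = coherence_score(dets, shuffled_graphs)
    return matched, shuffled, images


def run_pipeline(config: PipelineConfig, out_root: str | Path
                 ) -> dict:
    """Full experiment with persistence; returns the report dict."""
    root = Path(out_root)
    artifacts = fit_pipeline(config, root)
    log = _Log(root)
    report_path = root / "report.json"
    if report_path.exists():
        return json.loads(report_path.read_text())
    t0 = time.time()
    s_samp = stage_seed(config.seed, "samples")
    graphs = artifacts.eval_graphs()
    matched, shuffled, images = evaluate_conditioning(
        artifacts, graphs, config.omega, s_samp)
    samples_dir = root / "samples"
    samples_dir.mkdir(exist_ok=True)
    manifest = []
    for i, (im, g) in enumerate(zip(images, graphs)):
        rel = f"{i:04d}.png"
        save_image_png(samples_dir / rel, im)
        manifest.append({"image": rel, "graph": graph_to_json(g),
                         "omega": config.omega, "seed": s_samp})
    (samples_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    feats = codec_features(artifacts.codec_x)
    real = np.stack([s.image for s in artifacts.scenes_eval])
    fid, kid = fid_kid(real, images, feature_fn=feats)
    div = pairwise_diversity(images, feature_fn=feats)
    report = {
        "coherence": matched.to_json(),
        "coherence_shuffled": shuffled.to_json(),
        "fid": fid, "kid": kid, "diversity": div,
        "n_train_scenes": config.n_scenes, "omega": config.omega,
    }
    report_path.write_text(json.dumps(report, indent=1))
    log.event(stage="report", seed=s_samp, skipped=False,
              duration_s=round(time.time() - t0, 3))
    return report


def demo_edit_and_sample(artifacts: PipelineArtifacts, graph: SceneGraph,
                         edits, omega: float | None = None, n: int = 4,
                         seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Generate before/after sample sets for a graph edit.

    Mirrors the interactive protocol: condition on the ground-truth graph,
    apply edits (move / retype / delete), re-sample, and report coherence of
    each set against its own conditioning graph plus detection counts.
    """
    omega = artifacts.config.omega if omega is None else omega
    edited = edit_graph(graph, edits, artifacts.class_table)
    detector = RuleBasedDetector(artifacts.class_table)
    out: dict = {"omega": omega, "n": n, "edits": len(list(edits))}
    for tag, g in (("before", graph), ("after", edited)):
        conds = np.repeat(conditioning_for_graph(artifacts, g).values[None],
                          n, axis=0)
        images = generate_images(artifacts, [g] * n, omega, seed, conds=conds)
        dets = [detector(im) for im in images]
        rep = coherence_score(dets, [g] * n)
        tool_ids = set(artifacts.class_table.ids("tool"))
        out[tag] = {
            "conditioning_graph": graph_to_json(g),
            "coherence": rep.to_json(),
            "mean_tool_detections": float(np.mean(
                [sum(d.class_id in tool_ids for d in ds) for ds in dets])),
            "detected_centroids": [
                [{"class_id": d.class_id,
                  "centroid": [(d.box[0] + d.box[2]) / 2,
                               (d.box[1] + d.box[3]) / 2]} for d in ds]
                for ds in dets],
        }
        if out_dir:
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            for i, im in enumerate(images):
                save_image_png(d / f"{tag}_{i:02d}.png", im)
    if out_dir:
        (Path(out_dir) / "demo.json").write_text(json.dumps(out, indent=1))
    return out
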
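"""Reverse-workflow coherence evaluation and image-set metrics.

Coherence is scored by converting generated images back into object lists
and comparing them with the conditioning graphs: a detector predicts
per-class bounding boxes, detections are greedily matched to graph nodes of
the same class by descending IoU, and the report carries the mean best-IoU
over graph nodes (unmatched nodes score 0), the fraction of nodes matched
at IoU >= 0.5, and the detection F1 at the 0.5 IoU threshold.

For the package's synthetic scenes the detector is rule-based: each
non-background class has a known palette colour, so pixels within a
tolerance band of that colour are grouped into connected components and
each sufficiently large component becomes a detection with confidence 1.0.
A learned detector can be substituted through the same `detect_objects`
interface for real-data work.

Diversity and fidelity metrics are computed from a pluggable feature
embedding of the images (flattened pixels by default, or the trained image
codec's pooled latents): mean pairwise feature distance for diversity, the
Fréchet distance between Gaussian moment fits for FID, and an unbiased
polynomial-kernel MMD estimate for KID.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import sqrtm

from .graphs import SceneGraph
from .scenes import ClassTable

__all__ = [
    "Detection",
    "CoherenceReport",
    "iou",
    "RuleBasedDetector",
    "detect_objects",
    "coherence_score",
    "pairwise_diversity",
    "fid_kid",
    "flat_pixel_features",
    "codec_features",
]


def iou(box_a, box_b) -> float:
    """Intersection over union of two (x0, y0, x1, y1) boxes.

    Degenerate (non-positive-area) boxes score 0 by convention; disjoint
    boxes score 0.
    """
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a <= 0 or area_b <= 0:
        return 0.0
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class Detection:
    box: tuple[float, float, float, float]  # normalised (x0, y0, x1, y1)
    class_id: int
    score: float = 1.0


class RuleBasedDetector:
    """Colour-band + connected-component detector for synthetic scenes."""

    def __init__(self, class_table: ClassTable, tolerance: float = 0.13,
                 min_area_frac: float = 0.004, closing_frac: float = 0.1,
                 mode: str = "per_class"):
        self.class_table = class_table
        self.tolerance = tolerance
        self.min_area_frac = min_area_frac
        # a class region split by a thin occluder (an instrument crossing
        # the anatomy) is still one object: closing bridges gaps up to
        # closing_frac of the canvas before components are formed
        self.closing_frac = closing_frac
        # per_class: one detection per class, the union box of its non-speck
        # components — the exact mirror of graph extraction, which computes
        # one bounding box per class over all of its pixels (classes are
        # instance-like here). per_component: one detection per connected
        # component, for palettes where a class can appear as several
        # genuine instances.
        if mode not in ("per_class", "per_component"):
            raise ValueError("mode must be 'per_class' or 'per_component'")
        self.mode = mode

    def __call__(self, image: np.ndarray) -> list[Detection]:
        image = np.asarray(image, dtype=np.float64)
        H, W, _ = image.shape
        min_px = max(1, int(self.min_area_frac * H * W))
        close_iter = max(1, int(round(self.closing_frac * H / 2)))
        out: list[Detection] = []
        bg = self.class_table.background_id
        for entry in self.class_table.entries:
            if entry.class_id == bg:
                continue
            dist = np.abs(image - np.asarray(entry.color)).max(axis=2)
            hit = dist < self.tolerance
            if not hit.any():
                continue
            bridged = ndimage.binary_closing(
                hit, structure=np.ones((3, 3)), iterations=close_iter)
            labels, n = ndimage.label(bridged | hit)
            boxes = []
            for comp in range(1, n + 1):
                # boxes come from the actual colour-matching pixels; the
                # closed mask only decides the grouping
                ys, xs = np.nonzero((labels == comp) & hit)
                if len(xs) < min_px:
                    continue
                boxes.append((xs.min() / W, ys.min() / H,
                              (xs.max() + 1) / W, (ys.max() + 1) / H))
            if not boxes:
                continue
            if self.mode == "per_class":
                bs = np.asarray(boxes)
                out.append(Detection(
                    box=(bs[:, 0].min(), bs[:, 1].min(),
                         bs[:, 2].max(), bs[:, 3].max()),
                    class_id=entry.class_id, score=1.0))
            else:
                out.extend(Detection(box=b, class_id=entry.class_id,
                                     score=1.0) for b in boxes)
        return out


def detect_objects(image: np.ndarray, detector) -> list[Detection]:
    return detector(image)


@dataclass
class CoherenceReport:
    mean_iou: float
    f1: float
    iou_at_threshold: float      # fraction of graph nodes matched at >= thr
    per_class: dict[int, dict[str, float]]
    n_images: int
    iou_threshold: float = 0.5
    per_image_iou: list[float] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "mean_iou": self.mean_iou, "f1": self.f1,
            "iou_at_threshold": self.iou_at_threshold,
            "iou_threshold": self.iou_threshold, "n_images": self.n_images,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "per_image_iou": self.per_image_iou,
        }


def _greedy_match(nodes: list, detections: list[Detection]):
    """Greedy same-class matching by descending IoU; each node and each
    detection is used at most once. Returns {node_index: (det_index, iou)}."""
    pairs = []
    for ni, node in enumerate(nodes):
        for di, det in enumerate(detections):
            if det.class_id != node.class_id:
                continue
            v = iou(node.box(), det.box)
            if v > 0:
                pairs.append((v, ni, di))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_n, used_d, out = set(), set(), {}
    for v, ni, di in pairs:
        if ni in used_n or di in used_d:
            continue
        used_n.add(ni)
        used_d.add(di)
        out[ni] = (di, v)
    return out


def coherence_score(detections_per_image: list[list[Detection]],
                    graphs: list[SceneGraph],
                    iou_threshold: float = 0.5) -> CoherenceReport:
    """Score detections against their conditioning graphs.

    mean_iou aggregates each graph node's matched IoU (unmatched -> 0) over
    all nodes of all images; F1 counts a matched pair with IoU >= threshold
    as a true positive, any other detection as a false positive and any
    other graph node as a false negative.
    """
    if len(detections_per_image) != len(graphs):
        raise ValueError("need exactly one graph per image")
    tp = fp = fn = 0
    node_ious: list[float] = []
    per_image: list[float] = []
    per_class: dict[int, dict[str, float]] = {}
    for dets, graph in zip(detections_per_image, graphs):
        nodes = list(graph.nodes)
        match = _greedy_match(nodes, dets)
        img_ious = []
        matched_dets = set()
        for ni, node in enumerate(nodes):
            di_v = match.get(ni)
            v = di_v[1] if di_v else 0.0
            img_ious.append(v)
            node_ious.append(v)
            stats = per_class.setdefault(node.class_id,
                                         {"iou_sum": 0.0, "n": 0, "tp": 0,
                                          "fp": 0, "fn": 0})
            stats["iou_sum"] += v
            stats["n"] += 1
            if di_v and v >= iou_threshold:
                tp += 1
                stats["tp"] += 1
                matched_dets.add(di_v[0])
            else:
                fn += 1
                stats["fn"] += 1
        for di, det in enumerate(dets):
            if di not in matched_dets:
                fp += 1
                per_class.setdefault(det.class_id,
                                     {"iou_sum": 0.0, "n": 0, "tp": 0,
                                      "fp": 0, "fn": 0})["fp"] += 1
        per_image.append(float(np.mean(img_ious)) if img_ious else 1.0)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    for stats in per_class.values():
        stats["mean_iou"] = stats["iou_sum"] / stats["n"] if stats["n"] else 0.0
        del stats["iou_sum"]
    mean_iou = float(np.mean(node_ious)) if node_ious else 1.0
    at_thr = (float(np.mean([v >= iou_threshold for v in node_ious]))
              if node_ious else 1.0)
    return CoherenceReport(mean_iou=mean_iou, f1=f1, iou_at_threshold=at_thr,
                           per_class=per_class, n_images=len(graphs),
                           iou_threshold=iou_threshold, per_image_iou=per_image)


# ---- image-set metrics ---------------------------------------------------

def flat_pixel_features(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return arr.reshape(len(arr), -1)


def codec_features(codec):
    """Feature extractor: pooled quantised latents of the image codec."""
    from . import nn as _nn
    from .codec import vq_quantize

    def fn(images) -> np.ndarray:
        arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
        with _nn.no_grad():
            z = codec.encode_tensor(arr)
        z_q, _, _ = vq_quantize(codec.codebook, z.data)
        return z_q.mean(axis=(1, 2))

    return fn


def pairwise_diversity(images, feature_fn=None) -> float:
    """Mean pairwise RMS feature distance over all image pairs.

    With the default pixel features this is a plain distortion-based
    diversity score; pass a perceptual feature extractor for a perceptually
    weighted variant. A repeated identical image scores exactly 0.
    """
    if len(images) < 2:
        raise ValueError("diversity needs at least two images")
    feats = (feature_fn or flat_pixel_features)(images)
    dists = [np.sqrt(np.mean((feats[i] - feats[j]) ** 2))
             for i, j in itertools.combinations(range(len(feats)), 2)]
    return float(np.mean(dists))


def fid_kid(real_images, fake_images, feature_fn=None,
            kid_degree: int = 3) -> tuple[float, float]:
    """Fréchet and kernel distances between two image sets.

    FID: ||mu_r - mu_f||^2 + tr(S_r + S_f - 2 (S_r S_f)^(1/2)) on Gaussian
    moment fits of the feature embeddings. KID: unbiased MMD^2 with the
    polynomial kernel k(x, y) = (x.y / d + 1)^degree.
    """
    if len(real_images) < 2 or len(fake_images) < 2:
        raise ValueError("need at least two images per set")
    fn = feature_fn or flat_pixel_features
    fr, ff = fn(real_images), fn(fake_images)
    mu_r, mu_f = fr.mean(axis=0), ff.mean(axis=0)
    cov_r = np.cov(fr, rowvar=False)
    cov_f = np.cov(ff, rowvar=False)
    cov_r = np.atleast_2d(cov_r)
    cov_f = np.atleast_2d(cov_f)
    eps = 1e-9 * np.eye(cov_r.shape[0])
    covmean = sqrtm((cov_r + eps) @ (cov_f + eps))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    fid = float(((mu_r - mu_f) ** 2).sum()
                + np.trace(cov_r + cov_f - 2.0 * covmean))
    # unbiased MMD^2, polynomial kernel
    d = fr.shape[1]

    def k(a, b):
        return (a @ b.T / d + 1.0) ** kid_degree

    krr, kff, krf = k(fr, fr), k(ff, ff), k(fr, ff)
    m, n = len(fr), len(ff)
    kid = (
        (krr.sum() - np.trace(krr)) / (m * (m - 1))
        + (kff.sum() - np.trace(kff)) / (n * (n - 1))
        - 2.0 * krf.mean()
    )
    return fid, float(kid)
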
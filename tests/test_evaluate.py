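"""IoU, rule-based detection, coherence scoring and image-set metrics."""

import itertools

import numpy as np
import pytest

from sgdiff.evaluate import (Detection, RuleBasedDetector, coherence_score,
                             detect_objects, fid_kid, iou, pairwise_diversity)
from sgdiff.graphs import GraphNode, SceneGraph
from sgdiff.scenes import GeneratorConfig, sample_scene


def test_iou_identical_and_disjoint():
    assert iou((0, 0, 1, 1), (0, 0, 1, 1)) == 1.0
    assert iou((0, 0, 0.4, 0.4), (0.5, 0.5, 1, 1)) == 0.0


def test_iou_matches_pixel_count_oracle():
    a, b = (0, 0, 10, 10), (5, 5, 15, 15)
    grid = [(x, y) for x in range(20) for y in range(20)]
    in_a = {(x, y) for x, y in grid if 0 <= x < 10 and 0 <= y < 10}
    in_b = {(x, y) for x, y in grid if 5 <= x < 15 and 5 <= y < 15}
    oracle = len(in_a & in_b) / len(in_a | in_b)
    assert iou(a, b) == pytest.approx(oracle)
    assert iou(a, b) == pytest.approx(25 / 175)


def test_iou_symmetric_bounded(rng):
    for _ in range(500):
        p = rng.random(8)
        a = (min(p[0], p[1]), min(p[2], p[3]), max(p[0], p[1]) + 0.01,
             max(p[2], p[3]) + 0.01)
        b = (min(p[4], p[5]), min(p[6], p[7]), max(p[4], p[5]) + 0.01,
             max(p[6], p[7]) + 0.01)
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))
        assert (v == pytest.approx(1.0)) == (a == b)


def test_iou_degenerate_box_scores_zero():
    assert iou((0.2, 0.2, 0.2, 0.5), (0, 0, 1, 1)) == 0.0


def _tight_class_box(mask, cid):
    """Exact bbox of a class's rendered pixels (the generator's own truth)."""
    ys, xs = np.nonzero(mask == cid)
    H, W = mask.shape
    return (xs.min() / W, ys.min() / H, (xs.max() + 1) / W, (ys.max() + 1) / H)


def test_detector_recovers_fresh_scene_objects(class_table):
    """On a freshly rendered scene, every generator object's rendered-pixel
    box is recovered by a same-class detection at IoU >= 0.9."""
    cfg = GeneratorConfig(canvas=64, tool_count_range=(1, 1))
    detector = RuleBasedDetector(class_table)
    for seed in range(10):
        scene = sample_scene(cfg, seed)
        dets = detect_objects(scene.image, detector)
        for obj in scene.objects:
            truth = _tight_class_box(scene.mask, obj.class_id)
            best = max((iou(truth, d.box) for d in dets
                        if d.class_id == obj.class_id), default=0.0)
            assert best >= 0.9, (seed, obj.class_id, best)


def test_detector_blank_image_empty(class_table):
    detector = RuleBasedDetector(class_table)
    assert detector(np.full((32, 32, 3), 0.5)) == []


def test_detector_flip_equivariance(class_table):
    cfg = GeneratorConfig(canvas=64)
    detector = RuleBasedDetector(class_table)
    scene = sample_scene(cfg, 3)
    dets = detector(scene.image)
    flipped = detector(scene.image[:, ::-1])
    by_class = lambda ds: {d.class_id: d.box for d in ds}
    d0, d1 = by_class(dets), by_class(flipped)
    assert set(d0) == set(d1)
    for cid, (x0, y0, x1, y1) in d0.items():
        fx0, fy0, fx1, fy1 = d1[cid]
        assert fy0 == pytest.approx(y0, abs=1e-9)
        assert fx0 == pytest.approx(1 - x1, abs=1e-9)
        assert fx1 == pytest.approx(1 - x0, abs=1e-9)


def _graph_from_boxes(boxes_classes):
    nodes = []
    for i, (box, cid) in enumerate(boxes_classes):
        cx, cy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
        nodes.append(GraphNode(i, cid, (cx, cy),
                               (box[2] - box[0], box[3] - box[1]), 0.01))
    return SceneGraph(tuple(nodes), (), (64, 64))


def test_coherence_perfect_detections():
    g = _graph_from_boxes([((0.1, 0.1, 0.3, 0.3), 1),
                           ((0.5, 0.5, 0.9, 0.9), 4)])
    dets = [Detection(n.box(), n.class_id) for n in g.nodes]
    rep = coherence_score([dets], [g])
    assert rep.f1 == 1.0
    assert rep.mean_iou == pytest.approx(1.0)
    assert rep.iou_at_threshold == 1.0


def test_coherence_no_detections():
    g = _graph_from_boxes([((0.1, 0.1, 0.3, 0.3), 1)])
    rep = coherence_score([[]], [g])
    assert rep.f1 == 0.0 and rep.mean_iou == 0.0


def _exhaustive_best_f1(nodes, dets, thr=0.5):
    """Enumerate all one-to-one same-class matchings; return the best F1."""
    best = 0.0
    det_idx = range(len(dets))
    for k in range(min(len(nodes), len(dets)) + 1):
        for node_sel in itertools.permutations(range(len(nodes)), k):
            for det_sel in itertools.permutations(det_idx, k):
                tp = sum(
                    1 for ni, di in zip(node_sel, det_sel)
                    if nodes[ni].class_id == dets[di].class_id
                    and iou(nodes[ni].box(), dets[di].box) >= thr)
                fp = len(dets) - tp
                fn = len(nodes) - tp
                denom = 2 * tp + fp + fn
                if denom:
                    best = max(best, 2 * tp / denom)
    return best


def test_coherence_greedy_matches_exhaustive_three_node_case():
    g = _graph_from_boxes([((0.1, 0.1, 0.3, 0.3), 1),
                           ((0.4, 0.4, 0.6, 0.6), 4),
                           ((0.7, 0.1, 0.9, 0.3), 5)])
    dets = [
        Detection((0.1, 0.1, 0.3, 0.3), 2),    # class mismatch
        Detection((0.45, 0.45, 0.65, 0.65), 4),  # shifted but > 0.5 IoU
        Detection((0.7, 0.1, 0.9, 0.3), 5),
    ]
    rep = coherence_score([dets], [g])
    assert rep.f1 == pytest.approx(_exhaustive_best_f1(list(g.nodes), dets))


def test_coherence_invariant_to_image_order(rng):
    graphs, det_sets = [], []
    for i in range(5):
        g = _graph_from_boxes([((0.1, 0.1, 0.4, 0.4), 1),
                               ((0.5, 0.5, 0.8, 0.8), 4 + i % 3)])
        dets = [Detection((0.1 + 0.01 * i, 0.1, 0.4, 0.4), 1)]
        graphs.append(g)
        det_sets.append(dets)
    rep = coherence_score(det_sets, graphs)
    perm = rng.permutation(5)
    rep2 = coherence_score([det_sets[i] for i in perm],
                           [graphs[i] for i in perm])
    assert rep.f1 == pytest.approx(rep2.f1)
    assert rep.mean_iou == pytest.approx(rep2.mean_iou)


def test_coherence_degrading_a_match_never_raises_f1():
    g = _graph_from_boxes([((0.1, 0.1, 0.4, 0.4), 1),
                           ((0.5, 0.5, 0.8, 0.8), 4)])
    good = [Detection((0.1, 0.1, 0.4, 0.4), 1),
            Detection((0.5, 0.5, 0.8, 0.8), 4)]
    bad = [Detection((0.1, 0.1, 0.4, 0.4), 1),
           Detection((0.62, 0.62, 0.92, 0.92), 4)]  # pushed below 0.5 IoU
    assert coherence_score([bad], [g]).f1 <= coherence_score([good], [g]).f1


def test_coherence_length_mismatch():
    with pytest.raises(ValueError):
        coherence_score([[]], [])


def test_diversity_zero_for_identical_images(rng):
    img = rng.random((16, 16, 3))
    assert pairwise_diversity([img, img.copy(), img.copy()]) == 0.0


def test_diversity_ordering(rng):
    img = rng.random((16, 16, 3))
    strong = pairwise_diversity([img, 1.0 - img])
    weak = pairwise_diversity([img, np.clip(img + 1e-3, 0, 1)])
    assert strong > weak


def test_diversity_needs_two(rng):
    with pytest.raises(ValueError):
        pairwise_diversity([rng.random((8, 8, 3))])


def test_fid_zero_for_identical_sets(rng):
    imgs = [rng.random((8, 8, 3)) for _ in range(12)]
    fid, _ = fid_kid(imgs, [im.copy() for im in imgs])
    assert abs(fid) < 1e-5


def test_kid_near_zero_for_same_distribution(rng):
    # the unbiased kernel estimate is ~0 for two independent draws from the
    # same distribution (it is negatively biased for literally equal sets)
    a = [rng.random((8, 8, 3)) for _ in range(40)]
    b = [rng.random((8, 8, 3)) for _ in range(40)]
    _, kid = fid_kid(a, b)
    assert abs(kid) < 0.05


def test_fid_positive_for_different_sets(rng):
    a = [rng.random((8, 8, 3)) for _ in range(12)]
    b = [rng.random((8, 8, 3)) + 0.5 for _ in range(12)]
    fid, kid = fid_kid(a, b)
    assert fid > 0.1
    assert kid > 0.0
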
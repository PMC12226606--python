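"""Scene-graph extraction, relations, editing and serialisation."""

import numpy as np
import pytest

from sgdiff.graphs import (RELATIONS, AddNode, ContractError, DeleteNode,
                           GraphEdge, GraphNode, InvalidEditError, MoveNode,
                           RetypeNode, SceneGraph, SchemaError, edit_graph,
                           graph_from_json, graph_to_features, graph_to_json,
                           load_graph, mask_to_graph, relation_between,
                           save_graph)
from sgdiff.scenes import GeneratorConfig, sample_scene


def test_single_square_centroid_size_area(class_table):
    mask = np.zeros((64, 64), dtype=int)
    mask[28:36, 28:36] = 3  # 8x8 square, top-left pixel (28, 28)
    g = mask_to_graph(mask, class_table)
    assert len(g.nodes) == 1
    node = g.nodes[0]
    assert node.class_id == 3
    assert node.centroid == (0.5, 0.5)  # (31.5 + 0.5) / 64 on both axes
    assert node.size == (8 / 64, 8 / 64)
    assert node.area == 64 / 4096
    assert g.edges == ()


def test_all_background_mask_gives_empty_graph(class_table):
    g = mask_to_graph(np.zeros((32, 32), dtype=int), class_table)
    assert g.nodes == () and g.edges == ()


def test_unknown_mask_id_raises(class_table):
    mask = np.zeros((16, 16), dtype=int)
    mask[0, 0] = 99
    with pytest.raises(SchemaError):
        mask_to_graph(mask, class_table)


def test_extracted_relations_use_the_six_term_vocabulary(class_table):
    cfg = GeneratorConfig(canvas=32)
    for seed in range(200):
        g = mask_to_graph(sample_scene(cfg, seed).mask, class_table)
        for e in g.edges:
            assert e.relation in RELATIONS


def test_edge_completeness_all_ordered_pairs(class_table):
    cfg = GeneratorConfig(canvas=32)
    for seed in range(50):
        g = mask_to_graph(sample_scene(cfg, seed).mask, class_table)
        n = len(g.nodes)
        assert len(g.edges) == n * (n - 1)


def test_relation_duality_on_extracted_graphs(class_table):
    cfg = GeneratorConfig(canvas=32)
    dual = {"left_of": "right_of", "right_of": "left_of", "above": "below",
            "below": "above", "inside": "surrounding", "surrounding": "inside"}
    for seed in range(50):
        g = mask_to_graph(sample_scene(cfg, seed).mask, class_table)
        rel = {(e.src, e.dst): e.relation for e in g.edges}
        for (a, b), r in rel.items():
            assert rel[(b, a)] == dual[r], (seed, a, b, r)


def test_relation_containment_and_offsets():
    assert relation_between((0.4, 0.4, 0.6, 0.6), (0.1, 0.1, 0.9, 0.9)) == "inside"
    assert relation_between((0.1, 0.1, 0.9, 0.9), (0.4, 0.4, 0.6, 0.6)) == "surrounding"
    a = (0.1, 0.4, 0.3, 0.6)   # centred (0.2, 0.5)
    b = (0.7, 0.4, 0.9, 0.6)   # centred (0.8, 0.5)
    assert relation_between(a, b) == "left_of"
    assert relation_between(b, a) == "right_of"


def test_relation_degenerate_box_rejected():
    with pytest.raises(ContractError):
        relation_between((0.2, 0.2, 0.2, 0.4), (0.0, 0.0, 1.0, 1.0))


def _oracle_relation(box_a, box_b):
    """Independent predicate coding of the relation rule."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    a_in_b = bx0 < ax0 and by0 < ay0 and ax1 < bx1 and ay1 < by1
    b_in_a = ax0 < bx0 and ay0 < by0 and bx1 < ax1 and by1 < ay1
    if a_in_b:
        return "inside"
    if b_in_a:
        return "surrounding"
    dx = (bx0 + bx1) - (ax0 + ax1)
    dy = (by0 + by1) - (ay0 + ay1)
    if abs(dx) >= abs(dy):
        return "left_of" if dx >= 0 else "right_of"
    return "above" if dy > 0 else "below"


def test_relation_matches_brute_force_predicates(rng):
    """10k random box pairs against an independently coded checker, plus
    antisymmetry of the directional relations."""
    dual = {"left_of": "right_of", "right_of": "left_of", "above": "below",
            "below": "above", "inside": "surrounding", "surrounding": "inside"}
    for _ in range(10_000):
        pts = rng.random(8)
        a = (min(pts[0], pts[1]), min(pts[2], pts[3]),
             max(pts[0], pts[1]) + 0.01, max(pts[2], pts[3]) + 0.01)
        b = (min(pts[4], pts[5]), min(pts[6], pts[7]),
             max(pts[4], pts[5]) + 0.01, max(pts[6], pts[7]) + 0.01)
        r = relation_between(a, b)
        assert r == _oracle_relation(a, b)
        assert relation_between(b, a) == dual[r]


def test_generator_roundtrip_centroids_within_one_pixel(class_table):
    """Tool-free concentric scenes: extracted centroids agree with the
    generator's ground truth to one pixel, and class sets match."""
    cfg = GeneratorConfig(canvas=64, tool_count_range=(0, 0), misc_prob=0.0)
    for seed in range(25):
        scene = sample_scene(cfg, seed)
        g = mask_to_graph(scene.mask, class_table)
        assert g.classes() == {o.class_id for o in scene.objects}
        truth = {o.class_id: o.centroid for o in scene.objects}
        for node in g.nodes:
            tx, ty = truth[node.class_id]
            assert abs(node.centroid[0] - tx) <= 1 / 64
            assert abs(node.centroid[1] - ty) <= 1 / 64


def _random_graph(rng, n_nodes, n_classes=10):
    nodes = []
    classes = rng.choice(np.arange(1, n_classes), size=n_nodes, replace=False)
    for i, cid in enumerate(classes):
        cx, cy = rng.uniform(0.2, 0.8, 2)
        w, h = rng.uniform(0.05, 0.3, 2)
        nodes.append(GraphNode(i, int(cid), (cx, cy), (w, h),
                               float(rng.uniform(0, 0.2))))
    from sgdiff.graphs import _complete_edges

    return SceneGraph(tuple(nodes), _complete_edges(nodes), (64, 64))


def test_feature_matrix_layout(class_table):
    node = GraphNode(0, 2, (0.5, 0.25), (0.1, 0.2), 0.02)
    g = SceneGraph((node,), (), (64, 64))
    feats, ei, et = graph_to_features(g, 5)
    assert feats.shape == (1, 10)
    assert np.allclose(feats[0], [0, 0, 1, 0, 0, 0.5, 0.25, 0.1, 0.2, 0.02])
    assert len(ei) == 0 and len(et) == 0


def test_feature_matrix_empty_graph():
    g = SceneGraph((), (), (64, 64))
    feats, ei, et = graph_to_features(g, 10)
    assert feats.shape == (0, 15) and len(ei) == 0


def test_feature_rows_follow_node_permutation(rng):
    for _ in range(20):
        g = _random_graph(rng, int(rng.integers(2, 6)))
        feats, _, _ = graph_to_features(g, 10)
        perm = rng.permutation(len(g.nodes))
        g2 = SceneGraph(tuple(g.nodes[i] for i in perm), g.edges, g.canvas)
        feats2, _, _ = graph_to_features(g2, 10)
        assert np.allclose(feats2, feats[perm])


def test_edit_delete_only_tool(class_table, rng):
    g = _random_graph(rng, 3)
    victim = g.nodes[0].node_id
    out = edit_graph(g, [DeleteNode(victim)], class_table)
    assert victim not in {n.node_id for n in out.nodes}
    assert all(victim not in (e.src, e.dst) for e in out.edges)
    assert len(out.edges) == 2  # 2 remaining nodes, all ordered pairs


def test_edit_move_flips_relation(class_table):
    a = GraphNode(0, 4, (0.2, 0.5), (0.1, 0.1), 0.01)
    b = GraphNode(1, 5, (0.5, 0.5), (0.1, 0.1), 0.01)
    from sgdiff.graphs import _complete_edges

    g = SceneGraph((a, b), _complete_edges([a, b]), (64, 64))
    assert {e.relation for e in g.edges if e.src == 0} == {"left_of"}
    out = edit_graph(g, [MoveNode(0, (0.8, 0.5))], class_table)
    assert {e.relation for e in out.edges if e.src == 0} == {"right_of"}
    # edges recomputed from moved boxes equal an oracle recomputation
    moved = out.node(0)
    assert relation_between(moved.box(), out.node(1).box()) == "right_of"


def test_edit_empty_list_is_identity(class_table, rng):
    g = _random_graph(rng, 4)
    assert edit_graph(g, [], class_table) == g


def test_edit_retype_to_background_rejected(class_table, rng):
    g = _random_graph(rng, 2)
    with pytest.raises(InvalidEditError):
        edit_graph(g, [RetypeNode(0, class_table.background_id)], class_table)


def test_edit_add_and_retype(class_table, rng):
    g = _random_graph(rng, 2)
    free = list({1, 2, 3, 4, 5, 6, 7, 8, 9} - g.classes())
    out = edit_graph(g, [AddNode(free[0], (0.5, 0.5), (0.2, 0.2))], class_table)
    assert len(out.nodes) == 3
    assert len(out.edges) == 6
    out2 = edit_graph(out, [RetypeNode(out.nodes[-1].node_id, free[1])], class_table)
    assert free[1] in out2.classes()


def test_json_roundtrip_random_graphs(tmp_path, rng):
    for i in range(100):
        g = _random_graph(rng, int(rng.integers(0, 6)))
        path = tmp_path / f"g{i}.json"
        save_graph(g, path)
        assert load_graph(path) == g


def test_json_edge_to_missing_node_rejected():
    doc = {"version": 1, "canvas": [64, 64],
           "nodes": [{"id": 0, "class_id": 1, "centroid": [0.5, 0.5],
                      "size": [0.1, 0.1], "area": 0.01}],
           "edges": [{"src": 0, "dst": 7, "relation": "left_of"}]}
    with pytest.raises(SchemaError):
        graph_from_json(doc)


def test_json_unknown_version_rejected(rng):
    doc = graph_to_json(_random_graph(rng, 2))
    doc["version"] = 99
    with pytest.raises(SchemaError):
        graph_from_json(doc)


def test_graph_invariants_rejected():
    n0 = GraphNode(0, 1, (0.5, 0.5), (0.1, 0.1), 0.01)
    n1 = GraphNode(0, 2, (0.5, 0.5), (0.1, 0.1), 0.01)  # duplicate id
    with pytest.raises(SchemaError):
        SceneGraph((n0, n1), (), (64, 64))
    n2 = GraphNode(1, 1, (0.2, 0.2), (0.1, 0.1), 0.01)  # duplicate class
    with pytest.raises(SchemaError):
        SceneGraph((n0, n2), (), (64, 64))
    with pytest.raises(SchemaError):
        GraphEdge(0, 0, "left_of")
    with pytest.raises(SchemaError):
        GraphEdge(0, 1, "nextto")
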
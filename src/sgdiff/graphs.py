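"""Scene graphs from segmentation masks.

A scene graph has one node per non-background class present in a mask
(classes are instance-like in anterior-segment frames), with node features
encoding class identity, normalised centroid, bounding-box extents and pixel
area, and a complete set of directed edges: every ordered node pair carries
exactly one of six spatial relations — left_of, right_of, above, below,
inside, surrounding.

Conventions (repo-global): pixels are 0-based with origin at the top-left,
x rightward and y downward; bounding boxes are half-open
[x_min, x_max) x [y_min, y_max); centroids are means over pixel centres
(+0.5), everything normalised by canvas width/height. A node's box used for
relation assignment is centred on its centroid with its stored extents, so
editing a centroid translates the box rigidly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .scenes import ClassTable

__all__ = [
    "RELATIONS",
    "GraphNode",
    "GraphEdge",
    "SceneGraph",
    "SchemaError",
    "ContractError",
    "InvalidEditError",
    "relation_between",
    "mask_to_graph",
    "graph_to_features",
    "edit_graph",
    "MoveNode",
    "RetypeNode",
    "DeleteNode",
    "AddNode",
    "save_graph",
    "load_graph",
    "graph_to_json",
    "graph_from_json",
]

RELATIONS = ("left_of", "right_of", "above", "below", "inside", "surrounding")
_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


class ContractError(ValueError):
    pass


class InvalidEditError(ValueError):
    pass


@dataclass(frozen=True)
class GraphNode:
    node_id: int
    class_id: int
    centroid: tuple[float, float]  # (cx, cy) normalised
    size: tuple[float, float]      # (w, h) normalised bbox extents
    area: float                    # pixel fraction of the canvas

    def box(self) -> tuple[float, float, float, float]:
        """Centroid-centred box with the stored extents, clipped to the
        canvas (visible regions never extend past it)."""
        cx, cy = self.centroid
        w, h = self.size
        return (max(0.0, cx - w / 2), max(0.0, cy - h / 2),
                min(1.0, cx + w / 2), min(1.0, cy + h / 2))


@dataclass(frozen=True)
class GraphEdge:
    src: int
    dst: int
    relation: str

    def __post_init__(self):
        if self.src == self.dst:
            raise SchemaError("self-edges are not allowed")
        if self.relation not in RELATIONS:
            raise SchemaError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class SceneGraph:
    nodes: tuple[GraphNode, ...]
    edges: tuple[GraphEdge, ...]
    canvas: tuple[int, int]  # (H, W)

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate node ids")
        cids = [n.class_id for n in self.nodes]
        if len(set(cids)) != len(cids):
            raise SchemaError("at most one node per class")
        known = set(ids)
        for e in self.edges:
            if e.src not in known or e.dst not in known:
                raise SchemaError(f"edge ({e.src},{e.dst}) references a missing node")

    def node(self, node_id: int) -> GraphNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def classes(self) -> set[int]:
        return {n.class_id for n in self.nodes}


def relation_between(box_a, box_b) -> str:
    """One of the six spatial relations between two normalised boxes.

    Strict containment wins (inside / surrounding); otherwise the dominant
    axis of the centre displacement decides, with |dx| >= |dy| resolving to
    the horizontal branch. Coincident centres with no containment fall back
    to left_of (arbitrary but deterministic).
    """
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ContractError("degenerate (zero-area) box")
    if ax0 > bx0 and ay0 > by0 and ax1 < bx1 and ay1 < by1:
        return "inside"
    if bx0 > ax0 and by0 > ay0 and bx1 < ax1 and by1 < ay1:
        return "surrounding"
    dx = (bx0 + bx1) / 2 - (ax0 + ax1) / 2
    dy = (by0 + by1) / 2 - (ay0 + ay1) / 2
    if abs(dx) >= abs(dy):
        return "left_of" if dx >= 0 else "right_of"
    return "above" if dy > 0 else "below"


def _complete_edges(nodes) -> tuple[GraphEdge, ...]:
    edges = []
    for a in nodes:
        for b in nodes:
            if a.node_id == b.node_id:
                continue
            edges.append(GraphEdge(a.node_id, b.node_id,
                                   relation_between(a.box(), b.box())))
    return tuple(edges)


def mask_to_graph(mask: np.ndarray, class_table: ClassTable) -> SceneGraph:
    """Extract the scene graph of a segmentation mask.

    One node per non-background class present; an all-background mask yields
    an empty graph. Mask values outside the class table raise SchemaError.
    """
    mask = np.asarray(mask)
    H, W = mask.shape
    present = np.unique(mask)
    valid = set(range(len(class_table)))
    if not set(present.tolist()) <= valid:
        raise SchemaError(f"mask contains ids outside the class table: "
                          f"{sorted(set(present.tolist()) - valid)}")
    bg = class_table.background_id
    nodes = []
    for cid in present.tolist():
        if cid == bg:
            continue
        ys, xs = np.nonzero(mask == cid)
        cx = float((xs + 0.5).mean() / W)
        cy = float((ys + 0.5).mean() / H)
        w = float((xs.max() + 1 - xs.min()) / W)
        h = float((ys.max() + 1 - ys.min()) / H)
        area = float(len(xs) / (H * W))
        nodes.append(GraphNode(len(nodes), cid, (cx, cy), (w, h), area))
    return SceneGraph(tuple(nodes), _complete_edges(nodes), (H, W))


def graph_to_features(graph: SceneGraph, n_classes: int):
    """Tensorise a graph: (|V| x F node features, edge index, edge types).

    Row layout: one-hot class (n_classes) ++ (cx, cy, w, h, area), so
    F = n_classes + 5. Edge index entries are positions into the node list
    (not node_ids); edge types index into RELATIONS.
    """
    n = len(graph.nodes)
    feats = np.zeros((n, n_classes + 5))
    pos = {nd.node_id: i for i, nd in enumerate(graph.nodes)}
    for i, nd in enumerate(graph.nodes):
        feats[i, nd.class_id] = 1.0
        feats[i, n_classes:] = [nd.centroid[0], nd.centroid[1],
                                nd.size[0], nd.size[1], nd.area]
    edge_index = np.array([[pos[e.src], pos[e.dst]] for e in graph.edges],
                          dtype=np.intp).reshape(-1, 2)
    edge_type = np.array([RELATIONS.index(e.relation) for e in graph.edges],
                         dtype=np.intp)
    return feats, edge_index, edge_type


# ---- graph editing -------------------------------------------------------

@dataclass(frozen=True)
class MoveNode:
    node_id: int
    centroid: tuple[float, float]


@dataclass(frozen=True)
class RetypeNode:
    node_id: int
    class_id: int


@dataclass(frozen=True)
class DeleteNode:
    node_id: int


@dataclass(frozen=True)
class AddNode:
    class_id: int
    centroid: tuple[float, float]
    size: tuple[float, float]
    area: float = 0.0


def _edit_from_dict(d: dict):
    op = d["op"]
    if op == "move":
        return MoveNode(d["node_id"], tuple(d["centroid"]))
    if op == "retype":
        return RetypeNode(d["node_id"], d["class_id"])
    if op == "delete":
        return DeleteNode(d["node_id"])
    if op == "add":
        return AddNode(d["class_id"], tuple(d["centroid"]), tuple(d["size"]),
                       d.get("area", 0.0))
    raise InvalidEditError(f"unknown edit op {op!r}")


def edit_graph(graph: SceneGraph, edits, class_table: ClassTable) -> SceneGraph:
    """Apply node edits (move / retype / delete / add) and rebuild all edges.

    Moving translates a node's box rigidly with its centroid. Edges are
    always recomputed from the surviving nodes, never patched.
    """
    nodes = {n.node_id: n for n in graph.nodes}
    for raw in edits:
        e = _edit_from_dict(raw) if isinstance(raw, dict) else raw
        if isinstance(e, (MoveNode, RetypeNode, DeleteNode)) and e.node_id not in nodes:
            raise InvalidEditError(f"node {e.node_id} does not exist")
        if isinstance(e, MoveNode):
            cx, cy = e.centroid
            if not (0 <= cx <= 1 and 0 <= cy <= 1):
                raise InvalidEditError("new centroid must lie in [0,1]^2")
            nodes[e.node_id] = replace(nodes[e.node_id], centroid=(cx, cy))
        elif isinstance(e, RetypeNode):
            if e.class_id == class_table.background_id:
                raise InvalidEditError("cannot retype a node to background")
            others = {n.class_id for i, n in nodes.items() if i != e.node_id}
            if e.class_id in others:
                raise InvalidEditError(f"class {e.class_id} already present")
            nodes[e.node_id] = replace(nodes[e.node_id], class_id=e.class_id)
        elif isinstance(e, DeleteNode):
            del nodes[e.node_id]
        elif isinstance(e, AddNode):
            if e.class_id == class_table.background_id:
                raise InvalidEditError("cannot add a background node")
            if e.class_id in {n.class_id for n in nodes.values()}:
                raise InvalidEditError(f"class {e.class_id} already present")
            nid = max(nodes, default=-1) + 1
            nodes[nid] = GraphNode(nid, e.class_id, e.centroid, e.size, e.area)
        else:
            raise InvalidEditError(f"unsupported edit {e!r}")
    ordered = tuple(nodes[i] for i in sorted(nodes))
    return SceneGraph(ordered, _complete_edges(ordered), graph.canvas)


# ---- (de)serialisation ---------------------------------------------------

def graph_to_json(graph: SceneGraph) -> dict:
    return {
        "version": _SCHEMA_VERSION,
        "canvas": list(graph.canvas),
        "nodes": [
            {"id": n.node_id, "class_id": n.class_id,
             "centroid": list(n.centroid), "size": list(n.size), "area": n.area}
            for n in graph.nodes
        ],
        "edges": [{"src": e.src, "dst": e.dst, "relation": e.relation}
                  for e in graph.edges],
    }


def graph_from_json(doc: dict) -> SceneGraph:
    if doc.get("version") != _SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {doc.get('version')!r}")
    try:
        nodes = tuple(
            GraphNode(int(n["id"]), int(n["class_id"]),
                      tuple(float(v) for v in n["centroid"]),
                      tuple(float(v) for v in n["size"]), float(n["area"]))
            for n in doc["nodes"]
        )
        edges = tuple(GraphEdge(int(e["src"]), int(e["dst"]), e["relation"])
                      for e in doc["edges"])
        canvas = tuple(int(v) for v in doc["canvas"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed graph document: {exc}") from exc
    return SceneGraph(nodes, edges, canvas)  # validates endpoints


def save_graph(graph: SceneGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_to_json(graph), indent=1))


def load_graph(path: str | Path) -> SceneGraph:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON: {exc}") from exc
    return graph_from_json(doc)
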
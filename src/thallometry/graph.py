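"""Formal graph representation of a skeleton.

The classified skeleton is converted into a graph G = (V, E): vertices
are junctions and terminals, edges are the branch paths between them,
carried pixel by pixel.  A depth-first traversal from a root terminal
orients every edge parent-to-child, which the measurement layer uses to
define branch directions and sibling pairs at a junction.

Coordinates are 0-based (row, column) with origin at the top-left.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .skeleton import SkeletonImage, classify_features, trace_skeleton


class GraphError(ValueError):
    """Raised when a skeleton cannot be turned into a rooted graph."""


@dataclass
class Vertex:
    id: int
    coordinate: tuple[int, int]
    kind: str                       # "junction" | "terminal"
    is_root: bool = False
    members: list = field(default_factory=list)  # all pixels of the region


@dataclass
class Edge:
    id: int
    u: int
    v: int
    path: list                      # interior pixels ordered u -> v
    parent: int | None = None       # vertex id assigned by the DFS
    closes_cycle: bool = False

    def other(self, vid: int) -> int:
        return self.v if vid == self.u else self.u

    def path_from(self, vid: int) -> list:
        """Edge path ordered so it leaves vertex ``vid``."""
        return self.path if vid == self.u else list(reversed(self.path))


@dataclass
class SkeletonGraph:
    vertices: list
    edges: list
    root: int

    @property
    def terminals(self) -> list:
        return [v for v in self.vertices if v.kind == "terminal"]

    @property
    def junctions(self) -> list:
        return [v for v in self.vertices if v.kind == "junction"]

    def incident(self, vid: int) -> list:
        return [e for e in self.edges if vid in (e.u, e.v)]

    def children_of(self, vid: int) -> list:
        """Edges oriented away from ``vid`` by the DFS."""
        return [e for e in self.edges if e.parent == vid]


def _initial_angle(vertex: Vertex, edge: Edge, vertices: list) -> float:
    path = edge.path_from(vertex.id)
    if path:
        target = path[0]
    else:
        target = vertices[edge.other(vertex.id)].coordinate
    dy = target[0] - vertex.coordinate[0]
    dx = target[1] - vertex.coordinate[1]
    return math.atan2(dy, dx) % (2 * math.pi)


def build_graph(skel: SkeletonImage,
                root: tuple[int, int] | None = None) -> SkeletonGraph:
    """Build the skeleton graph of the component containing the root.

    ``root`` must be a terminal coordinate; when absent, the terminal
    with the smallest (row, column) is used.  A skeleton without any
    terminal (a pure ring) cannot be rooted: break the loop first
    (see :func:`thallometry.skeleton.break_loop`).
    """
    if not skel.classified:
        skel = classify_features(skel)
    traced = trace_skeleton(skel)
    terminals = [i for i, k in enumerate(traced.region_kind) if k == "terminal"]
    if not terminals:
        raise GraphError(
            "skeleton has no terminal to serve as root (closed ring?); "
            "inspect detect_loops() and insert a break_loop() cut first")
    if root is None:
        root_rid = min(terminals, key=lambda i: traced.region_rep[i])
    else:
        root = tuple(root)
        match = [i for i in terminals if traced.region_rep[i] == root]
        if not match:
            raise GraphError(f"root {root} is not a terminal of this skeleton")
        root_rid = match[0]

    labels = traced.component_labels()
    comp = labels[root_rid]
    keep = [i for i in range(len(traced.region_rep)) if labels[i] == comp]
    vid_of = {rid: i for i, rid in enumerate(keep)}
    vertices = [Vertex(vid_of[rid], traced.region_rep[rid],
                       traced.region_kind[rid], is_root=(rid == root_rid),
                       members=list(traced.region_members[rid]))
                for rid in keep]
    edges = [Edge(i, vid_of[e.u], vid_of[e.v], list(e.path))
             for i, e in enumerate(e for e in traced.edges
                                   if labels[e.u] == comp)]
    return SkeletonGraph(vertices, edges, root=vid_of[root_rid])


def build_graphs(skel: SkeletonImage) -> list[SkeletonGraph]:
    """One rooted graph per connected component with at least one terminal.

    Components without terminals (pure rings) are skipped with a warning;
    they are reported by loop detection instead.
    """
    if not skel.classified:
        skel = classify_features(skel)
    traced = trace_skeleton(skel)
    labels = traced.component_labels()
    graphs = []
    seen = set()
    for comp in sorted(set(labels)):
        terms = [i for i, k in enumerate(traced.region_kind)
                 if k == "terminal" and labels[i] == comp]
        if not terms:
            warnings.warn("skipping a skeleton component without terminals "
                          "(closed ring); see the loop report")
            continue
        root = traced.region_rep[min(terms, key=lambda i: traced.region_rep[i])]
        if root in seen:
            continue
        seen.add(root)
        graphs.append(build_graph(skel, root=root))
    if traced.ring_components:
        warnings.warn(f"{len(traced.ring_components)} isolated ring(s) "
                      "excluded from graphs; see the loop report")
    return graphs


def traverse_dfs(g: SkeletonGraph) -> list[tuple[str, int]]:
    """Depth-first traversal from the root; orients every edge.

    Returns the visit sequence as ("vertex", id) / ("edge", id) records.
    At each vertex the outgoing edges are explored ordered by the angle
    of the edge path's initial direction (then edge id), so the
    traversal is deterministic.  An edge leading to an already-visited
    vertex closes a cycle: it is visited once, flagged, and a warning
    points at the loop report.
    """
    order: list[tuple[str, int]] = []
    visited_v: set[int] = {g.root}
    visited_e: set[int] = set()
    cycle_seen = False

    def sorted_out(vid: int):
        vertex = g.vertices[vid]
        out = sorted(g.incident(vid),
                     key=lambda e: (_initial_angle(vertex, e, g.vertices), e.id))
        return iter(out)

    order.append(("vertex", g.root))
    stack: list[tuple[int, object]] = [(g.root, sorted_out(g.root))]
    while stack:
        vid, it = stack[-1]
        advanced = False
        for e in it:
            if e.id in visited_e:
                continue
            visited_e.add(e.id)
            e.parent = vid
            order.append(("edge", e.id))
            other = e.other(vid)
            if other in visited_v:
                e.closes_cycle = True
                cycle_seen = True
                continue
            visited_v.add(other)
            order.append(("vertex", other))
            stack.append((other, sorted_out(other)))
            advanced = True
            break
        if not advanced:
            stack.pop()
    if cycle_seen:
        warnings.warn("skeleton graph contains cycles; cycle-closing edges "
                      "were visited once and flagged (see the loop report)")
    return order


def graph_to_json(g: SkeletonGraph) -> dict:
    """JSON-serializable graph: 0-based (row, column), origin top-left."""
    return {
        "coordinate_system": "0-based (row, column), origin at top-left",
        "root": g.root,
        "vertices": [
            {"id": v.id, "row": v.coordinate[0], "col": v.coordinate[1],
             "kind": v.kind, "is_root": v.is_root}
            for v in g.vertices
        ],
        "edges": [
            {"id": e.id, "endpoints": [e.u, e.v],
             "path": [[r, c] for r, c in e.path],
             "closes_cycle": e.closes_cycle}
            for e in g.edges
        ],
    }


def save_graph_json(g: SkeletonGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_to_json(g), indent=1))
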
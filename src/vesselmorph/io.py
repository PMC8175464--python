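"""Data model and readers/writers for traced centerline skeletons.

A skeleton is an undirected graph of spherical nodes — 3D center (µm) plus
outer radius (µm) — connected by straight edges, the standard representation
produced by manual tracing of tubular structures (blood vessels, neurites)
in 3D image volumes.  Two serializations are supported:

* SWC — the de-facto standard 7-column text format for radius-annotated
  centerline trees.  SWC encodes a forest (each node has one parent), so it
  cannot represent anastomosing vessel networks with loops.
* A JSON graph dialect (``format_version: 1``) with explicit ``nodes`` and
  ``edges`` lists, which represents arbitrary undirected graphs, loops
  included, and round-trips losslessly.

All coordinates and radii are physical micrometres; any voxel-to-µm scaling
happens before construction (the CLI exposes a scale factor).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import numpy as np

from .errors import SkeletonFormatError, UnsupportedStructureError

JSON_FORMAT_VERSION = 1

__all__ = [
    "SkeletonNode",
    "SkeletonGraph",
    "UnbranchedPath",
    "read_swc",
    "write_swc",
    "read_json_graph",
    "write_json_graph",
    "decompose_paths",
]


@dataclass(frozen=True)
class SkeletonNode:
    """A traced centerline point: identifier, 3D position (µm), outer radius (µm)."""

    node_id: int
    position: np.ndarray
    radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"node {self.node_id}: position must be a finite 3-vector")
        if not (self.radius >= 0.0):
            raise ValueError(f"node {self.node_id}: radius must be non-negative")
        object.__setattr__(self, "position", pos)


class SkeletonGraph:
    """Undirected skeleton graph of :class:`SkeletonNode` with sample metadata.

    May contain cycles and multiple connected components; self-edges and
    duplicate edges are rejected.  Backed by :class:`networkx.Graph`.

    Parameters
    ----------
    metadata:
        Free-form sample annotations; conventional keys are ``sample_id``,
        ``kind`` (``"vessel"`` or ``"neurite"``), ``area`` and ``group``.
    """

    def __init__(self, metadata: dict | None = None):
        self._g = nx.Graph()
        self.metadata: dict = dict(metadata or {})

    # -- construction -------------------------------------------------

    def add_node(self, node: SkeletonNode, swc_type: int = 2) -> None:
        if node.node_id in self._g:
            raise ValueError(f"duplicate node id {node.node_id}")
        self._g.add_node(node.node_id, position=node.position,
                         radius=float(node.radius), swc_type=int(swc_type))

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-edge on node {u}")
        if u not in self._g or v not in self._g:
            missing = u if u not in self._g else v
            raise ValueError(f"edge ({u}, {v}) references unknown node {missing}")
        if self._g.has_edge(u, v):
            raise ValueError(f"duplicate edge ({u}, {v})")
        self._g.add_edge(u, v)

    # -- accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_ids(self) -> list[int]:
        return sorted(self._g.nodes)

    def node(self, node_id: int) -> SkeletonNode:
        d = self._g.nodes[node_id]
        return SkeletonNode(node_id, d["position"], d["radius"])

    def position(self, node_id: int) -> np.ndarray:
        return self._g.nodes[node_id]["position"]

    def radius(self, node_id: int) -> float:
        return self._g.nodes[node_id]["radius"]

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self._g.edges]

    def degree(self, node_id: int) -> int:
        return self._g.degree[node_id]

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self._g.neighbors(node_id))

    def has_edge(self, u: int, v: int) -> bool:
        return self._g.has_edge(u, v)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._g

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._g.nodes))

    @property
    def nx_graph(self) -> nx.Graph:
        """The underlying networkx graph (read-only by convention)."""
        return self._g

    def is_forest(self) -> bool:
        return nx.is_forest(self._g) if self.n_nodes else True

    def edge_length(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.position(u) - self.position(v)))

    def total_length(self) -> float:
        """Total traced length: the sum of Euclidean edge lengths (µm)."""
        return float(sum(self.edge_length(u, v) for u, v in self._g.edges))

    # -- cleanup ------------------------------------------------------

    def merge_zero_length_edges(self, tol: float = 1e-9) -> int:
        """Contract edges whose endpoints coincide (within ``tol`` µm).

        Coincident consecutive centers produce zero-length chords that break
        curvature estimation, so they are merged at load time.  Returns the
        number of contracted edges and warns if any were found.
        """
        n_merged = 0
        while True:
            degenerate = [(u, v) for u, v in self._g.edges
                          if np.linalg.norm(self.position(u) - self.position(v)) <= tol]
            if not degenerate:
                break
            for u, v in degenerate:
                if not self._g.has_edge(u, v):
                    continue  # may have been contracted via an earlier pair
                keep, drop = (u, v) if u < v else (v, u)
                for w in list(self._g.neighbors(drop)):
                    if w != keep and not self._g.has_edge(keep, w):
                        self._g.add_edge(keep, w)
                self._g.remove_node(drop)
                n_merged += 1
        if n_merged:
            warnings.warn(f"merged {n_merged} zero-length edge(s)", stacklevel=2)
        return n_merged


@dataclass(frozen=True)
class UnbranchedPath:
    """A maximal chain of degree-2 nodes (a "vessel segment").

    ``node_ids`` lists the nodes in traversal order.  For a closed loop the
    first node is *not* repeated at the end; ``closed`` marks the wrap-around
    edge.  Interior nodes have graph degree exactly 2; endpoints are branch
    points (degree ≥ 3), tips (degree 1), or — for loops — the lowest-id node
    of the cycle.
    """

    node_ids: tuple[int, ...]
    closed: bool = False

    def __len__(self) -> int:
        return len(self.node_ids)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges of this path as sorted id pairs (loop closure included)."""
        ids = self.node_ids
        edges = [tuple(sorted((ids[i], ids[i + 1]))) for i in range(len(ids) - 1)]
        if self.closed:
            edges.append(tuple(sorted((ids[-1], ids[0]))))
        return edges

    def points(self, graph: SkeletonGraph) -> np.ndarray:
        """(n, 3) node centers in path order; closed paths repeat the first point."""
        ids = list(self.node_ids) + ([self.node_ids[0]] if self.closed else [])
        return np.array([graph.position(i) for i in ids], dtype=float)

    def radii(self, graph: SkeletonGraph) -> np.ndarray:
        ids = list(self.node_ids) + ([self.node_ids[0]] if self.closed else [])
        return np.array([graph.radius(i) for i in ids], dtype=float)

    def arc_length(self, graph: SkeletonGraph) -> float:
        pts = self.points(graph)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(source: IO[str] | Iterable[str]) -> SkeletonGraph:
    """Parse an SWC stream into a :class:`SkeletonGraph`.

    Records are ``id type x y z radius parent`` (whitespace-separated,
    ``#`` comments ignored).  ``parent`` must be ``-1`` or a previously
    defined id; radii must be non-negative; ids must be unique.
    """
    graph = SkeletonGraph()
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SkeletonFormatError(
                f"expected 7 fields, got {len(fields)}", line=lineno)
        try:
            node_id = int(fields[0])
            swc_type = int(fields[1])
            x, y, z, radius = (float(f) for f in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SkeletonFormatError(f"unparseable record: {exc}", line=lineno) from None
        if radius < 0:
            raise SkeletonFormatError(f"negative radius {radius}", line=lineno)
        if node_id in graph:
            raise SkeletonFormatError(f"duplicate node id {node_id}", line=lineno)
        graph.add_node(SkeletonNode(node_id, np.array([x, y, z]), radius),
                       swc_type=swc_type)
        if parent != -1:
            if parent not in graph:
                raise SkeletonFormatError(
                    f"parent {parent} of node {node_id} not previously defined",
                    line=lineno)
            graph.add_edge(node_id, parent)
    return graph


def write_swc(graph: SkeletonGraph, sink: IO[str]) -> None:
    """Write a forest-shaped skeleton as SWC.

    Each tree is rooted at its lowest node id; children reference their
    parent, roots reference ``-1``.  Cyclic graphs cannot be encoded in SWC
    and raise :class:`UnsupportedStructureError` (use the JSON writer).
    """
    if not graph.is_forest():
        raise UnsupportedStructureError(
            "graph contains cycles; SWC encodes forests only — use write_json_graph")
    parent: dict[int, int] = {}
    order: list[int] = []
    seen: set[int] = set()
    for root in graph.node_ids():
        if root in seen:
            continue
        stack = [root]
        parent[root] = -1
        seen.add(root)
        while stack:
            u = stack.pop()
            order.append(u)
            for v in sorted(graph.neighbors(u), reverse=True):
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    stack.append(v)
    sink.write("# SWC export (id type x y z radius parent); lengths in um\n")
    for u in order:
        node = graph.node(u)
        t = graph.nx_graph.nodes[u].get("swc_type", 2)
        x, y, z = node.position
        sink.write(f"{u} {t} {x:.6g} {y:.6g} {z:.6g} {node.radius:.6g} {parent[u]}\n")


# ---------------------------------------------------------------------------
# JSON graph dialect
# ---------------------------------------------------------------------------

def read_json_graph(source: IO[str] | str) -> SkeletonGraph:
    """Parse the JSON graph dialect (``nodes``/``edges``/optional ``metadata``)."""
    text = source if isinstance(source, str) else source.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SkeletonFormatError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "nodes" not in doc or "edges" not in doc:
        raise SkeletonFormatError("document must contain 'nodes' and 'edges'")
    graph = SkeletonGraph(metadata=doc.get("metadata") or {})
    for rec in doc["nodes"]:
        try:
            node = SkeletonNode(int(rec["id"]),
                                np.array([rec["x"], rec["y"], rec["z"]], dtype=float),
                                float(rec["r"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SkeletonFormatError(f"bad node record {rec!r}: {exc}") from None
        try:
            graph.add_node(node)
        except ValueError as exc:
            raise SkeletonFormatError(str(exc)) from None
    for pair in doc["edges"]:
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise SkeletonFormatError(f"bad edge record {pair!r}")
        u, v = int(pair[0]), int(pair[1])
        if u == v:
            raise SkeletonFormatError(f"self-edge on node {u}")
        try:
            graph.add_edge(u, v)
        except ValueError as exc:
            raise SkeletonFormatError(str(exc)) from None
    return graph


def write_json_graph(graph: SkeletonGraph, sink: IO[str]) -> None:
    """Serialize any skeleton graph (loops allowed) to the JSON dialect."""
    doc = {
        "format_version": JSON_FORMAT_VERSION,
        "metadata": graph.metadata,
        "nodes": [
            {"id": i, "x": p[0], "y": p[1], "z": p[2], "r": graph.radius(i)}
            for i in graph.node_ids()
            for p in [graph.position(i).tolist()]
        ],
        "edges": [list(e) for e in sorted(graph.edges())],
    }
    json.dump(doc, sink, indent=1)
    sink.write("\n")


# ---------------------------------------------------------------------------
# Path decomposition
# ---------------------------------------------------------------------------

def decompose_paths(graph: SkeletonGraph) -> list[UnbranchedPath]:
    """Partition the edge set into maximal unbranched paths.

    Junction nodes (degree ≠ 2) start paths; the walk continues through
    degree-2 nodes until the next junction.  Components that are pure cycles
    (all degree 2) are returned as closed paths starting at their lowest node
    id, oriented toward the lower-id neighbor.  Every edge belongs to exactly
    one path; branch nodes appear as endpoints of several paths.
    """
    used: set[tuple[int, int]] = set()

    def edge_key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    paths: list[UnbranchedPath] = []
    junctions = [n for n in graph.node_ids() if graph.degree(n) != 2]

    def walk(start: int, first: int) -> list[int]:
        chain = [start, first]
        prev, cur = start, first
        while graph.degree(cur) == 2 and cur != start:
            nbrs = graph.neighbors(cur)
            nxt = nbrs[0] if nbrs[1] == prev else nbrs[1]
            used.add(edge_key(cur, nxt))
            chain.append(nxt)
            prev, cur = cur, nxt
        return chain

    for j in junctions:
        for nbr in graph.neighbors(j):
            k = edge_key(j, nbr)
            if k in used:
                continue
            used.add(k)
            paths.append(UnbranchedPath(tuple(walk(j, nbr))))

    # remaining unused edges lie on isolated cycles (every node degree 2)
    for start in graph.node_ids():
        if graph.degree(start) != 2:
            continue
        nbrs = [n for n in graph.neighbors(start) if edge_key(start, n) not in used]
        if not nbrs:
            continue
        first = min(nbrs)  # deterministic orientation: toward lower id
        used.add(edge_key(start, first))
        chain = walk(start, first)
        assert chain[-1] == start, "cycle walk must return to start"
        paths.append(UnbranchedPath(tuple(chain[:-1]), closed=True))

    return paths
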
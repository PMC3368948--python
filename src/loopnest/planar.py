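"""Embedded weighted planar graphs: the substrate of hierarchical loop decomposition.

A :class:`PlanarGraph` is a straight-line embedded graph whose *links* carry
positive scalar weights (vessel or vein widths).  Three operations turn a raw
graph into the objects the decomposition works on:

* :func:`prune_tree_components` — strip tree-like appendages until every
  vertex has degree >= 2;
* :func:`collapse_chains` — group links into maximal *edge chains* whose
  interior vertices have degree exactly 2, each carrying an aggregate
  strength (by default the weight of the weakest member link);
* :func:`extract_faces` / :func:`trace_faces` — recover the elementary loops
  (faces) of the embedding by half-edge traversal in counter-clockwise
  angular order, with the outer face identified as the one of largest
  absolute signed area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

VertexId = Hashable


class PlanarGraphError(ValueError):
    """An input graph violates the planar-substrate contract."""


#: Aggregation rules mapping the member link weights of a chain to its strength.
STRENGTH_RULES: dict[str, Callable[[Sequence[float]], float]] = {
    "min": min,
    "max": max,
    "median": lambda ws: float(np.median(np.asarray(ws, dtype=float))),
}


class PlanarGraph:
    """Weighted graph with a straight-line planar embedding.

    Thin wrapper around :class:`networkx.Graph`; vertices carry ``x``/``y``
    coordinates, links carry a strictly positive ``weight``.  ``meta`` holds
    generator provenance (lattice coordinates, phantom vertices, ...).
    """

    def __init__(self, graph: nx.Graph | None = None, meta: dict | None = None):
        self.g = graph if graph is not None else nx.Graph()
        self.meta: dict[str, Any] = dict(meta or {})

    # ------------------------------------------------------------------ build
    @classmethod
    def build(
        cls,
        vertices: Mapping[VertexId, tuple[float, float]],
        links: Iterable[tuple[VertexId, VertexId, float]],
    ) -> "PlanarGraph":
        pg = cls()
        for v, (x, y) in vertices.items():
            pg.g.add_node(v, x=float(x), y=float(y))
        seen: set[frozenset] = set()
        for u, v, w in links:
            if u == v:
                raise PlanarGraphError(f"self-loop at vertex {u!r}")
            if u not in pg.g or v not in pg.g:
                raise PlanarGraphError(f"link ({u!r}, {v!r}) references unknown vertex")
            key = frozenset((u, v))
            if key in seen:
                raise PlanarGraphError(f"duplicate link ({u!r}, {v!r})")
            seen.add(key)
            w = float(w)
            if not w > 0:
                raise PlanarGraphError(f"non-positive weight {w} on link ({u!r}, {v!r})")
            pg.g.add_edge(u, v, weight=w)
        return pg

    # ------------------------------------------------------------- accessors
    def position(self, v: VertexId) -> tuple[float, float]:
        d = self.g.nodes[v]
        return (d["x"], d["y"])

    @property
    def positions(self) -> dict[VertexId, tuple[float, float]]:
        return {v: (d["x"], d["y"]) for v, d in self.g.nodes(data=True)}

    def weight(self, u: VertexId, v: VertexId) -> float:
        return self.g.edges[u, v]["weight"]

    def set_weight(self, u: VertexId, v: VertexId, w: float) -> None:
        self.g.edges[u, v]["weight"] = float(w)

    def links(self) -> Iterator[tuple[VertexId, VertexId, float]]:
        for u, v, d in self.g.edges(data=True):
            yield u, v, d["weight"]

    def degree(self, v: VertexId) -> int:
        return self.g.degree(v)

    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.g.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_vertices > 0 and nx.is_connected(self.g)

    def copy(self) -> "PlanarGraph":
        return PlanarGraph(self.g.copy(), dict(self.meta))

    # ------------------------------------------------------------ validation
    def perturb_ties(self, seed: int = 0, rel: float = 1e-9) -> "PlanarGraph":
        """Break weight ties in place with seed-controlled jitter.

        Only tied weights are touched; jitter magnitude is at most
        ``rel`` x (smallest weight), so the strict ordering required by the
        decomposition is obtained without materially moving any weight.
        Returns ``self``.
        """
        weights: dict[tuple, float] = {(u, v): w for u, v, w in self.links()}
        if not weights:
            return self
        finite = [w for w in weights.values() if math.isfinite(w)]
        if not finite:
            return self
        eps = rel * min(finite)
        rng = np.random.default_rng(seed)
        # iterate (deterministically) until all finite weights are distinct
        for _ in range(64):
            groups: dict[float, list[tuple]] = {}
            for e, w in weights.items():
                if math.isfinite(w):
                    groups.setdefault(w, []).append(e)
            tied = [es for es in groups.values() if len(es) > 1]
            if not tied:
                break
            for es in tied:
                for e in sorted(es, key=repr):
                    weights[e] = weights[e] + float(rng.uniform(-1.0, 1.0)) * eps
        else:  # pragma: no cover - probability-zero under float jitter
            raise PlanarGraphError("could not break weight ties")
        for (u, v), w in weights.items():
            self.g.edges[u, v]["weight"] = w
        return self

    def validate_embedding(self, tol: float = 1e-12) -> None:
        """Check that no two links intersect except at shared endpoints."""
        from shapely.geometry import LineString, Point
        from shapely.strtree import STRtree

        edges = list(self.g.edges())
        pos = self.positions
        segs = [LineString([pos[u], pos[v]]) for u, v in edges]
        tree = STRtree(segs)
        for i, si in enumerate(segs):
            for j in tree.query(si):
                j = int(j)
                if j <= i:
                    continue
                inter = si.intersection(segs[j])
                if inter.is_empty:
                    continue
                shared = set(edges[i]) & set(edges[j])
                ok = (
                    inter.geom_type == "Point"
                    and any(Point(pos[s]).distance(inter) <= tol for s in shared)
                )
                if not ok:
                    raise PlanarGraphError(
                        f"links {edges[i]!r} and {edges[j]!r} cross: not a planar embedding"
                    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_tree_components(pg: PlanarGraph) -> PlanarGraph:
    """Iteratively strip degree<=1 vertices until every vertex lies on the loopy backbone.

    Raises :class:`PlanarGraphError` if no cycle remains ("no loopy backbone").
    """
    out = pg.copy()
    g = out.g
    stack = [v for v in g if g.degree(v) <= 1]
    while stack:
        v = stack.pop()
        if v not in g or g.degree(v) > 1:
            continue
        nbrs = list(g.neighbors(v))
        g.remove_node(v)
        for u in nbrs:
            if u in g and g.degree(u) <= 1:
                stack.append(u)
    if g.number_of_edges() == 0:
        raise PlanarGraphError("no loopy backbone: graph has no cycles")
    return out


# ---------------------------------------------------------------------------
# edge chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeChain:
    """Maximal chain of links whose interior vertices have degree exactly 2.

    ``endpoints`` are the two junction vertices (equal for a closed chain, e.g.
    an attached loop of degree-2 vertices, or an entire cycle component with no
    junction at all — the latter is flagged ``degenerate``).
    """

    links: tuple[tuple[VertexId, VertexId], ...]
    weights: tuple[float, ...]
    endpoints: tuple[VertexId, VertexId]
    degenerate: bool = False

    @property
    def closed(self) -> bool:
        return self.endpoints[0] == self.endpoints[1]

    @property
    def n_links(self) -> int:
        return len(self.links)

    def strength(self, rule: str = "min") -> float:
        try:
            agg = STRENGTH_RULES[rule]
        except KeyError:
            raise ValueError(f"unknown strength rule {rule!r}") from None
        return agg(self.weights)


def collapse_chains(pg: PlanarGraph) -> list[EdgeChain]:
    """Partition the links of a pruned graph into maximal edge chains."""
    g = pg.g
    junctions = {v for v in g if g.degree(v) != 2}
    visited: set[frozenset] = set()
    chains: list[EdgeChain] = []

    def walk(start: VertexId, first: VertexId) -> EdgeChain:
        links = [(start, first)]
        visited.add(frozenset((start, first)))
        prev, cur = start, first
        while cur not in junctions and cur != start:
            a, b = g.neighbors(cur)
            nxt = b if a == prev else a
            links.append((cur, nxt))
            visited.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
        ws = tuple(g.edges[u, v]["weight"] for u, v in links)
        return EdgeChain(tuple(links), ws, (start, cur))

    for j in sorted(junctions, key=repr):
        for nb in g.neighbors(j):
            if frozenset((j, nb)) in visited:
                continue
            chains.append(walk(j, nb))
    # pure-cycle components: no junction anywhere on them
    for u, v in g.edges():
        if frozenset((u, v)) not in visited:
            ch = walk(u, v)
            chains.append(EdgeChain(ch.links, ch.weights, ch.endpoints, degenerate=True))
    assert sum(c.n_links for c in chains) == g.number_of_edges()
    return chains


# ---------------------------------------------------------------------------
# faces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Face:
    """An elementary loop of the embedding: a vertex cycle with its polygon area."""

    id: int
    cycle: tuple[VertexId, ...]
    area: float          # absolute polygon area (shoelace)
    signed_area: float   # positive for counter-clockwise (internal) faces
    outer: bool = False
    terminal: bool = True


def _shoelace(coords: Sequence[tuple[float, float]]) -> float:
    x = np.array([c[0] for c in coords])
    y = np.array([c[1] for c in coords])
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def trace_faces(
    pg: PlanarGraph,
) -> tuple[list[Face], dict[tuple[VertexId, VertexId], int], int]:
    """Trace all faces of the embedding, including the outer face.

    Returns ``(faces, face_of, outer_id)`` where ``face_of[(u, v)]`` is the id
    of the face lying to the left of the directed link ``u -> v``; every
    undirected link therefore borders ``face_of[(u, v)]`` and
    ``face_of[(v, u)]`` (equal exactly when the link is a bridge).
    """
    g = pg.g
    if g.number_of_edges() == 0:
        raise PlanarGraphError("cannot trace faces of an empty graph")
    if not nx.is_connected(g):
        raise PlanarGraphError("face tracing requires a connected graph")
    pos = pg.positions

    # rotation system: neighbors in counter-clockwise angular order
    prev_ccw: dict[VertexId, dict[VertexId, VertexId]] = {}
    for v in g:
        x0, y0 = pos[v]
        nbrs = sorted(
            g.neighbors(v),
            key=lambda u: math.atan2(pos[u][1] - y0, pos[u][0] - x0),
        )
        prev_ccw[v] = {nbrs[i]: nbrs[i - 1] for i in range(len(nbrs))}

    face_of: dict[tuple[VertexId, VertexId], int] = {}
    faces: list[Face] = []
    for u0, v0 in list(g.edges()) + [(v, u) for u, v in g.edges()]:
        if (u0, v0) in face_of:
            continue
        fid = len(faces)
        cycle = []
        u, v = u0, v0
        while True:
            face_of[(u, v)] = fid
            cycle.append(u)
            u, v = v, prev_ccw[v][u]
            if (u, v) == (u0, v0):
                break
        signed = _shoelace([pos[w] for w in cycle])
        faces.append(Face(fid, tuple(cycle), abs(signed), signed))

    outer_id = max(range(len(faces)), key=lambda i: faces[i].area)
    faces[outer_id] = Face(
        outer_id,
        faces[outer_id].cycle,
        faces[outer_id].area,
        faces[outer_id].signed_area,
        outer=True,
    )
    return faces, face_of, outer_id


def extract_faces(pg: PlanarGraph, validate: bool = False) -> list[Face]:
    """Internal faces of a pruned, connected, non-crossing embedding.

    Satisfies Euler consistency ``F = L - V + 1`` and the area partition
    property: the internal face areas sum to the outer polygon area.
    """
    if validate:
        pg.validate_embedding()
    faces, _, outer_id = trace_faces(pg)
    internal = [f for f in faces if f.id != outer_id]
    expected = pg.n_links - pg.n_vertices + 1
    if len(internal) != expected:
        raise PlanarGraphError(
            f"face count {len(internal)} != L - V + 1 = {expected}; "
            "embedding is not planar or graph is not pruned/connected"
        )
    return internal
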
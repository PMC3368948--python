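"""Hierarchical loop decomposition: weakest-edge removal with loop merging.

The decomposition maps a pruned, weighted planar graph to a binary nesting
tree: repeatedly pop the globally weakest edge chain; when it separates two
distinct loops, merge them into a new tree node whose height is the removed
strength; when it borders the same loop on both sides (a bridge, or a chain
made redundant by earlier merges) simply delete it.  Whenever a deletion
leaves a junction of degree 2, the two incident chains fuse and the fused
strength is re-aggregated under the configured rule, so the next removal is
always the global minimum among the *current* chains.

Two exterior conventions are supported.  ``single_exterior`` treats the
unbounded outer region as one zero-area loop that boundary loops merge into.
``phantom_boundary`` first rings the graph with an enclosing polygon tied to
the perimeter by sentinel (infinite-weight) connectors, fragmenting the
outside into one phantom loop per perimeter junction so that boundary
neighborhood information is preserved in the tree.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import networkx as nx

from .planar import (
    STRENGTH_RULES,
    EdgeChain,
    PlanarGraph,
    PlanarGraphError,
    collapse_chains,
    prune_tree_components,
    trace_faces,
)
from .tree import NestingNode, NestingTree

logger = logging.getLogger(__name__)

MODES = ("single_exterior", "phantom_boundary")


# ---------------------------------------------------------------------------
# bridge handling
# ---------------------------------------------------------------------------

def reassign_bridge_weights(pg: PlanarGraph, rel_eps: float = 1e-9) -> PlanarGraph:
    """Lift every bridge weight above the loopy component it would disconnect.

    A bridge link (one whose removal disconnects the graph — equivalently one
    bordering the same face twice) gets weight ``m * (1 + rel_eps)`` where
    ``m`` is the smaller of the two sides' maximum link weights.  The weaker
    side therefore merges completely before its bridge is touched, and bridge
    removal never interrupts the decomposition.  Weights are read from the
    input graph throughout, so the result does not depend on bridge order.
    """
    out = pg.copy()
    bridges = list(nx.bridges(out.g))
    if not bridges:
        return out
    for u, v in bridges:
        g2 = nx.restricted_view(pg.g, [], [(u, v)])
        comp_u = nx.node_connected_component(g2, u)
        comp_v = nx.node_connected_component(g2, v)
        maxes = []
        for comp in (comp_u, comp_v):
            ws = [d["weight"] for a, b, d in pg.g.edges(comp, data=True)
                  if a in comp and b in comp]
            if ws:
                maxes.append(max(ws))
        if not maxes:
            continue
        m = min(maxes)
        out.set_weight(u, v, m * (1.0 + rel_eps))
    logger.info("reassigned %d bridge weight(s)", len(bridges))
    return out


# ---------------------------------------------------------------------------
# phantom boundary
# ---------------------------------------------------------------------------

def add_phantom_boundary(pg: PlanarGraph, scale: float = 1.2) -> PlanarGraph:
    """Surround the graph with an enclosing polygon of sentinel-weight links.

    The outer boundary is scaled by ``scale`` about its centroid; one
    connector of infinite weight runs from each perimeter junction vertex
    (degree >= 3; all perimeter vertices if fewer than three junctions exist)
    to its scaled image.  This creates one phantom face per connector.
    Calling it twice is an error — the graph already carries sentinel weights.
    """
    from shapely.geometry import Polygon

    if any(math.isinf(w) for _, _, w in pg.links()):
        raise PlanarGraphError("graph already carries a phantom boundary")
    faces, _, outer_id = trace_faces(pg)
    cyc = faces[outer_id].cycle
    if len(set(cyc)) != len(cyc):
        raise PlanarGraphError("non-simple perimeter: cannot attach phantom boundary")
    pos = pg.positions
    anchors = [v for v in cyc if pg.degree(v) >= 3]
    if len(anchors) < 3:
        anchors = list(cyc)
    poly = Polygon([pos[v] for v in cyc])
    cx, cy = poly.centroid.x, poly.centroid.y

    out = pg.copy()
    phantom_vertices = []
    for v in anchors:
        x, y = pos[v]
        pid = ("phantom", v)
        out.g.add_node(pid, x=cx + scale * (x - cx), y=cy + scale * (y - cy))
        out.g.add_edge(v, pid, weight=math.inf)
        phantom_vertices.append(pid)
    for a, b in zip(phantom_vertices, phantom_vertices[1:] + phantom_vertices[:1]):
        out.g.add_edge(a, b, weight=math.inf)
    out.meta["phantom_vertices"] = set(phantom_vertices)
    logger.info("added phantom boundary with %d phantom loops", len(anchors))
    return out


# ---------------------------------------------------------------------------
# the decomposition proper
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    endpoints: tuple
    weights: tuple
    strength: float
    faces: tuple  # original face ids; resolve through union-find when used


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent
        root = x
        while p.get(root, root) != root:
            root = p[root]
        while p.get(x, x) != x:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def decompose(
    pg: PlanarGraph,
    mode: str = "single_exterior",
    strength_rule: str = "min",
    seed: int = 0,
    phantom_scale: float = 1.2,
    validate: bool = False,
) -> NestingTree:
    """Run the full pipeline and return the binary nesting tree.

    Pipeline: prune tree-like components, reassign bridge weights, perturb
    weight ties (seeded), optionally attach the phantom boundary, trace
    faces, collapse chains, then iterate weakest-chain removal until a single
    loop remains.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if strength_rule not in STRENGTH_RULES:
        raise ValueError(f"unknown strength rule {strength_rule!r}")
    agg = STRENGTH_RULES[strength_rule]

    work = prune_tree_components(pg)
    if not work.is_connected():
        raise PlanarGraphError("graph must be connected")
    if validate:
        work.validate_embedding()
    work = reassign_bridge_weights(work)
    work.perturb_ties(seed)
    if mode == "phantom_boundary":
        work = add_phantom_boundary(work, scale=phantom_scale)
        phantom_vertices = work.meta["phantom_vertices"]
    else:
        phantom_vertices = set()

    faces, face_of, outer_id = trace_faces(work)
    chains0 = collapse_chains(work)
    pos = work.positions
    face_centroids = {
        f.id: (
            float(sum(pos[v][0] for v in f.cycle) / len(f.cycle)),
            float(sum(pos[v][1] for v in f.cycle) / len(f.cycle)),
        )
        for f in faces if f.id != outer_id
    }

    # --- leaves ------------------------------------------------------------
    nodes: dict[int, NestingNode] = {}
    node_of: dict = {}   # union-find root (face id) -> tree node id
    uf = _UnionFind()
    nid = 0
    for f in faces:
        if f.id == outer_id:
            if mode == "single_exterior":
                nodes[nid] = NestingNode(nid, (), 0.0, 1, None, True, face="exterior")
                node_of[f.id] = nid
                nid += 1
            else:
                node_of[f.id] = None  # the true outside never enters the tree
        elif phantom_vertices and any(v in phantom_vertices for v in f.cycle):
            nodes[nid] = NestingNode(nid, (), 0.0, 1, None, True,
                                     face=("phantom", nid))
            node_of[f.id] = nid
            nid += 1
        else:
            nodes[nid] = NestingNode(nid, (), f.area, 1, None, False, face=f.id)
            node_of[f.id] = nid
            nid += 1
    n_loops = sum(1 for v in node_of.values() if v is not None)
    if n_loops == 0:
        raise PlanarGraphError("no loops to decompose")

    # --- chain state -------------------------------------------------------
    chains: dict[int, _Chain] = {}
    inc: dict = {}
    heap: list[tuple[float, int, int]] = []
    counter = 0
    for ch in chains0:
        u, v = ch.endpoints
        lu, lv = ch.links[0], ch.links[-1]
        f1 = face_of[lu]
        f2 = face_of[(lu[1], lu[0])]
        cid = counter
        counter += 1
        chains[cid] = _Chain((u, v), ch.weights, ch.strength(strength_rule), (f1, f2))
        inc.setdefault(u, []).append(cid)
        inc.setdefault(v, []).append(cid)
        heapq.heappush(heap, (chains[cid].strength, cid, cid))

    def fuse(c1: int, c2: int, w) -> None:
        nonlocal counter
        ch1, ch2 = chains.pop(c1), chains.pop(c2)
        a = ch1.endpoints[0] if ch1.endpoints[1] == w else ch1.endpoints[1]
        b = ch2.endpoints[0] if ch2.endpoints[1] == w else ch2.endpoints[1]
        inc[a].remove(c1)
        inc[b].remove(c2)
        del inc[w]
        weights = ch1.weights + ch2.weights
        cid = counter
        counter += 1
        chains[cid] = _Chain((a, b), weights, agg(weights), ch1.faces)
        inc[a].append(cid)
        inc[b].append(cid)
        heapq.heappush(heap, (chains[cid].strength, cid, cid))

    def delete_chain(cid: int) -> None:
        ch = chains.pop(cid)
        u, v = ch.endpoints
        inc[u].remove(cid)
        inc[v].remove(cid)
        for w in {u, v}:
            lst = inc.get(w)
            if not lst:
                inc.pop(w, None)
            elif len(lst) == 2 and lst[0] != lst[1]:
                fuse(lst[0], lst[1], w)

    # --- main loop ---------------------------------------------------------
    merges_needed = n_loops - 1
    merges_done = 0
    discarded = 0
    while merges_done < merges_needed:
        if not heap:
            raise PlanarGraphError("decomposition incomplete: ran out of chains")
        s, _, cid = heapq.heappop(heap)
        if cid not in chains:
            continue
        ch = chains[cid]
        r1, r2 = uf.find(ch.faces[0]), uf.find(ch.faces[1])
        n1, n2 = node_of.get(r1), node_of.get(r2)
        if r1 == r2 or n1 is None or n2 is None:
            delete_chain(cid)
            discarded += 1
            continue
        delete_chain(cid)
        l, r = nodes[n1], nodes[n2]
        nodes[nid] = NestingNode(nid, (n1, n2), l.area + r.area,
                                 l.degree + r.degree, ch.strength,
                                 l.exterior or r.exterior)
        root_face = uf.union(r1, r2)
        node_of[root_face] = nid
        nid += 1
        merges_done += 1

    root = nid - 1
    logger.info(
        "decomposition: %d leaves, %d merges, %d chains discarded without merge",
        n_loops, merges_done, discarded,
    )
    provenance = {
        "mode": mode,
        "strength_rule": strength_rule,
        "seed": seed,
        "source": pg.meta.get("name"),
        "face_centroids": face_centroids,
    }
    return NestingTree(nodes, root, mode=mode, provenance=provenance)
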
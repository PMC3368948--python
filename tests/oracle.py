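"""Independent brute-force reference for the hierarchical loop decomposition.

Re-derives the merge-event sequence of weakest-chain removal directly from
definitions: after *every* chain deletion the faces, chains and strengths are
recomputed from scratch on the remaining graph (no incremental bookkeeping),
and loops are identified across iterations geometrically, by which original
face reference points their polygon contains.  Minimum strength rule and the
single-exterior convention only.
"""

from __future__ import annotations

import math

import networkx as nx
from shapely.geometry import Polygon

EXT = "EXT"


def _prune(g: nx.Graph) -> None:
    while True:
        drop = [v for v in g if g.degree(v) <= 1]
        if not drop:
            return
        g.remove_nodes_from(drop)


def _faces(g: nx.Graph, pos) -> list[tuple[tuple, float]]:
    """All faces of one connected component as (vertex cycle, signed area)."""
    order = {}
    for v in g:
        x0, y0 = pos[v]
        nbrs = sorted(g.neighbors(v),
                      key=lambda u: math.atan2(pos[u][1] - y0, pos[u][0] - x0))
        order[v] = {nbrs[i]: nbrs[i - 1] for i in range(len(nbrs))}
    seen = set()
    out = []
    for a, b in list(g.edges()) + [(y, x) for x, y in g.edges()]:
        if (a, b) in seen:
            continue
        cyc = []
        u, v = a, b
        while True:
            seen.add((u, v))
            cyc.append(u)
            u, v = v, order[v][u]
            if (u, v) == (a, b):
                break
        area = 0.0
        for i in range(len(cyc)):
            (x1, y1), (x2, y2) = pos[cyc[i]], pos[cyc[(i + 1) % len(cyc)]]
            area += x1 * y2 - x2 * y1
        out.append((tuple(cyc), 0.5 * area))
    return out


def _chains(g: nx.Graph) -> list[tuple[tuple, float]]:
    """Maximal degree-2 chains as (ordered link list, min weight)."""
    junctions = {v for v in g if g.degree(v) != 2}
    seen = set()
    chains = []

    def walk(a, b):
        links = [(a, b)]
        seen.add(frozenset((a, b)))
        prev, cur = a, b
        while cur not in junctions and cur != a:
            n1, n2 = g.neighbors(cur)
            nxt = n2 if n1 == prev else n1
            links.append((cur, nxt))
            seen.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
        return links

    for j in junctions:
        for nb in list(g.neighbors(j)):
            if frozenset((j, nb)) not in seen:
                links = walk(j, nb)
                chains.append((tuple(links),
                               min(g.edges[e]["weight"] for e in links)))
    for u, v in g.edges():
        if frozenset((u, v)) not in seen:
            links = walk(u, v)
            chains.append((tuple(links),
                           min(g.edges[e]["weight"] for e in links)))
    return chains


def _point_in_ring(pt, ring, pos) -> bool:
    """Even-odd rule; robust to rings that traverse a bridge twice."""
    x, y = pt
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = pos[ring[i]]
        x2, y2 = pos[ring[(i + 1) % n]]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xc > x:
                inside = not inside
    return inside


def reassign_bridges(g: nx.Graph) -> None:
    """Bridge weight := min over the two sides of (max side weight) * (1 + 1e-9)."""
    orig = {frozenset(e): g.edges[e]["weight"] for e in g.edges()}
    for u, v in list(nx.bridges(g)):
        h = g.copy()
        h.remove_edge(u, v)
        best = []
        for node in (u, v):
            comp = nx.node_connected_component(h, node)
            ws = [orig[frozenset((a, b))] for a, b in g.edges(comp)
                  if a in comp and b in comp and frozenset((a, b)) != frozenset((u, v))]
            if ws:
                best.append(max(ws))
        if best:
            g.edges[u, v]["weight"] = min(best) * (1.0 + 1e-9)


def original_faces(g: nx.Graph, pos):
    """(reference point, vertex cycle) of every internal face of the pruned input."""
    out = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        faces = _faces(sub, pos)
        outer = max(range(len(faces)), key=lambda i: abs(faces[i][1]))
        for i, (cyc, _) in enumerate(faces):
            if i != outer:
                rp = Polygon([pos[v] for v in cyc]).representative_point()
                out.append(((rp.x, rp.y), cyc))
    return out


def brute_force_decompose(graph: nx.Graph, pos):
    """Merge-event sequence [(loop_id_1, loop_id_2, strength), ...].

    A loop id is the frozenset of original-face indices whose reference
    points its polygon contains; the exterior is the string ``"EXT"``.
    Assumes strictly distinct weights (perturb ties beforehand).
    """
    g = graph.copy()
    _prune(g)
    reassign_bridges(g)
    refs = original_faces(g, pos)
    events = []

    while g.number_of_edges() > 0:
        _prune(g)
        if g.number_of_edges() == 0:
            break
        chains = _chains(g)
        strengths = sorted(s for _, s in chains)
        assert all(b > a for a, b in zip(strengths, strengths[1:])), "tied strengths"
        links, s = min(chains, key=lambda c: c[1])

        # loop identity of the two sides of the chain, from scratch
        comp = nx.node_connected_component(g, links[0][0])
        sub = g.subgraph(comp)
        faces = _faces(sub, pos)
        outer = max(range(len(faces)), key=lambda i: abs(faces[i][1]))

        def loop_id(face_idx):
            if face_idx == outer:
                return EXT
            cyc = faces[face_idx][0]
            inside = frozenset(
                i for i, (rp, _) in enumerate(refs) if _point_in_ring(rp, cyc, pos)
            )
            return inside

        # the two sides: the face containing the first link in each direction
        sides = []
        for direction in (links, [(b, a) for a, b in links]):
            d0 = direction[0]
            for i, (cyc, _) in enumerate(faces):
                edges_of_face = {(cyc[j], cyc[(j + 1) % len(cyc)]) for j in range(len(cyc))}
                if d0 in edges_of_face:
                    sides.append(loop_id(i))
                    break
        assert len(sides) == 2, "chain does not border two face traversals"

        g.remove_edges_from([tuple(e) for e in links])
        if sides[0] != sides[1]:
            events.append((sides[0], sides[1], s))

    return events


def tree_events(tree, refs, pos):
    """Convert a NestingTree to the oracle's event representation.

    Leaves are matched to oracle face indices by centroid containment;
    exterior-containing composites collapse to ``EXT`` exactly as the oracle
    sees them (content merged into the outside loses its separate identity).
    """
    leaf_idx = {}
    cents = tree.provenance["face_centroids"]
    for n in tree.nodes.values():
        if not n.is_leaf or n.exterior:
            continue
        c = cents[n.face]
        matches = [i for i, (_, cyc) in enumerate(refs) if _point_in_ring(c, cyc, pos)]
        assert len(matches) == 1, f"leaf {n.id} matched faces {matches}"
        leaf_idx[n.id] = matches[0]

    ids: dict[int, object] = {}
    events = []
    for n in sorted(tree.nodes.values(), key=lambda n: n.id):
        if n.is_leaf:
            ids[n.id] = EXT if n.exterior else frozenset([leaf_idx[n.id]])
            continue
        a, b = (ids[c] for c in n.children)
        events.append((a, b, n.h))
        ids[n.id] = EXT if (a == EXT or b == EXT) else a | b
    return events


def same_events(ev1, ev2, tol=1e-12) -> bool:
    if len(ev1) != len(ev2):
        return False
    for (a1, b1, h1), (a2, b2, h2) in zip(ev1, ev2):
        if {repr(a1), repr(b1)} != {repr(a2), repr(b2)}:
            return False
        if abs(h1 - h2) > tol * max(1.0, abs(h1)):
            return False
    return True
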
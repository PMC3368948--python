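"""Readers and writers: edge-list TSV, GraphML, Newick and JSON nesting trees.

The TSV dialect is two tab-separated sections in one UTF-8 file::

    #nodes
    <id>\t<x>\t<y>
    ...
    #links
    <id_a>\t<id_b>\t<weight>
    ...

Comment lines starting with ``#`` (other than the section markers) are
ignored, so outputs may carry provenance headers.  GraphML files use ``x``
and ``y`` node attributes and a ``weight`` edge attribute.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import networkx as nx

from .planar import PlanarGraph, PlanarGraphError
from .tree import NestingNode, NestingTree

_FORMATS = ("tsv", "graphml")


def _coerce_ids(vertices: dict, links: list) -> tuple[dict, list]:
    try:
        mapping = {v: int(v) for v in vertices}
        if len(set(mapping.values())) != len(mapping):
            raise ValueError
    except (TypeError, ValueError):
        return vertices, links
    return (
        {mapping[v]: xy for v, xy in vertices.items()},
        [(mapping[u], mapping[v], w) for u, v, w in links],
    )


def read_network(
    path: str | Path,
    format: str | None = None,
    seed: int = 0,
    validate: bool = True,
    largest_component: bool = False,
) -> PlanarGraph:
    """Load and validate a weighted embedded graph.

    Duplicate links, self-loops, missing coordinates and non-positive
    weights are errors; a disconnected input is an error unless
    ``largest_component`` keeps the biggest piece.  Weight ties are broken
    with seed-controlled perturbations; set ``validate=False`` to skip the
    (quadratic-ish) non-crossing check for noisy digitizations.
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "tsv"
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")

    vertices: dict[Any, tuple[float, float]] = {}
    links: list[tuple[Any, Any, float]] = []
    if format == "tsv":
        section = None
        for lineno, raw in enumerate(path.read_text().splitlines(), 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tag = line.lstrip("#").strip().lower()
                if tag in ("nodes", "links"):
                    section = tag
                continue
            parts = line.split("\t")
            if section == "nodes":
                if len(parts) != 3:
                    raise PlanarGraphError(f"{path}:{lineno}: expected 'id x y'")
                vertices[parts[0]] = (float(parts[1]), float(parts[2]))
            elif section == "links":
                if len(parts) != 3:
                    raise PlanarGraphError(f"{path}:{lineno}: expected 'a b weight'")
                links.append((parts[0], parts[1], float(parts[2])))
            else:
                raise PlanarGraphError(f"{path}:{lineno}: data before a #nodes/#links marker")
        vertices, links = _coerce_ids(vertices, links)
    else:
        g = nx.read_graphml(path, force_multigraph=True)
        if any(True for _ in nx.selfloop_edges(g)):
            raise PlanarGraphError("self-loops in GraphML input")
        simple = nx.Graph(g)
        if simple.number_of_edges() != g.number_of_edges():
            raise PlanarGraphError("duplicate links in GraphML input")
        for v, d in g.nodes(data=True):
            if "x" not in d or "y" not in d:
                raise PlanarGraphError(f"vertex {v!r} missing x/y coordinates")
            vertices[v] = (float(d["x"]), float(d["y"]))
        for u, v, d in simple.edges(data=True):
            if "weight" not in d:
                raise PlanarGraphError(f"link ({u!r}, {v!r}) missing weight")
            links.append((u, v, float(d["weight"])))
        vertices, links = _coerce_ids(vertices, links)

    pg = PlanarGraph.build(vertices, links)
    if not pg.is_connected():
        if not largest_component:
            raise PlanarGraphError(
                "input graph is disconnected (pass largest_component=True to keep the biggest piece)"
            )
        comp = max(nx.connected_components(pg.g), key=len)
        pg = PlanarGraph(pg.g.subgraph(comp).copy(), pg.meta)
    pg.perturb_ties(seed)
    if validate:
        pg.validate_embedding()
    pg.meta.setdefault("name", path.stem)
    return pg


def write_network(pg: PlanarGraph, path: str | Path, format: str | None = None,
                  header: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "tsv"
    if format == "tsv":
        lines = []
        if header:
            lines.append(f"# {header}")
        lines.append("#nodes")
        for v, (x, y) in pg.positions.items():
            lines.append(f"{v}\t{x!r}\t{y!r}")
        lines.append("#links")
        for u, v, w in pg.links():
            lines.append(f"{u}\t{v}\t{w!r}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        g = nx.Graph()
        for v, (x, y) in pg.positions.items():
            g.add_node(v, x=x, y=y)
        for u, v, w in pg.links():
            g.add_edge(u, v, weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"format must be one of {_FORMATS}")


# ---------------------------------------------------------------------------
# nesting trees
# ---------------------------------------------------------------------------

def _float_repr(x: float | None) -> str:
    if x is None:
        return "none"
    return repr(float(x))


def _tree_label(n: NestingNode) -> str:
    face = "" if n.face is None else f"|face={n.face!r}"
    return (f"id={n.id}|A={_float_repr(n.area)}|d={n.degree}"
            f"|h={_float_repr(n.h)}|ext={int(n.exterior)}{face}")


def tree_to_newick(t: NestingTree) -> str:
    """Serialize a nesting tree as Newick with quoted attribute labels.

    Each node label encodes ``id | A | d | h | ext [| face]``; branch
    structure carries the topology.  Assembly is iterative, so arbitrarily
    deep (caterpillar) trees serialize without recursion limits.
    """
    parts: dict[int, str] = {}
    for n in t.postorder():
        label = "'" + _tree_label(n).replace("'", "''") + "'"
        if n.is_leaf:
            parts[n.id] = label
        else:
            c1, c2 = n.children
            parts[n.id] = f"({parts[c1]},{parts[c2]}){label}"
    return parts[t.root] + ";"


def tree_from_newick(text: str, mode: str = "single_exterior") -> NestingTree:
    """Parse an annotated Newick nesting tree (written by :func:`tree_to_newick`)."""
    import sys

    import dendropy

    # caterpillar-shaped nesting trees nest deeply; the reader recurses
    depth = 0
    cur = 0
    for ch in text:
        if ch == "(":
            cur += 1
            depth = max(depth, cur)
        elif ch == ")":
            cur -= 1
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 3000 + 8 * depth))
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=False,
                           preserve_underscores=True)
    nodes: dict[int, NestingNode] = {}

    def parse_label(label: str) -> dict:
        fields = {}
        for part in label.split("|"):
            k, _, v = part.partition("=")
            fields[k] = v
        return fields

    root_id = None
    for nd in dt.postorder_node_iter():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None:
            raise ValueError("nesting-tree Newick requires labels on every node")
        f = parse_label(label)
        nid = int(f["id"])
        children = tuple(
            int(parse_label(c.taxon.label if c.taxon else c.label)["id"])
            for c in nd.child_nodes()
        )
        h = None if f["h"] == "none" else float(f["h"])
        face: Any = None
        if "face" in f:
            raw = f["face"]
            try:
                face = int(raw)
            except ValueError:
                face = raw.strip("'\"")
        nodes[nid] = NestingNode(nid, children, float(f["A"]), int(f["d"]),
                                 h, bool(int(f["ext"])), face=face)
        root_id = nid
    return NestingTree(nodes, root_id, mode=mode)


def tree_to_json(t: NestingTree) -> dict:
    return {
        "mode": t.mode,
        "root": t.root,
        "provenance": {k: v for k, v in t.provenance.items() if _jsonable(v)},
        "nodes": [
            {
                "id": n.id,
                "children": list(n.children),
                "area": n.area,
                "degree": n.degree,
                "h": None if n.h is None else (repr(n.h) if math.isinf(n.h) else n.h),
                "exterior": n.exterior,
                "face": n.face if _jsonable(n.face) else repr(n.face),
            }
            for n in t.nodes.values()
        ],
    }


def _jsonable(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False


def tree_from_json(obj: dict) -> NestingTree:
    nodes = {}
    for d in obj["nodes"]:
        h = d["h"]
        if isinstance(h, str):
            h = float(h)
        nodes[d["id"]] = NestingNode(
            d["id"], tuple(d["children"]), d["area"], d["degree"],
            h, d["exterior"], face=d.get("face"),
        )
    return NestingTree(nodes, obj["root"], mode=obj.get("mode", "single_exterior"),
                       provenance=obj.get("provenance", {}))


def write_nesting_tree(t: NestingTree, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "newick" if path.suffix.lower() in (".nwk", ".newick", ".tre") else "json"
    if format == "newick":
        path.write_text(tree_to_newick(t) + "\n")
    elif format == "json":
        path.write_text(json.dumps(tree_to_json(t), indent=1))
    else:
        raise ValueError("format must be 'newick' or 'json'")


def read_nesting_tree(path: str | Path, format: str | None = None) -> NestingTree:
    path = Path(path)
    if format is None:
        format = "newick" if path.suffix.lower() in (".nwk", ".newick", ".tre") else "json"
    if format == "newick":
        return tree_from_newick(path.read_text())
    if format == "json":
        return tree_from_json(json.loads(path.read_text()))
    raise ValueError("format must be 'newick' or 'json'")


def write_series_tsv(series, path: str | Path, header: str | None = None) -> None:
    """Write a MetricSeries as TSV: abscissa, value[, stderr]."""
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# {header}")
    for k, v in sorted(series.meta.items()):
        lines.append(f"# {k}: {v}")
    if series.yerr is None:
        lines += [f"{x!r}\t{y!r}" for x, y in zip(series.x, series.y)]
    else:
        lines += [f"{x!r}\t{y!r}\t{e!r}"
                  for x, y, e in zip(series.x, series.y, series.yerr)]
    path.write_text("\n".join(lines) + "\n")
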
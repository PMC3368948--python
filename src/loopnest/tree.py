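"""Binary nesting trees: the merge history of a hierarchical loop decomposition.

Leaves are the elementary loops of the decomposed graph (plus one exterior
leaf, or a ring of phantom boundary leaves); each internal node records the
merge of its two children through the removal of an edge chain of strength
``h``.  Nodes carry the enclosed area (exterior content contributes zero),
the degree (number of leaf descendants) and an ``exterior`` flag marking
nodes whose subtree contains exterior/phantom leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Iterator


@dataclass(frozen=True)
class NestingNode:
    id: int
    children: tuple[int, ...]  # () for leaves, exactly 2 ids otherwise
    area: float
    degree: int
    h: float | None            # strength of the removed chain; None for leaves
    exterior: bool
    face: Any = None           # original face id for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


class NestingTree:
    """Full binary tree of merge events.

    ``mode`` is ``"single_exterior"`` or ``"phantom_boundary"``;
    ``provenance`` records how the tree was produced (strength rule, seed,
    source metadata) so a run is reproducible from its persisted output.
    """

    def __init__(
        self,
        nodes: dict[int, NestingNode],
        root: int,
        mode: str = "single_exterior",
        provenance: dict | None = None,
    ):
        self.nodes = nodes
        self.root = root
        self.mode = mode
        self.provenance = dict(provenance or {})
        self._parent: dict[int, int] | None = None

    # ------------------------------------------------------------- traversal
    def node(self, nid: int) -> NestingNode:
        return self.nodes[nid]

    def parent(self, nid: int) -> int | None:
        if self._parent is None:
            self._parent = {}
            for n in self.nodes.values():
                for c in n.children:
                    self._parent[c] = n.id
        return self._parent.get(nid)

    def postorder(self, start: int | None = None) -> Iterator[NestingNode]:
        """Iterative post-order traversal (children before parents)."""
        root = self.root if start is None else start
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            nid, expanded = stack.pop()
            node = self.nodes[nid]
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((nid, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def subtree_nodes(self, nid: int) -> Iterator[NestingNode]:
        stack = [nid]
        while stack:
            n = self.nodes[stack.pop()]
            yield n
            stack.extend(n.children)

    def leaves(self, start: int | None = None) -> list[NestingNode]:
        root = self.root if start is None else start
        return [n for n in self.subtree_nodes(root) if n.is_leaf]

    def internal_nodes(self) -> list[NestingNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return self.nodes[self.root].degree

    # ------------------------------------------------------------ invariants
    def validate(self, rtol: float = 1e-9) -> None:
        """Check full-binary shape, degree and area additivity, node counts."""
        n_leaves = n_internal = 0
        for n in self.postorder():
            if n.is_leaf:
                n_leaves += 1
                continue
            n_internal += 1
            if len(n.children) != 2:
                raise ValueError(f"node {n.id} has {len(n.children)} children")
            c1, c2 = (self.nodes[c] for c in n.children)
            if n.degree != c1.degree + c2.degree:
                raise ValueError(f"degree not additive at node {n.id}")
            tot = c1.area + c2.area
            if abs(n.area - tot) > rtol * max(1.0, abs(tot)):
                raise ValueError(f"area not conserved at node {n.id}")
            if n.exterior != (c1.exterior or c2.exterior):
                raise ValueError(f"exterior flag inconsistent at node {n.id}")
        if n_internal != n_leaves - 1:
            raise ValueError(
                f"{n_internal} internal nodes for {n_leaves} leaves (full binary tree expects leaves - 1)"
            )

    def merge_strengths(self) -> list[float]:
        """Removal strengths h in merge order (ascending node id)."""
        return [n.h for n in sorted(self.internal_nodes(), key=lambda n: n.id)]

    # ------------------------------------------------------------- builders
    @classmethod
    def from_nested(cls, spec, mode: str = "single_exterior") -> "NestingTree":
        """Build a tree from nested pairs.

        A leaf is a number (its area) or a ``dict`` with optional
        ``area``/``exterior``/``face`` keys; an internal node is a 2-tuple
        ``(left, right)`` or 3-tuple ``(left, right, h)``.  Merge heights
        default to 1, 2, ... in post-order.
        """
        nodes: dict[int, NestingNode] = {}
        counter = {"id": 0, "h": 0.0, "face": 0}

        def build(obj) -> int:
            if isinstance(obj, tuple):
                if len(obj) == 2:
                    left, right = obj
                    h = None
                else:
                    left, right, h = obj
                li, ri = build(left), build(right)
                if h is None:
                    counter["h"] += 1.0
                    h = counter["h"]
                nid = counter["id"]
                counter["id"] += 1
                l, r = nodes[li], nodes[ri]
                nodes[nid] = NestingNode(
                    nid, (li, ri), l.area + r.area, l.degree + r.degree,
                    float(h), l.exterior or r.exterior,
                )
                return nid
            if isinstance(obj, dict):
                area = float(obj.get("area", 1.0))
                ext = bool(obj.get("exterior", False))
                face = obj.get("face", counter["face"])
            else:
                area, ext, face = float(obj), False, counter["face"]
            counter["face"] += 1
            nid = counter["id"]
            counter["id"] += 1
            nodes[nid] = NestingNode(nid, (), 0.0 if ext else area, 1, None, ext,
                                     face=None if ext else face)
            return nid

        root = build(spec)
        return cls(nodes, root, mode=mode, provenance={"builder": "from_nested"})

    @classmethod
    def caterpillar(cls, n_leaves: int, leaf_area: float = 1.0) -> "NestingTree":
        """Purely additive history: leaves join a running composite one at a time."""
        if n_leaves < 2:
            raise ValueError("caterpillar needs >= 2 leaves")
        nodes: dict[int, NestingNode] = {}
        for i in range(n_leaves):
            nodes[i] = NestingNode(i, (), leaf_area, 1, None, False, face=i)
        cur = 0
        for i in range(1, n_leaves):
            nid = n_leaves + i - 1
            l, r = nodes[cur], nodes[i]
            nodes[nid] = NestingNode(nid, (cur, i), l.area + r.area,
                                     l.degree + r.degree, float(i), False)
            cur = nid
        return cls(nodes, cur, provenance={"builder": "caterpillar"})

    @classmethod
    def complete_binary(cls, depth: int, leaf_area: float = 1.0) -> "NestingTree":
        """Purely multiplicative history: 2**depth leaves merging pairwise."""
        nodes: dict[int, NestingNode] = {}
        nid = 0
        level = []
        for i in range(2 ** depth):
            nodes[nid] = NestingNode(nid, (), leaf_area, 1, None, False, face=i)
            level.append(nid)
            nid += 1
        h = 0.0
        while len(level) > 1:
            nxt = []
            for a, b in zip(level[::2], level[1::2]):
                h += 1.0
                l, r = nodes[a], nodes[b]
                nodes[nid] = NestingNode(nid, (a, b), l.area + r.area,
                                         l.degree + r.degree, h, False)
                nxt.append(nid)
                nid += 1
            level = nxt
        return cls(nodes, level[0], provenance={"builder": "complete_binary"})


def restricted_topology(t: NestingTree, keep: Iterable) -> Any:
    """Canonical (unordered) topology of the tree restricted to a leaf subset.

    Leaves are identified by their ``face`` attribute; internal nodes with a
    single surviving side are spliced out.  Returns nested frozensets (a
    hashable canonical form), or ``None`` if no kept leaf exists.
    """
    keep = set(keep)
    memo: dict[int, Any] = {}
    for n in t.postorder():
        if n.is_leaf:
            memo[n.id] = n.face if n.face in keep else None
        else:
            l, r = (memo[c] for c in n.children)
            if l is None:
                memo[n.id] = r
            elif r is None:
                memo[n.id] = l
            else:
                memo[n.id] = frozenset((l, r))
    return memo[t.root]
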
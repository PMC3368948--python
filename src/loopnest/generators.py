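"""Synthetic loopy networks: hexagonal triangular-lattice patches and weight models.

All models share one substrate (a hexagonal patch of the triangular lattice,
``rings`` concentric hexagons around a central vertex) and one weight
multiset (the ranks ``1..L`` over the ``L`` links); an architecture is
defined purely by *where* each weight goes:

* ``gradient``   — weights decay with the link midpoint's distance from the
  left-most vertex (a smooth source-to-tip gradient; additive architecture);
* ``random_links`` — a seeded uniform permutation of weights over links
  (no long-range order);
* ``nested``     — the three families of parallel lattice lines are ranked by
  recursive bisection (boundary and central lines order 0, bisectors of
  order-k spans order k+1) and thicker links occupy lower-order lines
  (self-similar, multiplicative architecture);
* ``nested5`` / ``nested10`` — nested, with 5 (10) randomly chosen lines
  randomly permuted among their positions (increasing disorder);
* ``random_lines`` — a full random permutation of the line order (long-range
  order in lines, none in their ranking);
* ``peaks``      — thick links concentrate around seven equidistant peaks
  (the center plus six half-radius hexagon corners).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .planar import PlanarGraph, PlanarGraphError, extract_faces

SQRT3_2 = math.sqrt(3.0) / 2.0

MODELS = (
    "gradient", "random_links", "nested", "nested5", "nested10",
    "random_lines", "peaks",
)


@dataclass(frozen=True)
class LatticeSpec:
    """Hexagonal patch of the triangular lattice: ``1 + 3n(n+1)`` vertices,
    ``9n^2 + 3n`` links, ``6n^2`` faces for ``n`` rings."""

    rings: int
    spacing: float = 1.0

    @property
    def n_vertices(self) -> int:
        return 1 + 3 * self.rings * (self.rings + 1)

    @property
    def n_links(self) -> int:
        return 9 * self.rings ** 2 + 3 * self.rings

    @property
    def n_faces(self) -> int:
        return 6 * self.rings ** 2


@dataclass(frozen=True)
class ModelSpec:
    model: str
    seed: int = 0
    peaks_count: int = 7
    swap_k: int | None = None  # number of permuted lines for nested variants


def triangular_lattice_hex(spec: LatticeSpec | int, spacing: float | None = None) -> PlanarGraph:
    """Build the hexagonal triangular-lattice patch with unit link weights."""
    if not isinstance(spec, LatticeSpec):
        spec = LatticeSpec(int(spec), spacing if spacing is not None else 1.0)
    n, a = spec.rings, spec.spacing
    if n < 1:
        raise ValueError("need at least 1 ring")
    axial = [
        (q, r)
        for q in range(-n, n + 1)
        for r in range(max(-n, -q - n), min(n, -q + n) + 1)
    ]
    index = {qr: i for i, qr in enumerate(axial)}
    vertices = {
        i: (a * (q + r / 2.0), a * r * SQRT3_2) for (q, r), i in index.items()
    }
    links = []
    for (q, r), i in index.items():
        for dq, dr in ((1, 0), (0, 1), (-1, 1)):
            j = index.get((q + dq, r + dr))
            if j is not None:
                links.append((i, j, 1.0))
    pg = PlanarGraph.build(vertices, links)
    pg.meta.update(
        name=f"hex_lattice_{n}",
        rings=n,
        spacing=a,
        axial={i: qr for qr, i in index.items()},
    )
    assert pg.n_vertices == spec.n_vertices and pg.n_links == spec.n_links
    return pg


# ---------------------------------------------------------------------------
# lattice lines
# ---------------------------------------------------------------------------

def _link_line(qr_a: tuple[int, int], qr_b: tuple[int, int]) -> tuple[str, int, int]:
    """(family, line index, position along line) of a lattice link."""
    (qa, ra), (qb, rb) = qr_a, qr_b
    if ra == rb:
        return ("r", ra, min(qa, qb))
    if qa == qb:
        return ("q", qa, min(ra, rb))
    sa = -qa - ra
    if sa != -qb - rb:
        raise PlanarGraphError("link does not follow a lattice line")
    return ("s", sa, min(ra, rb))


def _bisection_orders(n: int) -> dict[int, int]:
    """Self-similar ranking of line indices -n..n: boundaries and center are
    order 0, bisectors of order-k spans are order k+1 (lower index wins ties)."""
    order = {-n: 0, 0: 0, n: 0}

    def rec(lo: int, hi: int, k: int) -> None:
        if hi - lo < 2:
            return
        mid = (lo + hi) // 2
        order[mid] = k
        rec(lo, mid, k + 1)
        rec(mid, hi, k + 1)

    rec(-n, 0, 1)
    rec(0, n, 1)
    return order


def _lines(pg: PlanarGraph) -> dict[tuple[str, int], list[tuple[int, int]]]:
    """Group links by lattice line, each line's links sorted by position."""
    axial = pg.meta.get("axial")
    if axial is None:
        raise PlanarGraphError("line-based models need a lattice graph with axial metadata")
    lines: dict[tuple[str, int], list[tuple[int, tuple[int, int]]]] = {}
    for u, v, _ in pg.links():
        fam, idx, pos = _link_line(axial[u], axial[v])
        lines.setdefault((fam, idx), []).append((pos, (u, v)))
    return {
        key: [e for _, e in sorted(members)] for key, members in sorted(lines.items())
    }


def _nested_line_sequence(pg: PlanarGraph) -> list[tuple[str, int]]:
    if "rings" not in pg.meta:
        raise PlanarGraphError(
            "line-based models need a hex-patch lattice graph with line metadata"
        )
    n = pg.meta["rings"]
    order = _bisection_orders(n)
    keys = sorted(_lines(pg).keys(), key=lambda k: (order[k[1]], k[0], k[1]))
    return keys


# ---------------------------------------------------------------------------
# weight assignment
# ---------------------------------------------------------------------------

def _deal_by_lines(pg: PlanarGraph, sequence: list[tuple[str, int]]) -> dict[tuple, float]:
    """Deal the descending weight multiset line by line along a line sequence."""
    lines = _lines(pg)
    L = pg.n_links
    weights: dict[tuple, float] = {}
    w = float(L)
    for key in sequence:
        for (u, v) in lines[key]:
            weights[(u, v)] = w
            w -= 1.0
    assert w == 0.0
    return weights


def _rank_by_distance(pg: PlanarGraph, points: np.ndarray) -> dict[tuple, float]:
    """Descending weights by ascending link-midpoint distance to the nearest point."""
    pos = pg.positions
    edges = list(pg.g.edges())
    mids = np.array([
        [(pos[u][0] + pos[v][0]) / 2.0, (pos[u][1] + pos[v][1]) / 2.0]
        for u, v in edges
    ])
    d = np.min(
        np.linalg.norm(mids[:, None, :] - points[None, :, :], axis=2), axis=1
    )
    keys = sorted(range(len(edges)), key=lambda i: (d[i], mids[i, 0], mids[i, 1]))
    L = len(edges)
    return {edges[i]: float(L - rank) for rank, i in enumerate(keys)}


def default_peaks(pg: PlanarGraph, count: int = 7) -> np.ndarray:
    """Seven equidistant peaks: the center plus six half-radius hexagon corners."""
    if count != 7:
        raise ValueError("the default layout defines exactly 7 peaks; pass "
                         "explicit positions for other counts")
    n, a = pg.meta["rings"], pg.meta["spacing"]
    corners = [(n, 0), (0, n), (-n, n), (-n, 0), (0, -n), (n, -n)]
    pts = [(0.0, 0.0)] + [
        (0.5 * a * (q + r / 2.0), 0.5 * a * r * SQRT3_2) for q, r in corners
    ]
    return np.asarray(pts)


def assign_model_weights(
    pg: PlanarGraph,
    spec: ModelSpec | str,
    seed: int | None = None,
    peak_points: np.ndarray | None = None,
) -> PlanarGraph:
    """Assign the rank weight multiset ``1..L`` to the links per model rule.

    Every model is a bijection of the same multiset onto the links, so all
    models on the same lattice share the weight distribution exactly.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec, seed=seed if seed is not None else 0)
    model = spec.model
    rng = np.random.default_rng(spec.seed)
    out = pg.copy()

    if model == "gradient":
        pos = pg.positions
        left = min(pg.g.nodes, key=lambda v: (pos[v][0], pos[v][1]))
        weights = _rank_by_distance(pg, np.array([pos[left]]))
    elif model == "peaks":
        pts = peak_points if peak_points is not None else default_peaks(pg, spec.peaks_count)
        weights = _rank_by_distance(pg, np.asarray(pts, dtype=float))
    elif model == "random_links":
        edges = list(pg.g.edges())
        perm = rng.permutation(len(edges))
        weights = {e: float(p + 1) for e, p in zip(edges, perm)}
    elif model in ("nested", "nested5", "nested10", "random_lines"):
        sequence = _nested_line_sequence(pg)
        if model == "random_lines":
            sequence = [sequence[i] for i in rng.permutation(len(sequence))]
        elif model != "nested":
            k = spec.swap_k or int(model.removeprefix("nested"))
            # k seeded transpositions drawn from one permutation prefix: for
            # a fixed seed the pairs swapped by nested5 are a subset of those
            # swapped by nested10, coupling the variants for paired tests
            idx = rng.permutation(len(sequence))[: 2 * k]
            for i in range(k):
                a, b = idx[2 * i], idx[2 * i + 1]
                sequence[a], sequence[b] = sequence[b], sequence[a]
        weights = _deal_by_lines(pg, sequence)
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")

    for (u, v), w in weights.items():
        out.set_weight(u, v, w)
    out.meta.update(model=model, seed=spec.seed,
                    name=f"{pg.meta.get('name', 'graph')}_{model}_s{spec.seed}")
    return out


def assign_sector_weights(
    pg: PlanarGraph, points: np.ndarray | None = None
) -> PlanarGraph:
    """Vein-bounded sector fixture: thick links along sector boundaries.

    Emulates the geometry that makes leaf intercostal fields segmentable:
    each of the given points seeds a sector, links are thickest along the
    ridges equidistant between neighboring points and along the graph
    perimeter (the bounding veins), and thinnest deep inside a sector.
    Decomposing such a network merges each sector internally before any two
    sectors join, so the sectors appear as high-level nesting-tree subtrees.
    """
    from shapely.geometry import Point, Polygon

    from .planar import trace_faces

    if points is None:
        points = default_peaks(pg)
    points = np.asarray(points, dtype=float)
    pos = pg.positions
    edges = list(pg.g.edges())
    mids = np.array([
        [(pos[u][0] + pos[v][0]) / 2.0, (pos[u][1] + pos[v][1]) / 2.0]
        for u, v in edges
    ])
    dists = np.sort(np.linalg.norm(mids[:, None, :] - points[None, :, :], axis=2), axis=1)
    ridge = dists[:, 1] - dists[:, 0]          # small on sector boundaries
    faces, _, outer = trace_faces(pg)
    boundary = Polygon([pos[v] for v in faces[outer].cycle]).exterior
    bdist = np.array([boundary.distance(Point(m)) for m in mids])
    interiorness = np.minimum(ridge, bdist)    # large deep inside a sector
    order = sorted(range(len(edges)),
                   key=lambda i: (-interiorness[i], mids[i, 0], mids[i, 1]))
    out = pg.copy()
    for rank, i in enumerate(order):
        u, v = edges[i]
        out.set_weight(u, v, float(rank + 1))
    out.meta.update(model="sectors", n_sectors=len(points),
                    name=pg.meta.get("name", "graph") + "_sectors")
    return out


# ---------------------------------------------------------------------------
# contamination fixture
# ---------------------------------------------------------------------------

def plant_contamination(
    pg: PlanarGraph,
    n_spurious: int = 40,
    seed: int = 0,
    strength_range: tuple[float, float] = (0.90, 0.98),
) -> PlanarGraph:
    """Plant spuriously strong minor loops along the central (high-weight) lines.

    Emulates digitization bias (non-uniform staining) in which small loops
    next to major veins acquire inflated widths: for ``n_spurious`` randomly
    chosen triangular faces touching a central lattice line, the face's
    off-line links are boosted into ``strength_range`` (as a fraction of the
    top weight).  Such faces persist late into the decomposition and join the
    running composite one at a time, producing partition asymmetries near 1 —
    the signature the cleaning step removes.
    """
    axial = pg.meta.get("axial")
    if axial is None:
        raise PlanarGraphError("contamination fixture needs a lattice graph")
    rng = np.random.default_rng(seed)

    def on_central(u, v) -> bool:
        fam, idx, _ = _link_line(axial[u], axial[v])
        return idx == 0

    candidates = []
    for f in extract_faces(pg):
        cyc = f.cycle
        pairs = list(zip(cyc, cyc[1:] + cyc[:1]))
        if any(on_central(u, v) for u, v in pairs):
            candidates.append((f, pairs))
    if n_spurious > len(candidates):
        raise ValueError(f"only {len(candidates)} central-line faces available")
    picks = rng.choice(len(candidates), size=n_spurious, replace=False)

    out = pg.copy()
    top = max(w for _, _, w in pg.links())
    planted = []
    for i in picks:
        f, pairs = candidates[i]
        for u, v in pairs:
            if not on_central(u, v):
                out.set_weight(u, v, float(rng.uniform(*strength_range)) * top)
        planted.append(f.id)
    out.meta.update(contaminated_faces=planted,
                    name=pg.meta.get("name", "graph") + "_contaminated")
    return out
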
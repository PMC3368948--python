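"""Small hand-built planar fixtures used across the test suite."""

from loopnest import PlanarGraph


def two_triangles_shared_edge(shared_weight: float = 1.0) -> PlanarGraph:
    """Two triangles glued along one edge; the shared edge is the weakest."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 0), 3: (0.5, 1), 4: (0.5, -1)},
        [(1, 2, shared_weight), (1, 3, 5), (2, 3, 4), (1, 4, 7), (2, 4, 6)],
    )


def square_with_diagonal() -> PlanarGraph:
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 0), 3: (1, 1), 4: (0, 1)},
        [(1, 2, 2), (2, 3, 3), (3, 4, 4), (4, 1, 5), (1, 3, 1)],
    )


def theta() -> PlanarGraph:
    """Two vertices joined by three parallel chains."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (2, 0), 3: (1, 1), 4: (1, -1), 5: (1, 0)},
        [(1, 3, 2), (3, 2, 3), (1, 5, 4), (5, 2, 5), (1, 4, 6), (4, 2, 7)],
    )


def two_triangles_bridge() -> PlanarGraph:
    """Weak triangle (max 5) and strong triangle (max 9) joined by a weight-1 bridge."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 0), 3: (0.5, 0.8), 4: (3, 0), 5: (4, 0), 6: (3.5, 0.8)},
        [(1, 2, 3), (2, 3, 4), (1, 3, 5), (2, 4, 1.0), (4, 5, 8), (5, 6, 9), (4, 6, 7)],
    )


def three_blob_chain() -> PlanarGraph:
    """Three triangles in a row joined by two bridges; middle blob strongest."""
    return PlanarGraph.build(
        {
            1: (0, 0), 2: (1, 0), 3: (0.5, 0.8),        # maxes 5
            4: (3, 0), 5: (4, 0), 6: (3.5, 0.8),        # maxes 9
            7: (6, 0), 8: (7, 0), 9: (6.5, 0.8),        # maxes 7
        },
        [
            (1, 2, 3), (2, 3, 4), (1, 3, 5),
            (4, 5, 8), (5, 6, 9), (4, 6, 8.5),
            (7, 8, 6), (8, 9, 7), (7, 9, 6.5),
            (2, 4, 1.0), (5, 7, 2.0),
        ],
    )


def triangle_with_pendant() -> PlanarGraph:
    """Triangle plus a 3-link pendant path (pruned away entirely)."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 0), 3: (0.5, 0.8), 4: (2, 0), 5: (3, 0.2), 6: (4, 0)},
        [(1, 2, 3), (2, 3, 4), (1, 3, 5), (2, 4, 1), (4, 5, 2), (5, 6, 6)],
    )


def single_triangle() -> PlanarGraph:
    """Degenerate all-degree-2 cycle: one closed chain around one face."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 0), 3: (0.5, 0.8)},
        [(1, 2, 1), (2, 3, 2), (1, 3, 3)],
    )


def crossing_pair() -> PlanarGraph:
    """Two links that cross away from their endpoints: not an embedding."""
    return PlanarGraph.build(
        {1: (0, 0), 2: (1, 1), 3: (0, 1), 4: (1, 0), 5: (2, 0.5)},
        [(1, 2, 1), (3, 4, 2), (2, 5, 3), (4, 5, 4), (1, 3, 5)],
    )
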
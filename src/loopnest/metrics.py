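"""Tree metrics: partition asymmetry, cumulative size distribution, Strahler orders.

All metrics operate on a :class:`~loopnest.tree.NestingTree`.

* **Asymmetry** — the partition asymmetry ``q = |r - s| / (r + s - 2)`` of a
  bifurcation with subtree degrees ``r`` and ``s`` (``q = 0`` for the
  degenerate ``r = s = 1`` partition); the subtree asymmetry ``A(n)`` is the
  weighted mean of ``q`` over the internal nodes of the subtree (uniform
  weights by default); the averaged asymmetry ``Lambda(d)`` is the mean of
  ``A`` over subtrees whose degree lies within a log2 window of ``d``.
  A purely additive (caterpillar) history of degree ``d`` has
  ``A = (d - 2) / (d - 1)``; a purely multiplicative (complete binary)
  history has ``A = 0``.
* **Cumulative size distribution (CSD)** — the probability ``P(A > a)`` over
  the areas of all positive-area nesting-tree nodes (terminal loops and
  composites), with total area normalized to 1.  Additive histories give a
  straight line of slope -1/2 on linear axes; self-similar histories give
  ``P ~ 1/a``, so the adjusted CSD ``a * P(A > a)`` fluctuates about a
  constant.
* **Strahler** — leaves have order 1; a parent of equal-order children
  increments the order, otherwise takes the larger.  Stream counts ``N_w``
  count maximal same-order paths, and the bifurcation ratio ``R_B`` is the
  geometric decay rate of ``N_w``, fit by least squares through the fixed
  point ``(1, log N_1)`` with the noisy highest order discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .tree import NestingNode, NestingTree


@dataclass
class MetricSeries:
    """(abscissa, ordinate) pairs with optional errors and provenance metadata."""

    x: np.ndarray
    y: np.ndarray
    yerr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.yerr is not None:
            self.yerr = np.asarray(self.yerr, dtype=float)


# ---------------------------------------------------------------------------
# asymmetry
# ---------------------------------------------------------------------------

def subtree_degree(t: NestingTree, nid: int) -> int:
    """Number of leaf descendants of a node (a leaf has degree 1)."""
    return t.nodes[nid].degree


def partition_asymmetry(r: int, s: int, normalization: str = "vanpelt") -> float:
    """Imbalance of a bifurcation with subtree degrees r and s.

    ``normalization="vanpelt"`` (default): ``q = |r - s| / (r + s - 2)``,
    with ``q = 0`` for the degenerate partition ``r = s = 1``; under it a
    purely additive history of degree d has subtree asymmetry exactly
    ``(d - 2)/(d - 1)``.  ``normalization="degree_sum"``:
    ``q = |r - s| / (r + s)``, which damps the universal fine-scale
    partitions of self-similar architectures and so resolves graded
    architectural disorder more sharply (see the methods note).  Both are
    symmetric in (r, s) and bounded in [0, 1].
    """
    if r < 1 or s < 1:
        raise ValueError(f"subtree degrees must be >= 1, got ({r}, {s})")
    if normalization == "vanpelt":
        if r + s == 2:
            return 0.0
        return abs(r - s) / (r + s - 2)
    if normalization == "degree_sum":
        return abs(r - s) / (r + s)
    raise ValueError(f"unknown normalization {normalization!r}")


def partition_asymmetries(t: NestingTree, normalization: str = "vanpelt") -> dict[int, float]:
    """q at every internal node."""
    out = {}
    for n in t.internal_nodes():
        c1, c2 = (t.nodes[c] for c in n.children)
        out[n.id] = partition_asymmetry(c1.degree, c2.degree, normalization)
    return out


def subtree_asymmetries(t: NestingTree, normalization: str = "vanpelt") -> dict[int, float]:
    """A(n) for every internal node, uniform partition weights, in O(n).

    Accumulates the sum and count of q bottom-up, so deep (caterpillar-like)
    trees are handled without recursion.
    """
    q = partition_asymmetries(t, normalization)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    out: dict[int, float] = {}
    for n in t.postorder():
        if n.is_leaf:
            sums[n.id] = 0.0
            counts[n.id] = 0
            continue
        c1, c2 = n.children
        sums[n.id] = sums[c1] + sums[c2] + q[n.id]
        counts[n.id] = counts[c1] + counts[c2] + 1
        out[n.id] = sums[n.id] / counts[n.id]
    return out


def subtree_asymmetry(
    t: NestingTree,
    nid: int,
    weight_fn: Callable[[NestingNode], float] | None = None,
    normalization: str = "vanpelt",
) -> float:
    """Weighted mean of q over the internal nodes of the subtree rooted at nid.

    ``weight_fn`` maps an internal node to its partition weight w_j (uniform
    if omitted); the normalization is the sum of the weights.  Undefined for
    leaves (degree-1 subtrees).
    """
    node = t.nodes[nid]
    if node.is_leaf:
        raise ValueError("subtree asymmetry is undefined for a degree-1 node")
    if weight_fn is None:
        return subtree_asymmetries(t, normalization)[nid]
    num = den = 0.0
    for n in t.subtree_nodes(nid):
        if n.is_leaf:
            continue
        c1, c2 = (t.nodes[c] for c in n.children)
        w = weight_fn(n)
        num += w * partition_asymmetry(c1.degree, c2.degree, normalization)
        den += w
    if den == 0:
        raise ValueError("partition weights sum to zero")
    return num / den


def asymmetry_scatter(
    t: NestingTree, exclude: Iterable[int] = (), normalization: str = "vanpelt"
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """(log2 degree, A) scatter over internal nodes, for density plots."""
    A = subtree_asymmetries(t, normalization)
    skip = set(exclude)
    ids = [n.id for n in t.internal_nodes() if n.id not in skip]
    d = np.array([math.log2(t.nodes[i].degree) for i in ids])
    a = np.array([A[i] for i in ids])
    order = np.argsort(d, kind="stable")
    return d[order], a[order], [ids[i] for i in order]


def averaged_asymmetry(
    t: NestingTree,
    d: float,
    window_halfwidth_log2: float = 0.5,
    variant: str = "window",
    exclude: Iterable[int] = (),
    normalization: str = "vanpelt",
) -> float:
    """Lambda(d): mean subtree asymmetry around degree d.

    ``variant="window"`` averages A over internal nodes with
    ``|log2 d_j - log2 d| <= window_halfwidth_log2``; ``variant="exact"``
    averages over nodes with degree exactly ``round(d)``.  An empty window
    yields NaN (a missing point, not an exception).
    """
    logd, a, _ = asymmetry_scatter(t, exclude=exclude, normalization=normalization)
    if variant == "window":
        mask = np.abs(logd - math.log2(d)) <= window_halfwidth_log2
    elif variant == "exact":
        mask = np.isclose(2.0 ** logd, round(d))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if not mask.any():
        return float("nan")
    return float(a[mask].mean())


def asymmetry_series(
    t: NestingTree,
    d_values: Sequence[float] | None = None,
    window_halfwidth_log2: float = 0.5,
    exclude: Iterable[int] = (),
    normalization: str = "vanpelt",
) -> MetricSeries:
    """Lambda(d) on a log2-degree grid (default: half-octave steps)."""
    if d_values is None:
        dmax = max(n.degree for n in t.internal_nodes())
        grid = np.arange(1.0, math.log2(dmax) + 0.25, 0.5)
        d_values = 2.0 ** grid
    y = np.array([
        averaged_asymmetry(t, d, window_halfwidth_log2, exclude=exclude,
                           normalization=normalization)
        for d in d_values
    ])
    return MetricSeries(np.asarray(d_values, float), y,
                        meta={"window_halfwidth_log2": window_halfwidth_log2,
                              "quantity": "averaged_asymmetry",
                              "normalization": normalization})


# ---------------------------------------------------------------------------
# cumulative size distribution
# ---------------------------------------------------------------------------

def node_areas(t: NestingTree, normalize: bool = True) -> np.ndarray:
    """Areas of all positive-area nesting-tree nodes (terminal loops and
    composites); zero-area exterior/phantom leaves are excluded.  Normalized
    so the total graph area is 1."""
    areas = np.array([n.area for n in t.nodes.values() if n.area > 0], dtype=float)
    if areas.size == 0:
        raise ValueError("tree has no positive-area node")
    if normalize:
        areas = areas / t.nodes[t.root].area
    return areas


def cumulative_size_distribution(t: NestingTree, normalize: bool = True) -> MetricSeries:
    """P(A > a) over the node-area multiset, evaluated at all distinct areas."""
    areas = np.sort(node_areas(t, normalize=normalize))
    n = areas.size
    x = np.unique(areas)
    # count strictly greater: n - index of last occurrence of x
    y = (n - np.searchsorted(areas, x, side="right")) / n
    return MetricSeries(x, y, meta={"n": int(n), "quantity": "csd",
                                    "normalized": normalize})


def csd_probability(series: MetricSeries, a: float) -> float:
    """Evaluate the right-continuous step function P(A > a) from a CSD series."""
    if a < series.x[0]:
        return 1.0
    i = np.searchsorted(series.x, a, side="right") - 1
    return float(series.y[i])


def adjusted_csd(series: MetricSeries) -> MetricSeries:
    """a * P(A > a): constant for scale-invariant (P ~ 1/a) architectures."""
    return MetricSeries(series.x, series.x * series.y,
                        meta={**series.meta, "quantity": "adjusted_csd"})


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    stderr: float
    n_points: int


def fit_slope(
    series: MetricSeries,
    a_range: tuple[float, float] | None = None,
    axes: str = "linear",
) -> FitResult:
    """Ordinary least squares on linear or log-log axes over an abscissa range."""
    from scipy import stats

    x, y = series.x, series.y
    mask = np.ones_like(x, dtype=bool)
    if a_range is not None:
        mask &= (x >= a_range[0]) & (x <= a_range[1])
    if axes == "loglog":
        mask &= (x > 0) & (y > 0)
        xv, yv = np.log10(x[mask]), np.log10(y[mask])
    elif axes == "linear":
        xv, yv = x[mask], y[mask]
    else:
        raise ValueError(f"axes must be 'linear' or 'loglog', got {axes!r}")
    if xv.size < 2:
        raise ValueError("fewer than 2 points in fit range")
    res = stats.linregress(xv, yv)
    return FitResult(float(res.slope), float(res.intercept),
                     float(res.stderr) if res.stderr is not None else float("nan"),
                     int(xv.size))


# ---------------------------------------------------------------------------
# Strahler
# ---------------------------------------------------------------------------

def strahler_orders(t: NestingTree) -> dict[int, int]:
    """Strahler order of every node: leaves 1; equal children increment."""
    out: dict[int, int] = {}
    for n in t.postorder():
        if n.is_leaf:
            out[n.id] = 1
        else:
            o1, o2 = (out[c] for c in n.children)
            out[n.id] = o1 + 1 if o1 == o2 else max(o1, o2)
    return out


def stream_counts(t: NestingTree) -> np.ndarray:
    """N_w for w = 1..Omega: number of maximal same-order paths (streams).

    A stream head is a node whose parent has a different (higher) order, or
    the root; each stream is counted once at its head.  N_1 equals the number
    of leaves.
    """
    orders = strahler_orders(t)
    omega = orders[t.root]
    counts = np.zeros(omega, dtype=int)
    for n in t.nodes.values():
        pid = t.parent(n.id)
        if pid is None or orders[pid] != orders[n.id]:
            counts[orders[n.id] - 1] += 1
    return counts


@dataclass(frozen=True)
class StrahlerFit:
    ratio: float
    slope: float          # fitted slope of ln N_w vs w (negative)
    stderr: float         # standard error of the slope (NaN if not estimable)
    counts: np.ndarray
    two_point: bool = False


def fit_bifurcation_ratio(counts: Sequence[int]) -> StrahlerFit:
    """Constrained law-of-stream-numbers fit from a stream-count vector.

    Least squares of ``ln N_w`` vs ``w`` forced through ``(1, ln N_1)`` with
    the highest-order point discarded; ``R_B = exp(-slope)``.  With fewer
    than 3 distinct orders, falls back to the flagged two-point ratio
    ``N_1 / N_2``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2 or np.any(counts <= 0):
        raise ValueError("need positive stream counts for at least 2 orders")
    omega = counts.size
    if omega < 3:
        ratio = counts[0] / counts[1]
        return StrahlerFit(float(ratio), -math.log(ratio), float("nan"),
                           counts.astype(int), two_point=True)
    w = np.arange(2, omega)            # drop w = Omega (noise-sensitive)
    x = w - 1.0
    y = np.log(counts[w - 1]) - math.log(counts[0])
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    dof = x.size - 1
    if dof > 0:
        stderr = float(math.sqrt(float(resid @ resid) / dof / float(x @ x)))
    else:
        stderr = 0.0 if float(resid @ resid) < 1e-20 else float("nan")
    return StrahlerFit(math.exp(-slope), slope, stderr, counts.astype(int))


def bifurcation_ratio(t: NestingTree) -> StrahlerFit:
    """R_B of a nesting tree via the constrained stream-number fit."""
    return fit_bifurcation_ratio(stream_counts(t))
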
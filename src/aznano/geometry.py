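"""Geometric primitives for localization clusters.

Cluster areas are measured with 2-D alpha shapes: the sub-complex of the
Delaunay triangulation whose triangles have squared circumradius <= alpha
(alpha carries nm^2, the squared-radius convention).  Shape descriptors
(circularity, equivalent radius) and the distance kernels used throughout
the clustering workflow live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaShapeResult",
    "center_of_mass",
    "alpha_shape",
    "circularity",
    "equivalent_radius",
    "min_distance_to_set",
    "neighbor_distances",
]


def center_of_mass(points: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of the coordinates (the c.o.m.)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("center_of_mass of an empty point set is undefined")
    return pts.mean(axis=0)


@dataclass
class AlphaShapeResult:
    """Area/perimeter of the alpha complex of a point set.

    ``area``/``perimeter`` describe the alpha complex itself (holes excluded
    from area, hole boundaries included in perimeter).  ``outline_area`` /
    ``outline_perimeter`` describe the exterior outline with holes filled —
    the descriptor used for planar-view circularity.  ``degenerate`` is set
    (with area 0) when fewer than 3 non-collinear points exist or no
    triangle survives at this alpha.
    """

    area: float
    perimeter: float
    outline_area: float
    outline_perimeter: float
    alpha: float
    degenerate: bool
    boundary: list[np.ndarray] = field(default_factory=list)


def _degenerate(alpha: float) -> AlphaShapeResult:
    return AlphaShapeResult(0.0, 0.0, 0.0, 0.0, alpha, True)


def alpha_shape(points: np.ndarray, alpha: float) -> AlphaShapeResult:
    """Alpha complex of ``points`` at squared-circumradius threshold ``alpha`` (nm^2).

    Keeps every Delaunay triangle with circumradius^2 <= alpha; the result's
    area is the total area of kept triangles and its perimeter the length of
    the complex boundary.  Degenerate inputs are flagged, never raised.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return _degenerate(alpha)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _degenerate(alpha)  # collinear or otherwise flat input
    simp = tri.simplices
    a = pts[simp[:, 0]]
    b = pts[simp[:, 1]]
    c = pts[simp[:, 2]]
    # squared circumradius = (|ab|^2 |bc|^2 |ca|^2) / (16 S^2)
    ab2 = ((b - a) ** 2).sum(1)
    bc2 = ((c - b) ** 2).sum(1)
    ca2 = ((a - c) ** 2).sum(1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = cross**2 / 4.0  # S^2
    with np.errstate(divide="ignore", invalid="ignore"):
        circum2 = np.where(area2 > 0, ab2 * bc2 * ca2 / (16.0 * area2), np.inf)
    keep = circum2 <= alpha
    if not keep.any():
        return _degenerate(alpha)
    polys = [shapely.Polygon(t) for t in np.stack([a[keep], b[keep], c[keep]], axis=1)]
    merged = shapely.union_all(polys)
    geoms = (
        list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    )
    area = 0.0
    perim = 0.0
    out_area = 0.0
    out_perim = 0.0
    boundary: list[np.ndarray] = []
    for g in geoms:
        if g.is_empty or g.geom_type != "Polygon":
            continue
        area += g.area
        perim += g.exterior.length + sum(r.length for r in g.interiors)
        ext = shapely.Polygon(g.exterior)
        out_area += ext.area
        out_perim += g.exterior.length
        boundary.append(np.asarray(g.exterior.coords))
    if area <= 0:
        return _degenerate(alpha)
    return AlphaShapeResult(area, perim, out_area, out_perim, alpha, False, boundary)


def circularity(
    points: np.ndarray, alpha: float, mode: str = "outline", shape: AlphaShapeResult | None = None
) -> float:
    """Isoperimetric shape score 4*pi*A/P^2 of the alpha shape, in [0, 1].

    ``mode="outline"`` (default) uses the exterior outline with holes
    filled, so a planar-view ring scores like its outline (a circle -> 1);
    ``mode="boundary"`` uses the alpha complex's total area and total
    perimeter, hole boundaries included.  Multi-component shapes use totals.
    Degenerate shapes have no defined circularity and return NaN.
    """
    res = shape if shape is not None else alpha_shape(points, alpha)
    if res.degenerate:
        return float("nan")
    if mode == "outline":
        a, p = res.outline_area, res.outline_perimeter
    elif mode == "boundary":
        a, p = res.area, res.perimeter
    else:
        raise ValueError(f"unknown circularity mode {mode!r}")
    if p <= 0:
        return float("nan")
    return float(min(1.0, max(0.0, 4.0 * np.pi * a / p**2)))


def equivalent_radius(area: float) -> float:
    """Radius of the circle with the given area: sqrt(area / pi)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return float(np.sqrt(area / np.pi))


def min_distance_to_set(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per query point, the minimum Euclidean distance to any reference point."""
    ref = np.asarray(reference, dtype=float).reshape(-1, 2)
    if len(ref) == 0:
        raise ValueError("reference point set must be non-empty")
    q = np.asarray(query, dtype=float).reshape(-1, 2)
    if len(q) == 0:
        return np.empty(0)
    d, _ = cKDTree(ref).query(q, k=1)
    return np.atleast_1d(d)


def neighbor_distances(points: np.ndarray, k: int = 1) -> np.ndarray:
    """Per-point distance to its k-th nearest other point (k = 1 is the NND).

    Points with fewer than k neighbors are omitted: with n points each has
    n - 1 neighbors, so the result is empty whenever n <= k.  Ties in
    neighbor rank are broken by point index for determinism.
    """
    if not 1 <= k:
        raise ValueError("k must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n <= k:
        return np.empty(0)
    d, _ = cKDTree(pts).query(pts, k=k + 1)
    return d[:, k]
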
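"""Ripley's K and the derived H function for cluster-radius estimation.

The estimator is the plain (uncorrected) pair-count form

    K_hat(r) = A / (n (n - 1)) * sum_{i != j} 1(d_ij <= r)

with no edge correction, evaluated on an inclusive grid of radii
(default 0..120 nm in 1-nm steps).  H(r) = sqrt(K(r)/pi) - r, so complete
spatial randomness is the zero line and the maximum of the averaged curve
reads out the dominant cluster-radius scale.

Without edge correction K_hat is biased low near the window boundary; for
CSR on an L x L square the exact expectation is
E[K_hat](r) = pi r^2 - 8 r^3 / (3 L) + r^4 / (2 L^2).  The optional
``period`` argument computes toroidal (periodic) distances instead, a
simulation convention that removes this deficit; the analysis pipeline
itself always uses plain Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "default_radii",
    "HCurve",
    "ripley_k",
    "h_function",
    "aggregate_h",
    "estimate_radius",
    "csr_expected_k",
]


def default_radii(r_max: float = 120.0, step: float = 1.0) -> np.ndarray:
    """Inclusive radius grid 0..r_max in ``step`` nm steps."""
    return np.arange(0.0, r_max + 0.5 * step, step)


def _pair_distances(points: np.ndarray, period) -> np.ndarray:
    if period is None:
        return pdist(points)
    lx, ly = (float(period), float(period)) if np.isscalar(period) else map(float, period)
    iu = np.triu_indices(len(points), 1)
    dx = np.abs(points[iu[0], 0] - points[iu[1], 0])
    dy = np.abs(points[iu[0], 1] - points[iu[1], 1])
    dx = np.minimum(dx, lx - dx)
    dy = np.minimum(dy, ly - dy)
    return np.hypot(dx, dy)


def ripley_k(
    points: np.ndarray,
    radii: np.ndarray,
    study_area: float,
    period: tuple[float, float] | float | None = None,
) -> np.ndarray:
    """Uncorrected Ripley K estimate at each radius (inclusive <=)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise ValueError("ripley_k requires at least 2 points")
    if not study_area > 0:
        raise ValueError("study_area must be > 0")
    d = np.sort(_pair_distances(pts, period))
    counts = 2 * np.searchsorted(d, np.asarray(radii, dtype=float), side="right")
    return study_area * counts / (n * (n - 1))


def h_function(
    points: np.ndarray,
    radii: np.ndarray,
    study_area: float,
    period: tuple[float, float] | float | None = None,
) -> np.ndarray:
    """H(r) = sqrt(K(r)/pi) - r; identically zero under CSR."""
    k = ripley_k(points, radii, study_area, period=period)
    return np.sqrt(k / np.pi) - np.asarray(radii, dtype=float)


def _cluster_area(points: np.ndarray, method: str) -> float:
    if method == "bbox":
        return float(np.ptp(points[:, 0]) * np.ptp(points[:, 1]))
    if method == "hull":
        from scipy.spatial import ConvexHull, QhullError

        try:
            return float(ConvexHull(points).volume)
        except QhullError:
            return 0.0
    raise ValueError(f"unknown study-area method {method!r}")


@dataclass
class HCurve:
    """Per-cluster H values aggregated as mean +- SD over clusters.

    The Poisson (CSR) reference for this transform is identically zero.
    """

    radii: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_clusters: int
    n_skipped: int = 0
    per_cluster: np.ndarray | None = None
    poisson_reference: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.poisson_reference is None:
            self.poisson_reference = np.zeros_like(np.asarray(self.radii, dtype=float))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "r_nm": self.radii,
                "h_mean_nm": self.mean,
                "h_sd_nm": self.sd,
                "n_clusters": self.n_clusters,
            }
        )


def aggregate_h(
    clusters: list[np.ndarray],
    radii: np.ndarray | None = None,
    study_area: str = "bbox",
    keep_curves: bool = False,
) -> HCurve:
    """Average per-cluster H curves (mean +- SD across clusters).

    ``study_area`` selects how each cluster's window area is measured
    ("bbox": axis-aligned bounding box, the default; "hull": convex hull).
    Clusters with fewer than 2 points or zero window area are skipped and
    counted in ``n_skipped``.
    """
    radii = default_radii() if radii is None else np.asarray(radii, dtype=float)
    curves = []
    skipped = 0
    for pts in clusters:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if len(pts) < 2:
            skipped += 1
            continue
        area = _cluster_area(pts, study_area)
        if not area > 0:
            skipped += 1
            continue
        curves.append(h_function(pts, radii, area))
    if not curves:
        raise ValueError("no usable clusters (need >= 2 points and nonzero area)")
    arr = np.asarray(curves)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros_like(radii)
    return HCurve(
        radii=radii,
        mean=arr.mean(axis=0),
        sd=sd,
        n_clusters=len(arr),
        n_skipped=skipped,
        per_cluster=arr if keep_curves else None,
    )


def estimate_radius(curve: HCurve) -> float:
    """Radius at the maximum of the mean H curve (ties -> smallest radius).

    An all-nonpositive curve (pure CSR or emptier) has no defined cluster
    radius and yields NaN; a boundary maximum at r = 0 is returned but
    flagged in the log as degenerate.
    """
    mean = np.asarray(curve.mean, dtype=float)
    if mean.size == 0:
        raise ValueError("empty H curve")
    if not np.any(mean > 0):
        logger.warning("H curve never exceeds the CSR reference; radius undefined")
        return float("nan")
    idx = int(np.argmax(mean))  # argmax returns the first (smallest-radius) tie
    r = float(np.asarray(curve.radii, dtype=float)[idx])
    if idx == 0:
        logger.warning("H curve maximum at the boundary r = %g nm (degenerate)", r)
    return r


def csr_expected_k(radii: np.ndarray, side: float) -> np.ndarray:
    """Exact expectation of the uncorrected K estimator under CSR on a square.

    E[K_hat](r) = pi r^2 - 8 r^3 / (3 L) + r^4 / (2 L^2) for r <= L, the
    boundary deficit of counting only in-window pairs.
    """
    r = np.asarray(radii, dtype=float)
    return np.pi * r**2 - 8.0 * r**3 / (3.0 * side) + r**4 / (2.0 * side**2)
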
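"""Three-level density-clustering workflow for two-channel AZ data.

Level 1 extracts Brp scaffold clusters (one cluster = one candidate active
zone; HDBSCAN, minimum cluster size 100 / minimum samples 25) and gates
them on alpha-shape area (excluded when <= 0.03 or >= 0.3 um^2).  The
target channel is denoised either against the retained scaffold
localizations (discard everything farther than 20 nm) or by a first-pass
HDBSCAN of its own (20 / 5, unclustered points are noise).  Level 2
extracts target subclusters (SCs; HDBSCAN 2 / 2), assigns each SC to the
scaffold cluster with the nearest localization, and classifies it as
intrasynaptic (<= 50 nm to scaffold signal), in AZ vicinity (> 50 and
<= 400 nm, at AZs of circularity >= 0.6) or extrasynaptic-far.  Level 3
clusters the SC centres of mass of one AZ into superclusters (SpCs;
HDBSCAN 2 / 2 with leaf selection).

The clustering backend is injectable: any callable mapping (points,
ClusterParams) to integer labels (-1 = noise) can stand in for HDBSCAN,
e.g. an exhaustive oracle on tiny inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AlphaShapeResult,
    alpha_shape,
    center_of_mass,
    circularity,
    min_distance_to_set,
)
from .locio import LocalizationTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "ScaffoldCluster",
    "Subcluster",
    "Supercluster",
    "hdbscan_labels",
    "cluster_scaffold",
    "denoise_by_reference",
    "denoise_single_channel",
    "extract_subclusters",
    "assign_to_scaffold",
    "classify_synaptic",
    "extract_superclusters",
    "parameter_scan",
]

AREA_GATE_LOW_UM2 = 0.03
AREA_GATE_HIGH_UM2 = 0.3
CIRCULARITY_GATE = 0.6


@dataclass(frozen=True)
class ClusterParams:
    """HDBSCAN parameter set: minimum cluster size, minimum samples and
    the cluster selection method (excess-of-mass or leaf)."""

    min_cluster_size: int
    min_samples: int
    selection: str = "eom"

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.selection not in ("eom", "leaf"):
            raise ValueError("selection must be 'eom' or 'leaf'")


Backend = Callable[[np.ndarray, ClusterParams], np.ndarray]


def hdbscan_labels(points: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Default clustering backend: scikit-learn's HDBSCAN.

    Inputs too small to cluster (fewer points than the minimum cluster
    size, or not more points than ``min_samples``) are all labelled noise.
    Labels are re-numbered by order of first appearance so results are
    deterministic in the input ordering.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < max(2, params.min_cluster_size) or n <= params.min_samples:
        return np.full(n, -1, dtype=int)
    from sklearn.cluster import HDBSCAN

    raw = HDBSCAN(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_method=params.selection,
        copy=True,
    ).fit_predict(pts)
    # renumber by first appearance for deterministic downstream ids
    out = np.full(n, -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ScaffoldCluster:
    """One first-level Brp cluster = one candidate AZ."""

    az_id: int
    indices: np.ndarray  # row indices into the Brp table
    xy: np.ndarray  # member localization coordinates (nm)
    com: np.ndarray
    area_um2: float
    circularity: float
    excluded: bool
    exclusion_reason: str  # "too-small" | "too-large" | "none"
    n_locs: int
    shape: AlphaShapeResult | None = None


@dataclass
class Subcluster:
    """One second-level target-channel cluster (SC)."""

    sc_id: int
    indices: np.ndarray  # row indices into the denoised target table
    xy: np.ndarray
    com: np.ndarray
    n_locs: int
    area_nm2: float
    density: float  # localizations / nm^2; NaN when area degenerate
    degenerate_area: bool
    az_id: int = -1
    radial_distance_nm: float = float("nan")
    dist_to_scaffold_nm: float = float("nan")
    synaptic_class: str = "unassigned"
    excluded: bool = False
    spc_id: int = -1


@dataclass
class Supercluster:
    """Third-level grouping of SC centres of mass within one AZ."""

    spc_id: int
    az_id: int
    member_sc_ids: list[int]
    com: np.ndarray
    mean_sc_distance_nm: float


def area_gate(area_um2: float) -> tuple[bool, str]:
    """Scaffold retention gate: excluded when area <= 0.03 or >= 0.3 um^2
    (both bounds inclusive)."""
    if area_um2 <= AREA_GATE_LOW_UM2:
        return True, "too-small"
    if area_um2 >= AREA_GATE_HIGH_UM2:
        return True, "too-large"
    return False, "none"


def cluster_scaffold(
    brp: LocalizationTable,
    params: ClusterParams = ClusterParams(100, 25),
    alpha: float = 800.0,
    backend: Backend = hdbscan_labels,
) -> list[ScaffoldCluster]:
    """Extract scaffold (AZ) clusters; noise localizations are discarded.

    Every cluster gets a centre of mass, alpha-shape area (alpha defaults
    to 800 nm^2), outline circularity and an area-gate exclusion flag.
    Excluded clusters stay in the output, flagged, because SCs assigned to
    them are excluded downstream.
    """
    xy = brp.xy
    labels = backend(xy, params)
    out: list[ScaffoldCluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        idx = np.nonzero(labels == lab)[0]
        pts = xy[idx]
        shape = alpha_shape(pts, alpha)
        area_um2 = shape.area / 1e6
        excl, reason = area_gate(area_um2)
        out.append(
            ScaffoldCluster(
                az_id=lab,
                indices=idx,
                xy=pts,
                com=center_of_mass(pts),
                area_um2=area_um2,
                circularity=circularity(pts, alpha, shape=shape),
                excluded=excl,
                exclusion_reason=reason,
                n_locs=len(idx),
                shape=shape,
            )
        )
    return out


def retained_scaffold_xy(scaffolds: Sequence[ScaffoldCluster]) -> np.ndarray:
    """All clustered scaffold localizations (area-excluded clusters kept:
    they are still scaffold signal for distance purposes)."""
    if not scaffolds:
        return np.empty((0, 2))
    return np.concatenate([s.xy for s in scaffolds])


def denoise_by_reference(
    rim: LocalizationTable,
    brp_retained: np.ndarray | LocalizationTable,
    threshold: float = 20.0,
) -> LocalizationTable:
    """Two-channel denoising: keep target localizations within ``threshold``
    nm (inclusive) of any retained scaffold localization."""
    ref = brp_retained.xy if isinstance(brp_retained, LocalizationTable) else np.asarray(brp_retained)
    if len(ref) == 0:
        raise ValueError("two-channel denoising requires a non-empty scaffold set")
    if len(rim) == 0:
        return rim
    d = min_distance_to_set(rim.xy, ref)
    return rim.select(d <= threshold)


def denoise_single_channel(
    rim: LocalizationTable,
    params: ClusterParams = ClusterParams(20, 5),
    backend: Backend = hdbscan_labels,
) -> LocalizationTable:
    """Single-channel denoising: first-pass HDBSCAN; unclustered
    localizations are considered noise and discarded."""
    if len(rim) == 0:
        return rim
    labels = backend(rim.xy, params)
    return rim.select(labels >= 0)


def extract_subclusters(
    rim_denoised: LocalizationTable,
    params: ClusterParams = ClusterParams(2, 2),
    alpha: float = 300.0,
    backend: Backend = hdbscan_labels,
) -> list[Subcluster]:
    """Second-level clustering of the denoised target channel into SCs.

    Per SC: members, centre of mass, alpha-shape area (alpha defaults to
    300 nm^2) and localization density.  SCs whose sparse signal yields a
    degenerate (zero) area are flagged; they are excluded from area and
    density statistics downstream but keep their localization count.
    """
    xy = rim_denoised.xy
    if len(xy) < 2:
        return []
    labels = backend(xy, params)
    out: list[Subcluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        idx = np.nonzero(labels == lab)[0]
        pts = xy[idx]
        shape = alpha_shape(pts, alpha)
        degenerate = shape.degenerate
        out.append(
            Subcluster(
                sc_id=lab,
                indices=idx,
                xy=pts,
                com=center_of_mass(pts),
                n_locs=len(idx),
                area_nm2=shape.area,
                density=(len(idx) / shape.area) if not degenerate else float("nan"),
                degenerate_area=degenerate,
            )
        )
    return out


def assign_to_scaffold(
    scs: Sequence[Subcluster], scaffolds: Sequence[ScaffoldCluster]
) -> list[Subcluster]:
    """Assign each SC to the scaffold cluster with the nearest localization.

    The assignment minimizes the SC-c.o.m.-to-scaffold-localization
    distance (ties broken by lowest az_id); the SC's radial distance is the
    Euclidean distance between the SC c.o.m. and the AZ c.o.m.  SCs
    assigned to area-excluded scaffolds inherit the exclusion.
    """
    if not scaffolds:
        raise ValueError("assignment requires at least one scaffold cluster")
    scs = list(scs)
    if not scs:
        return scs
    ordered = sorted(scaffolds, key=lambda s: s.az_id)
    by_id = {s.az_id: s for s in ordered}
    coms = np.array([sc.com for sc in scs])
    # distance matrix SC c.o.m. -> nearest localization of each scaffold
    dists = np.column_stack([min_distance_to_set(coms, s.xy) for s in ordered])
    best = np.argmin(dists, axis=1)  # argmin takes the first (lowest-az_id) tie
    for i, sc in enumerate(scs):
        scaffold = ordered[int(best[i])]
        sc.az_id = scaffold.az_id
        sc.dist_to_scaffold_nm = float(dists[i, best[i]])
        sc.radial_distance_nm = float(np.hypot(*(sc.com - scaffold.com)))
        sc.excluded = scaffold.excluded
    return scs


def classify_synaptic(
    scs: Sequence[Subcluster],
    scaffolds: Sequence[ScaffoldCluster],
    r_intra: float = 50.0,
    r_vicinity: float = 400.0,
) -> list[Subcluster]:
    """Synaptic classification by SC-c.o.m. distance to scaffold signal.

    intrasynaptic: d <= r_intra (inclusive); vicinity: r_intra < d <=
    r_vicinity at a parent AZ of circularity >= 0.6; extrasynaptic-far
    otherwise.  Distances to the scaffold were fixed during assignment
    (nearest retained scaffold localization).
    """
    by_id = {s.az_id: s for s in scaffolds}
    for sc in scs:
        d = sc.dist_to_scaffold_nm
        if not np.isfinite(d):
            sc.synaptic_class = "unassigned"
            continue
        if d <= r_intra:
            sc.synaptic_class = "intrasynaptic"
        elif d <= r_vicinity and by_id.get(sc.az_id) is not None and (
            by_id[sc.az_id].circularity >= CIRCULARITY_GATE
        ):
            sc.synaptic_class = "vicinity"
        else:
            sc.synaptic_class = "extrasynaptic-far"
    return list(scs)


def extract_superclusters(
    scs_of_az: Sequence[Subcluster],
    params: ClusterParams = ClusterParams(2, 2, "leaf"),
    backend: Backend = hdbscan_labels,
) -> list[Supercluster]:
    """Third-level clustering of one AZ's SC centres of mass into SpCs.

    Input SCs are sorted by sc_id before clustering so degenerate
    tie-break geometries resolve deterministically.  Unclustered SCs keep
    spc_id = -1.  Fewer than 2 SCs yield no SpCs.
    """
    scs = sorted(scs_of_az, key=lambda s: s.sc_id)
    if len(scs) < 2:
        return []
    az_ids = {sc.az_id for sc in scs}
    if len(az_ids) > 1:
        raise ValueError("superclusters are defined within a single AZ")
    coms = np.array([sc.com for sc in scs])
    labels = backend(coms, params)
    out: list[Supercluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = [scs[i] for i in np.nonzero(labels == lab)[0]]
        mcoms = np.array([m.com for m in members])
        com = center_of_mass(mcoms)
        dists = np.hypot(*(mcoms - com).T)
        spc = Supercluster(
            spc_id=lab,
            az_id=members[0].az_id,
            member_sc_ids=[m.sc_id for m in members],
            com=com,
            mean_sc_distance_nm=float(dists.mean()),
        )
        for m in members:
            m.spc_id = lab
        out.append(spc)
    return out


def parameter_scan(
    images: Sequence[LocalizationTable],
    grid: Sequence[tuple[int, int]],
    selection: str = "eom",
    backend: Backend = hdbscan_labels,
) -> pd.DataFrame:
    """First-pass cluster counts over a (min_samples, min_cluster_size) grid.

    For each grid cell the first-pass clustering runs on every image and
    the median cluster count across images is recorded — the contour-plot
    data used to pick single-channel denoising parameters.
    """
    if not images:
        raise ValueError("parameter_scan requires at least one image")
    rows = []
    for min_samples, min_cluster_size in grid:
        params = ClusterParams(min_cluster_size, min_samples, selection)
        counts = []
        for img in images:
            labels = backend(img.xy, params)
            counts.append(int(labels.max() + 1) if labels.size else 0)
        rows.append(
            {
                "min_samples": min_samples,
                "min_cluster_size": min_cluster_size,
                "median_cluster_count": float(np.median(counts)),
                "n_images": len(images),
            }
        )
    return pd.DataFrame(rows)
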
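"""End-to-end orchestration of the two-channel AZ analysis.

``run_two_channel`` executes the reference workflow: ROI masking, scaffold
(AZ) extraction, 20-nm two-channel denoising of the target channel, SC
extraction, AZ assignment, synaptic classification, circularity-gated
supercluster extraction, per-AZ Ripley H aggregation and summary tables.
``run_single_channel`` swaps the 20-nm rule for the single-channel
first-pass HDBSCAN denoiser, which additionally makes extrasynaptic SC
populations quantifiable.  ``recover_parameters`` scores a result bundle
against the generative ground truth of a synthetic scene.

All localization counts convert to approximate molecule numbers through
the 0.134 molecules-per-localization factor.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import __version__
from .cluster_core import (
    Backend,
    ClusterParams,
    ScaffoldCluster,
    Subcluster,
    Supercluster,
    assign_to_scaffold,
    classify_synaptic,
    cluster_scaffold,
    denoise_by_reference,
    denoise_single_channel,
    extract_subclusters,
    extract_superclusters,
    hdbscan_labels,
    retained_scaffold_xy,
)
from .geometry import equivalent_radius, min_distance_to_set, neighbor_distances
from .locio import LocalizationTable, RoiMask, apply_roi
from .ripley import HCurve, aggregate_h, default_radii
from .synthgen import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ResultBundle",
    "RecoveryReport",
    "run_two_channel",
    "run_single_channel",
    "summarize",
    "normalized_histogram",
    "recover_parameters",
]

MOLECULES_PER_LOCALIZATION = 0.134


@dataclass
class PipelineConfig:
    """Every stage parameter of the workflow, at its reference default."""

    scaffold_min_cluster_size: int = 100
    scaffold_min_samples: int = 25
    scaffold_alpha_nm2: float = 800.0
    area_gate_low_um2: float = 0.03
    area_gate_high_um2: float = 0.3
    denoise_threshold_nm: float = 20.0
    single_min_cluster_size: int = 20
    single_min_samples: int = 5
    sc_min_cluster_size: int = 2
    sc_min_samples: int = 2
    sc_alpha_nm2: float = 300.0
    circularity_gate: float = 0.6
    r_intrasynaptic_nm: float = 50.0
    r_vicinity_nm: float = 400.0
    spc_min_cluster_size: int = 2
    spc_min_samples: int = 2
    spc_selection: str = "leaf"
    h_r_max_nm: float = 120.0
    h_step_nm: float = 1.0
    h_study_area: str = "bbox"  # or "hull"
    molecules_per_localization: float = MOLECULES_PER_LOCALIZATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.area_gate_low_um2 < self.area_gate_high_um2:
            raise ValueError("area gates must be ordered low < high")
        if not self.r_intrasynaptic_nm < self.r_vicinity_nm:
            raise ValueError("synaptic thresholds must be ordered intra < vicinity")
        for name, val in asdict(self).items():
            if isinstance(val, (int, float)) and name != "seed" and val <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def scaffold_params(self) -> ClusterParams:
        return ClusterParams(self.scaffold_min_cluster_size, self.scaffold_min_samples)

    @property
    def single_params(self) -> ClusterParams:
        return ClusterParams(self.single_min_cluster_size, self.single_min_samples)

    @property
    def sc_params(self) -> ClusterParams:
        return ClusterParams(self.sc_min_cluster_size, self.sc_min_samples)

    @property
    def spc_params(self) -> ClusterParams:
        return ClusterParams(self.spc_min_cluster_size, self.spc_min_samples, self.spc_selection)

    @property
    def h_radii(self) -> np.ndarray:
        return default_radii(self.h_r_max_nm, self.h_step_nm)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


@dataclass
class ResultBundle:
    """Everything one pipeline run produces."""

    route: str
    scaffolds: list[ScaffoldCluster]
    subclusters: list[Subcluster]
    superclusters: list[Supercluster]
    sc_table: pd.DataFrame
    az_table: pd.DataFrame
    spc_table: pd.DataFrame
    hcurve_table: pd.DataFrame
    nnd_table: pd.DataFrame
    summary_table: pd.DataFrame
    hcurve: HCurve | None
    run_meta: dict


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, (KeyboardInterrupt, SystemExit)):
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _intra(scs: list[Subcluster]) -> list[Subcluster]:
    return [s for s in scs if s.synaptic_class == "intrasynaptic" and not s.excluded]


def _sc_table(scs: list[Subcluster], mol_factor: float) -> pd.DataFrame:
    rows = []
    for sc in scs:
        rows.append(
            {
                "sc_id": sc.sc_id,
                "az_id": sc.az_id,
                "com_x_nm": sc.com[0],
                "com_y_nm": sc.com[1],
                "n_locs": sc.n_locs,
                "area_nm2": sc.area_nm2,
                "density_per_nm2": sc.density,
                "equivalent_radius_nm": equivalent_radius(sc.area_nm2)
                if not sc.degenerate_area
                else np.nan,
                "radial_distance_nm": sc.radial_distance_nm,
                "dist_to_scaffold_nm": sc.dist_to_scaffold_nm,
                "synaptic_class": sc.synaptic_class,
                "excluded": sc.excluded,
                "degenerate_area": sc.degenerate_area,
                "spc_id": sc.spc_id,
                "est_molecules": sc.n_locs * mol_factor,
            }
        )
    cols = [
        "sc_id", "az_id", "com_x_nm", "com_y_nm", "n_locs", "area_nm2",
        "density_per_nm2", "equivalent_radius_nm", "radial_distance_nm",
        "dist_to_scaffold_nm", "synaptic_class", "excluded", "degenerate_area",
        "spc_id", "est_molecules",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["excluded"] = df["excluded"].astype(bool)
    df["degenerate_area"] = df["degenerate_area"].astype(bool)
    return df


def _az_table(
    scaffolds: list[ScaffoldCluster],
    scs: list[Subcluster],
    spcs: list[Supercluster],
    mol_factor: float,
) -> pd.DataFrame:
    intra = _intra(scs)
    spc_by_az: dict[int, int] = {}
    for spc in spcs:
        spc_by_az[spc.az_id] = spc_by_az.get(spc.az_id, 0) + 1
    rows = []
    for s in scaffolds:
        mine = [sc for sc in intra if sc.az_id == s.az_id]
        n_locs = int(sum(sc.n_locs for sc in mine))
        area_sum = float(sum(sc.area_nm2 for sc in mine if not sc.degenerate_area))
        in_spc = sum(1 for sc in mine if sc.spc_id >= 0)
        rows.append(
            {
                "az_id": s.az_id,
                "com_x_nm": s.com[0],
                "com_y_nm": s.com[1],
                "n_brp_locs": s.n_locs,
                "area_um2": s.area_um2,
                "circularity": s.circularity,
                "excluded": s.excluded,
                "exclusion_reason": s.exclusion_reason,
                "n_sc": len(mine),
                "n_rim_locs": n_locs,
                "rim_area_sum_nm2": area_sum,
                "mean_radial_nm": float(np.mean([sc.radial_distance_nm for sc in mine]))
                if mine
                else np.nan,
                "n_spc": spc_by_az.get(s.az_id, 0),
                "pct_sc_in_spc": 100.0 * in_spc / len(mine) if mine else np.nan,
                "est_molecules": n_locs * mol_factor,
            }
        )
    cols = [
        "az_id", "com_x_nm", "com_y_nm", "n_brp_locs", "area_um2", "circularity",
        "excluded", "exclusion_reason", "n_sc", "n_rim_locs", "rim_area_sum_nm2",
        "mean_radial_nm", "n_spc", "pct_sc_in_spc", "est_molecules",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def _spc_table(spcs: list[Supercluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spc_id": spc.spc_id,
                "az_id": spc.az_id,
                "n_sc": len(spc.member_sc_ids),
                "com_x_nm": spc.com[0],
                "com_y_nm": spc.com[1],
                "mean_sc_distance_nm": spc.mean_sc_distance_nm,
            }
            for spc in spcs
        ],
        columns=["spc_id", "az_id", "n_sc", "com_x_nm", "com_y_nm", "mean_sc_distance_nm"],
    )


def _nnd_table(scaffolds: list[ScaffoldCluster], scs: list[Subcluster]) -> pd.DataFrame:
    """Per-AZ nearest to 5th-neighbor distances between intrasynaptic SC
    c.o.m.s; per k, AZs with too few SCs drop out."""
    rows = []
    intra = _intra(scs)
    for s in scaffolds:
        if s.excluded:
            continue
        coms = np.array([sc.com for sc in intra if sc.az_id == s.az_id])
        for k in range(1, 6):
            if len(coms) <= k:
                continue
            for d in neighbor_distances(coms, k):
                rows.append({"az_id": s.az_id, "k": k, "distance_nm": float(d)})
    return pd.DataFrame(rows, columns=["az_id", "k", "distance_nm"])


def _h_groups(
    rim_denoised: LocalizationTable,
    scaffolds: list[ScaffoldCluster],
    config: PipelineConfig,
) -> list[np.ndarray]:
    """Denoised target localizations grouped per retained circular AZ.

    Each localization joins the scaffold cluster with the nearest member
    localization; localizations farther than the vicinity threshold from
    every scaffold are left out (relevant for the single-channel route,
    where extrasynaptic signal survives denoising).
    """
    keep = [
        s
        for s in scaffolds
        if not s.excluded and np.isfinite(s.circularity) and s.circularity >= config.circularity_gate
    ]
    if not keep or len(rim_denoised) == 0:
        return []
    xy = rim_denoised.xy
    dists = np.column_stack([min_distance_to_set(xy, s.xy) for s in keep])
    nearest = np.argmin(dists, axis=1)
    within = dists[np.arange(len(xy)), nearest] <= config.r_vicinity_nm
    groups = []
    for i in range(len(keep)):
        pts = xy[(nearest == i) & within]
        if len(pts) >= 2:
            groups.append(pts)
    return groups


def _run(
    route: str,
    config: PipelineConfig,
    brp: LocalizationTable,
    rim: LocalizationTable,
    roi: RoiMask | None,
    backend: Backend,
) -> ResultBundle:
    if roi is not None:
        with _stage("roi-masking"):
            brp = apply_roi(brp, roi)
            rim = apply_roi(rim, roi)

    with _stage("scaffold-clustering"):
        scaffolds = cluster_scaffold(
            brp, config.scaffold_params, config.scaffold_alpha_nm2, backend=backend
        )
        brp_retained = retained_scaffold_xy(scaffolds)

    with _stage("denoising"):
        if route == "two-channel":
            rim_d = denoise_by_reference(rim, brp_retained, config.denoise_threshold_nm)
        else:
            rim_d = denoise_single_channel(rim, config.single_params, backend=backend)

    with _stage("subcluster-extraction"):
        scs = extract_subclusters(rim_d, config.sc_params, config.sc_alpha_nm2, backend=backend)

    if scaffolds:
        with _stage("scaffold-assignment"):
            scs = assign_to_scaffold(scs, scaffolds)
        with _stage("synaptic-classification"):
            scs = classify_synaptic(
                scs, scaffolds, config.r_intrasynaptic_nm, config.r_vicinity_nm
            )
    else:
        logger.warning("no scaffold clusters found; SCs left unassigned")

    with _stage("supercluster-extraction"):
        spcs: list[Supercluster] = []
        next_id = 0
        intra = _intra(scs)
        for s in scaffolds:
            if (
                s.excluded
                or not np.isfinite(s.circularity)
                or s.circularity < config.circularity_gate
            ):
                continue
            mine = [sc for sc in intra if sc.az_id == s.az_id]
            found = extract_superclusters(mine, config.spc_params, backend=backend)
            for spc in found:  # renumber globally, preserving per-AZ order
                spc.spc_id = next_id
                for sc in mine:
                    if sc.sc_id in spc.member_sc_ids:
                        sc.spc_id = next_id
                next_id += 1
            spcs.extend(found)

    with _stage("h-function"):
        groups = _h_groups(rim_d, scaffolds, config)
        hcurve = None
        if groups:
            hcurve = aggregate_h(groups, config.h_radii, study_area=config.h_study_area)
        hcurve_table = (
            hcurve.to_frame()
            if hcurve is not None
            else pd.DataFrame(columns=["r_nm", "h_mean_nm", "h_sd_nm", "n_clusters"])
        )

    with _stage("tables"):
        mol = config.molecules_per_localization
        sc_table = _sc_table(scs, mol)
        az_table = _az_table(scaffolds, scs, spcs, mol)
        spc_table = _spc_table(spcs)
        nnd_table = _nnd_table(scaffolds, scs)

    bundle = ResultBundle(
        route=route,
        scaffolds=scaffolds,
        subclusters=scs,
        superclusters=spcs,
        sc_table=sc_table,
        az_table=az_table,
        spc_table=spc_table,
        hcurve_table=hcurve_table,
        nnd_table=nnd_table,
        summary_table=pd.DataFrame(),
        hcurve=hcurve,
        run_meta={
            "package": "aznano",
            "version": __version__,
            "route": route,
            "seed": config.seed,
            **{f"config_{k}": v for k, v in asdict(config).items() if not isinstance(v, tuple)},
        },
    )
    bundle.summary_table = summarize(bundle)
    _check_bundle_invariants(bundle)
    return bundle


def run_two_channel(
    config: PipelineConfig,
    brp: LocalizationTable,
    rim: LocalizationTable,
    roi: RoiMask | None = None,
    backend: Backend = hdbscan_labels,
) -> ResultBundle:
    """Reference workflow: scaffold clustering then 20-nm two-channel denoising."""
    return _run("two-channel", config, brp, rim, roi, backend)


def run_single_channel(
    config: PipelineConfig,
    brp: LocalizationTable,
    rim: LocalizationTable,
    roi: RoiMask | None = None,
    backend: Backend = hdbscan_labels,
) -> ResultBundle:
    """Alternative workflow: single-channel HDBSCAN denoising (makes
    extrasynaptic and vicinity SC populations quantifiable)."""
    return _run("single-channel", config, brp, rim, roi, backend)


def _check_bundle_invariants(bundle: ResultBundle) -> None:
    """Per-AZ totals must equal sums over member SCs; asserted every run."""
    sc = bundle.sc_table
    intra = sc[(sc.synaptic_class == "intrasynaptic") & (~sc.excluded)]
    for _, row in bundle.az_table.iterrows():
        mine = intra[intra.az_id == row.az_id]
        assert int(row.n_sc) == len(mine)
        assert int(row.n_rim_locs) == int(mine.n_locs.sum())
        good = mine[~mine.degenerate_area]
        assert np.isclose(row.rim_area_sum_nm2, good.area_nm2.sum())
    pct = bundle.az_table.pct_sc_in_spc.dropna()
    assert ((pct >= 0) & (pct <= 100)).all()


# ---------------------------------------------------------------------------
# summaries


def _quartile_row(name: str, scope: str, values: np.ndarray) -> dict:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"metric": name, "scope": scope, "n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan}
    q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return {"metric": name, "scope": scope, "n": int(vals.size), "median": med, "q25": q25, "q75": q75}


def summarize(bundle: ResultBundle) -> pd.DataFrame:
    """Median (25th-75th percentile) summary rows, the reporting format of
    the study: per-SC metrics over intrasynaptic SCs, per-AZ metrics over
    retained AZs, per-SpC metrics over superclusters."""
    sc = bundle.sc_table
    az = bundle.az_table
    spc = bundle.spc_table
    intra = sc[(sc.synaptic_class == "intrasynaptic") & (~sc.excluded)]
    ok_area = intra[~intra.degenerate_area]
    keep_az = az[~az.excluded]
    rows = [
        _quartile_row("sc_n_locs", "intrasynaptic SC", intra.n_locs),
        _quartile_row("sc_area_nm2", "intrasynaptic SC", ok_area.area_nm2),
        _quartile_row("sc_density_per_nm2", "intrasynaptic SC", ok_area.density_per_nm2),
        _quartile_row("sc_equivalent_radius_nm", "intrasynaptic SC", ok_area.equivalent_radius_nm),
        _quartile_row("sc_radial_distance_nm", "intrasynaptic SC", intra.radial_distance_nm),
        _quartile_row("sc_est_molecules", "intrasynaptic SC", intra.est_molecules),
        _quartile_row("az_n_sc", "AZ", keep_az.n_sc),
        _quartile_row("az_n_rim_locs", "AZ", keep_az.n_rim_locs),
        _quartile_row("az_rim_area_sum_nm2", "AZ", keep_az.rim_area_sum_nm2),
        _quartile_row("az_mean_radial_nm", "AZ", keep_az.mean_radial_nm),
        _quartile_row("az_circularity", "AZ", keep_az.circularity),
        _quartile_row("az_area_um2", "AZ", keep_az.area_um2),
        _quartile_row("az_n_spc", "AZ", keep_az.n_spc),
        _quartile_row("az_pct_sc_in_spc", "AZ", keep_az.pct_sc_in_spc),
        _quartile_row("spc_n_sc", "SpC", spc.n_sc),
        _quartile_row("spc_mean_sc_distance_nm", "SpC", spc.mean_sc_distance_nm),
    ]
    for cls in ("vicinity", "extrasynaptic-far"):
        sub = sc[(sc.synaptic_class == cls) & (~sc.excluded)]
        good = sub[~sub.degenerate_area]
        rows.append(_quartile_row("sc_n_locs", f"{cls} SC", sub.n_locs))
        rows.append(_quartile_row("sc_area_nm2", f"{cls} SC", good.area_nm2))
        rows.append(_quartile_row("sc_density_per_nm2", f"{cls} SC", good.density_per_nm2))
    return pd.DataFrame(rows, columns=["metric", "scope", "n", "median", "q25", "q75"])


def normalized_histogram(values: np.ndarray, bins) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with counts normalized to the total number of observed
    events (the total is set to 1)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    counts, edges = np.histogram(vals, bins=bins)
    total = counts.sum()
    return (counts / total if total else counts.astype(float)), edges


# ---------------------------------------------------------------------------
# ground-truth recovery


@dataclass
class RecoveryReport:
    """Per-parameter comparison between generative truth and a bundle."""

    table: pd.DataFrame
    az_detection_rate: float
    sc_detection_rate: float
    n_truth_az: int
    n_truth_sc: int


def _match(
    truth_xy: np.ndarray, found_xy: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centre bipartite matching under a distance cutoff; returns
    (truth indices, found indices) of matched pairs."""
    if len(truth_xy) == 0 or len(found_xy) == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.hypot(
        truth_xy[:, None, 0] - found_xy[None, :, 0],
        truth_xy[:, None, 1] - found_xy[None, :, 1],
    )
    cost = np.where(d <= cutoff, d, 1e9)
    ti, fi = linear_sum_assignment(cost)
    ok = d[ti, fi] <= cutoff
    return ti[ok], fi[ok]


def recover_parameters(
    bundle: ResultBundle,
    truth: GroundTruth,
    az_match_cutoff: float | None = None,
    sc_match_cutoff: float = 20.0,
    generative_sc_radius_nm: float | None = None,
) -> RecoveryReport:
    """Score a bundle against ground truth by nearest-centre matching.

    AZs match within the ring radius (default cutoff), SCs within
    ``sc_match_cutoff`` nm.  The report gives, per parameter, the
    generative value, the recovered median and the relative error.
    """
    meta_seed = bundle.run_meta.get("seed")
    if meta_seed is not None and truth.seed is not None and meta_seed != truth.seed:
        raise ValueError(
            f"bundle seed {meta_seed} does not match truth seed {truth.seed}"
        )
    if az_match_cutoff is None:
        az_match_cutoff = float(truth.az.ring_radius.max()) if len(truth.az) else 200.0

    az = bundle.az_table
    az_xy = az[["com_x_nm", "com_y_nm"]].to_numpy()
    truth_az_xy = truth.az[["x", "y"]].to_numpy()
    ti, fi = _match(truth_az_xy, az_xy, az_match_cutoff)
    az_rate = len(ti) / len(truth.az) if len(truth.az) else np.nan

    sc = bundle.sc_table
    intra = sc[(sc.synaptic_class == "intrasynaptic") & (~sc.excluded)]
    truth_intra = truth.sc[~truth.sc.extrasynaptic]
    si, sj = _match(
        truth_intra[["x", "y"]].to_numpy(),
        intra[["com_x_nm", "com_y_nm"]].to_numpy(),
        sc_match_cutoff,
    )
    sc_rate = len(si) / len(truth_intra) if len(truth_intra) else np.nan

    rows = []

    def add(name, generative, recovered):
        rel = (
            abs(recovered - generative) / abs(generative)
            if np.isfinite(generative) and generative != 0 and np.isfinite(recovered)
            else np.nan
        )
        rows.append(
            {"parameter": name, "generative": generative, "recovered": recovered, "relative_error": rel}
        )

    add("az_count", float(len(truth.az)), float((~az.excluded).sum()))
    truth_counts = truth_intra.groupby("az_id").size()
    add(
        "sc_count_per_az",
        float(truth_counts.median()) if len(truth_counts) else np.nan,
        float(az[~az.excluded].n_sc.median()) if len(az) else np.nan,
    )
    add(
        "radial_distance_nm",
        float(truth_intra.radial_distance.median()) if len(truth_intra) else np.nan,
        float(az[~az.excluded].mean_radial_nm.median()) if len(az) else np.nan,
    )
    good = intra[~intra.degenerate_area]
    add(
        "sc_equivalent_radius_nm",
        generative_sc_radius_nm if generative_sc_radius_nm is not None else np.nan,
        float(good.equivalent_radius_nm.median()) if len(good) else np.nan,
    )
    table = pd.DataFrame(rows, columns=["parameter", "generative", "recovered", "relative_error"])
    return RecoveryReport(
        table=table,
        az_detection_rate=float(az_rate),
        sc_detection_rate=float(sc_rate),
        n_truth_az=len(truth.az),
        n_truth_sc=len(truth_intra),
    )
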
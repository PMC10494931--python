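"""Synthetic two-channel SMLM scenes with ground truth.

Each scene emulates the nanotopology the analysis pipeline targets: active
zones (AZs) whose scaffold channel is an annular Brp point cloud (ring
radius 186.3 nm), a target channel whose subclusters (SCs) of 1-2 molecules
sit at ~120 nm radial distance from the AZ centre, geometric blinking that
reproduces the 0.134 molecules-per-localization conversion factor,
extrasynaptic SC sites of larger spread, and uniform background noise in
both channels.  Every localization is attributable to exactly one source
(AZ scaffold, SC molecule, or background) through the emitted tables, so
the scene doubles as a parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locio import LocalizationTable

__all__ = ["SceneConfig", "GroundTruth", "blink_expand", "sample_az_layout", "generate_scene"]


@dataclass
class SceneConfig:
    """Generative parameters of a two-channel AZ scene (lengths in nm).

    Defaults encode the emulated study conditions: ~10 SCs per AZ at
    ~120 nm radial distance, 1-2 molecules per SC blinking with
    p = 0.134 (mean 1/p ~= 7.5 localizations per molecule), a Brp annulus
    of ring radius 186.3 nm whose alpha-shape area falls inside the
    0.03-0.3 um^2 retention gate, and 8 nm lateral localization precision.
    """

    field_size: tuple[float, float] = (6000.0, 6000.0)
    n_az: int = 20
    az_ring_radius: float = 186.3
    az_ring_thickness: float = 180.0
    brp_locs_mean: float = 1200.0
    brp_locs_min: int = 300
    sc_per_az_mean: float = 10.0
    sc_radial_mean: float = 120.0
    sc_radial_sd: float = 30.0
    sc_radial_bounds: tuple[float, float] = (30.0, 180.0)
    sc_molecules: tuple[int, int] = (1, 2)
    sc_spread: float = 4.0
    blink_p: float = 0.134
    localization_precision: float = 8.0
    background_density: float = 20.0  # localizations per um^2 per channel
    extrasynaptic_sc_rate: int = 12  # SC count per scene
    extrasynaptic_spread_factor: float = 2.0
    extrasynaptic_site_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.blink_p <= 1.0:
            raise ValueError("blink_p must lie in (0, 1]")
        for name in (
            "az_ring_radius",
            "az_ring_thickness",
            "brp_locs_mean",
            "sc_per_az_mean",
            "sc_radial_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.localization_precision < 0 or self.sc_spread < 0:
            raise ValueError("spreads must be >= 0")
        if self.background_density < 0 or self.extrasynaptic_sc_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def min_az_separation(self) -> float:
        """Required pairwise AZ-centre separation: no overlap between one
        AZ's outermost SC zone and the next."""
        return 2.0 * (self.az_ring_radius + self.sc_radial_bounds[1])


@dataclass
class GroundTruth:
    """Generative record of a scene; the oracle for recovery tests.

    ``az``: az_id, x, y, ring_radius, n_brp_locs.
    ``sc``: sc_id, az_id (-1 for extrasynaptic), x, y, n_molecules,
    n_localizations, radial_distance, extrasynaptic.
    """

    az: pd.DataFrame
    sc: pd.DataFrame
    n_background_brp: int = 0
    n_background_rim: int = 0
    seed: int = 0

    @property
    def n_az(self) -> int:
        return len(self.az)


def blink_expand(
    molecules: np.ndarray,
    blink_p: float,
    precision: float,
    rng: np.random.Generator,
) -> LocalizationTable:
    """Expand molecule positions into blinking localizations.

    Each molecule emits k >= 1 localizations with k ~ Geometric(blink_p)
    (support 1, 2, ...; mean 1/blink_p, i.e. the molecules-per-localization
    ratio converges to blink_p), each displaced by isotropic Gaussian noise
    of sd ``precision``.  The emitted table carries a ``molecule`` column
    with the source molecule index.
    """
    if not 0.0 < blink_p <= 1.0:
        raise ValueError("blink_p must lie in (0, 1]")
    mols = np.asarray(molecules, dtype=float).reshape(-1, 2)
    if len(mols) == 0:
        return LocalizationTable(pd.DataFrame({"x": [], "y": [], "molecule": []}))
    k = rng.geometric(blink_p, size=len(mols))
    idx = np.repeat(np.arange(len(mols)), k)
    locs = mols[idx]
    if precision > 0:
        locs = locs + rng.normal(0.0, precision, size=locs.shape)
    df = pd.DataFrame({"x": locs[:, 0], "y": locs[:, 1], "molecule": idx})
    return LocalizationTable(df, channel_label="blink")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (narrow tails, cheap)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_az_layout(config: SceneConfig, rng: np.random.Generator) -> GroundTruth:
    """Place AZ centres and SC truth records.

    AZ centres sit on a jittered grid guaranteeing pairwise separation
    greater than ``config.min_az_separation``; SC centres are placed at a
    truncated-normal radial distance (default mean 120 nm) in a uniform
    random direction.  Extrasynaptic SCs are laid out in small sites
    uniformly over the field outside all AZ disks.
    """
    w, h = config.field_size
    sep = config.min_az_separation
    cell = sep * 1.05
    ncol, nrow = int(w // cell), int(h // cell)
    if ncol * nrow < config.n_az:
        raise ValueError(
            f"field {w:g}x{h:g} nm too small for {config.n_az} AZs at "
            f"minimum separation {sep:g} nm"
        )
    cells = [(i, j) for i in range(nrow) for j in range(ncol)]
    chosen = [cells[i] for i in rng.permutation(len(cells))[: config.n_az]]
    jitter = (cell - sep) / 2.0
    az_rows = []
    for az_id, (i, j) in enumerate(sorted(chosen)):
        cx = (j + 0.5) * cell + rng.uniform(-jitter, jitter)
        cy = (i + 0.5) * cell + rng.uniform(-jitter, jitter)
        az_rows.append((az_id, cx, cy, config.az_ring_radius, 0))
    az = pd.DataFrame(az_rows, columns=["az_id", "x", "y", "ring_radius", "n_brp_locs"])

    sc_rows = []
    sc_id = 0
    for _, row in az.iterrows():
        n_sc = max(1, int(rng.poisson(config.sc_per_az_mean)))
        radial = _truncated_normal(
            rng, config.sc_radial_mean, config.sc_radial_sd, *config.sc_radial_bounds, size=n_sc
        )
        theta = rng.uniform(0.0, 2.0 * np.pi, n_sc)
        for r, t in zip(radial, theta):
            nmol = int(rng.integers(config.sc_molecules[0], config.sc_molecules[1] + 1))
            sc_rows.append(
                (sc_id, int(row.az_id), row.x + r * np.cos(t), row.y + r * np.sin(t), nmol, 0, r, False)
            )
            sc_id += 1

    # extrasynaptic SC sites, uniform outside all AZ disks
    outer = config.az_ring_radius + config.az_ring_thickness / 2.0
    az_xy = az[["x", "y"]].to_numpy()
    n_extra = int(config.extrasynaptic_sc_rate)
    site_size = max(1, int(config.extrasynaptic_site_size))
    placed = 0
    while placed < n_extra:
        for _ in range(1000):
            p = rng.uniform([0, 0], [w, h])
            if len(az_xy) == 0 or np.min(np.hypot(*(az_xy - p).T)) > outer + 50.0:
                break
        else:
            raise ValueError("could not place extrasynaptic site outside AZ disks")
        for _ in range(min(site_size, n_extra - placed)):
            off = rng.uniform(0.0, 100.0) * np.array(
                [np.cos(a := rng.uniform(0, 2 * np.pi)), np.sin(a)]
            )
            nmol = int(rng.integers(config.sc_molecules[0], config.sc_molecules[1] + 1))
            sc_rows.append((sc_id, -1, p[0] + off[0], p[1] + off[1], nmol, 0, np.nan, True))
            sc_id += 1
            placed += 1

    sc = pd.DataFrame(
        sc_rows,
        columns=["sc_id", "az_id", "x", "y", "n_molecules", "n_localizations", "radial_distance", "extrasynaptic"],
    )
    return GroundTruth(az=az, sc=sc, seed=config.seed)


def _sample_annulus(
    rng: np.random.Generator, center: np.ndarray, r_mid: float, thickness: float, n: int
) -> np.ndarray:
    r_in = max(0.0, r_mid - thickness / 2.0)
    r_out = r_mid + thickness / 2.0
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, n))  # uniform by area
    t = rng.uniform(0.0, 2.0 * np.pi, n)
    return center + np.c_[r * np.cos(t), r * np.sin(t)]


def generate_scene(
    config: SceneConfig,
) -> tuple[LocalizationTable, LocalizationTable, GroundTruth]:
    """Generate the Brp (scaffold) and RIM (target) channels plus truth.

    Fully reproducible from ``config.seed``.  Channel tables carry source
    bookkeeping columns (``az_id`` / ``sc_id`` / ``molecule``; -1 means
    background), so conservation against the truth record is checkable.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_az_layout(config, rng)
    w, h = config.field_size
    area_um2 = w * h / 1e6
    prec = config.localization_precision

    # ---- scaffold channel ----
    brp_parts = []
    brp_counts = []
    for _, row in truth.az.iterrows():
        n = max(config.brp_locs_min, int(rng.poisson(config.brp_locs_mean)))
        pts = _sample_annulus(
            rng, np.array([row.x, row.y]), config.az_ring_radius, config.az_ring_thickness, n
        )
        if prec > 0:
            pts = pts + rng.normal(0.0, prec, pts.shape)
        brp_parts.append(
            pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "az_id": int(row.az_id)})
        )
        brp_counts.append(n)
    truth.az["n_brp_locs"] = brp_counts
    n_bg_brp = int(rng.poisson(config.background_density * area_um2))
    bg = rng.uniform([0, 0], [w, h], (n_bg_brp, 2))
    brp_parts.append(pd.DataFrame({"x": bg[:, 0], "y": bg[:, 1], "az_id": -1}))
    truth.n_background_brp = n_bg_brp
    brp = LocalizationTable(
        pd.concat(brp_parts, ignore_index=True), channel_label="brp", source="synthetic"
    )

    # ---- target channel ----
    rim_parts = []
    loc_counts = []
    mol_offset = 0
    for _, row in truth.sc.iterrows():
        spread = config.sc_spread * (
            config.extrasynaptic_spread_factor if row.extrasynaptic else 1.0
        )
        mols = np.array([row.x, row.y]) + rng.normal(0.0, spread, (int(row.n_molecules), 2))
        tab = blink_expand(mols, config.blink_p, prec, rng).data
        tab["molecule"] = tab["molecule"].astype(int) + mol_offset
        mol_offset += int(row.n_molecules)
        tab["sc_id"] = int(row.sc_id)
        rim_parts.append(tab)
        loc_counts.append(len(tab))
    truth.sc["n_localizations"] = loc_counts
    n_bg_rim = int(rng.poisson(config.background_density * area_um2))
    bg = rng.uniform([0, 0], [w, h], (n_bg_rim, 2))
    rim_parts.append(
        pd.DataFrame({"x": bg[:, 0], "y": bg[:, 1], "molecule": -1, "sc_id": -1})
    )
    truth.n_background_rim = n_bg_rim
    rim = LocalizationTable(
        pd.concat(rim_parts, ignore_index=True), channel_label="rim", source="synthetic"
    )
    return brp, rim, truth
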
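"""Localization-table and ROI input/output.

Localization tables are delimited-text exports (one row per localization,
coordinates in nm after ``ColumnMap.unit_scale``); rapidSTORM-style exports
are readable by naming their coordinate columns.  Regions of interest come
either as a binary raster (TIFF/PNG at a stated nm-per-pixel binning, the
convention of 10 nm px^-1 reconstructions masked in FIJI) or as a polygon
vertex list.  All coordinates inside the package are 2-D nanometres.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMap",
    "LocalizationTable",
    "RoiMask",
    "read_localizations",
    "apply_roi",
    "write_results",
]


@dataclass(frozen=True)
class ColumnMap:
    """How to pull x/y (in nm) out of a delimited localization export.

    ``unit_scale`` multiplies raw coordinate values to nanometres
    (e.g. 1000 for a table exported in micrometres).
    """

    x_column: str = "x[nm]"
    y_column: str = "y[nm]"
    unit_scale: float = 1.0
    delimiter: str = ","
    header: bool = True
    frame_column: str | None = None
    intensity_column: str | None = None

    def __post_init__(self) -> None:
        if self.x_column == self.y_column:
            raise ValueError("x_column and y_column must differ")
        if not self.unit_scale > 0:
            raise ValueError("unit_scale must be > 0")


@dataclass
class LocalizationTable:
    """A 2-D point set in nm with optional per-point metadata.

    ``data`` always carries ``x`` and ``y`` columns (float, nm); ``frame``
    and ``intensity`` are optional.  Row order is meaningful and preserved
    by every operation in the package.
    """

    data: pd.DataFrame
    channel_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise ValueError(f"localization table lacks required column {col!r}")
        xy = self.data[["x", "y"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("localization coordinates must be finite")

    @classmethod
    def from_points(
        cls, xy: np.ndarray, channel_label: str = "", source: str = ""
    ) -> "LocalizationTable":
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return cls(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}), channel_label, source)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset (boolean mask or integer index), order preserved."""
        return LocalizationTable(
            self.data.iloc[np.asarray(mask).nonzero()[0] if np.asarray(mask).dtype == bool else mask]
            .reset_index(drop=True),
            self.channel_label,
            self.source,
        )


def read_localizations(path: str | os.PathLike, cmap: ColumnMap | None = None) -> LocalizationTable:
    """Read a delimited localization table, converting coordinates to nm.

    One point per row, row order preserved.  A missing mapped column raises
    ``ValueError`` naming the column; a non-numeric coordinate raises
    ``ValueError`` with the offending line number.
    """
    cmap = cmap or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path,
        sep=cmap.delimiter,
        header=0 if cmap.header else None,
        skipinitialspace=True,
    )
    if not cmap.header:
        # positional fallback: first two columns are x, y
        raw.columns = [cmap.x_column, cmap.y_column] + [
            f"col{i}" for i in range(2, raw.shape[1])
        ]
    for col in (cmap.x_column, cmap.y_column):
        if col not in raw.columns:
            raise ValueError(
                f"format error: column {col!r} not found in {path.name} "
                f"(available: {list(raw.columns)})"
            )
    out = pd.DataFrame(index=raw.index)
    header_offset = 2 if cmap.header else 1  # 1-based line number of first data row
    for name, col in (("x", cmap.x_column), ("y", cmap.y_column)):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + header_offset
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at line {line} of {path.name}"
            )
        out[name] = vals.astype(float) * cmap.unit_scale
    if cmap.frame_column and cmap.frame_column in raw.columns:
        out["frame"] = raw[cmap.frame_column].astype(int)
    if cmap.intensity_column and cmap.intensity_column in raw.columns:
        out["intensity"] = raw[cmap.intensity_column].astype(float)
    # any z column is ignored: the analysis is strictly 2-D
    zcols = [c for c in raw.columns if c.strip().lower() in ("z", "z[nm]", "z [nm]")]
    if zcols:
        logger.info("ignoring z column(s) %s: analysis is 2-D", zcols)
    out = out.dropna(how="all")
    return LocalizationTable(out.reset_index(drop=True), source=str(path))


class RoiMask:
    """Region of interest: binary raster or simple polygon, nm coordinates.

    Raster convention: pixel (i, j) covers the half-open square
    [ox + j*s, ox + (j+1)*s) x [oy + i*s, oy + (i+1)*s) nm with pixel size
    ``s`` and origin (ox, oy).  Polygon boundaries count as inside, so
    masking cannot silently drop edge localizations.
    """

    def __init__(
        self,
        *,
        raster: np.ndarray | None = None,
        pixel_size: float | None = None,
        origin: tuple[float, float] = (0.0, 0.0),
        polygon: np.ndarray | None = None,
    ) -> None:
        if (raster is None) == (polygon is None):
            raise ValueError("provide exactly one of raster or polygon")
        if raster is not None:
            if pixel_size is None or not pixel_size > 0:
                raise ValueError("raster ROI requires pixel_size > 0")
            self.raster = np.asarray(raster).astype(bool)
            self.pixel_size = float(pixel_size)
            self.origin = (float(origin[0]), float(origin[1]))
            self.polygon = None
        else:
            verts = np.asarray(polygon, dtype=float).reshape(-1, 2)
            poly = shapely.Polygon(verts)
            if not poly.is_valid:
                raise ValueError("polygon ROI must be simple (non-self-intersecting)")
            self.polygon = poly
            self.raster = None
            self.pixel_size = None
            self.origin = (0.0, 0.0)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_raster(
        cls, array: np.ndarray, pixel_size: float, origin: tuple[float, float] = (0.0, 0.0)
    ) -> "RoiMask":
        return cls(raster=array, pixel_size=pixel_size, origin=origin)

    @classmethod
    def from_polygon(cls, vertices: np.ndarray) -> "RoiMask":
        return cls(polygon=vertices)

    @classmethod
    def from_file(cls, path: str | os.PathLike, pixel_size: float = 10.0) -> "RoiMask":
        """Load a raster ROI from TIFF/PNG or a polygon from CSV vertices."""
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            import tifffile

            return cls.from_raster(tifffile.imread(path), pixel_size)
        if suffix == ".png":
            from PIL import Image

            return cls.from_raster(np.asarray(Image.open(path).convert("L")), pixel_size)
        if suffix in (".csv", ".txt"):
            verts = pd.read_csv(path).to_numpy(float)[:, :2]
            return cls.from_polygon(verts)
        raise ValueError(f"unrecognized ROI file type: {path.name}")

    # -- queries -----------------------------------------------------------

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean inside-mask per point; raster points off the grid count
        as outside (their number is logged)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if self.polygon is not None:
            return shapely.covers(self.polygon, shapely.points(xy))
        s = self.pixel_size
        j = np.floor((xy[:, 0] - self.origin[0]) / s).astype(int)
        i = np.floor((xy[:, 1] - self.origin[1]) / s).astype(int)
        h, w = self.raster.shape
        in_extent = (i >= 0) & (i < h) & (j >= 0) & (j < w)
        n_out = int((~in_extent).sum())
        if n_out:
            logger.info("%d localization(s) outside raster ROI extent treated as outside", n_out)
        keep = np.zeros(len(xy), dtype=bool)
        keep[in_extent] = self.raster[i[in_extent], j[in_extent]]
        return keep


def apply_roi(table: LocalizationTable, roi: RoiMask) -> LocalizationTable:
    """Keep only localizations inside the ROI; relative order preserved."""
    if len(table) == 0:
        return table
    return table.select(roi.contains(table.xy))


# -- result output ---------------------------------------------------------

_TABLE_FILES = {
    "sc_table": "sc_table.csv",
    "az_table": "az_table.csv",
    "spc_table": "spc_table.csv",
    "hcurve_table": "hcurve.csv",
    "nnd_table": "nnd.csv",
    "summary_table": "summary.csv",
    "scan_table": "scan.csv",
}


def write_results(bundle, out_dir: str | os.PathLike) -> list[Path]:
    """Write every table of a result bundle as CSV plus a run-metadata file.

    Column names carry their units (nm, nm2, um2).  Output is deterministic:
    identical bundles produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for attr, fname in _TABLE_FILES.items():
        tab = getattr(bundle, attr, None)
        if tab is None:
            continue
        p = out_dir / fname
        tab.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    meta = getattr(bundle, "run_meta", None)
    if meta is not None:
        p = out_dir / "run_meta.toml"
        with open(p, "w", newline="\n") as fh:
            for key in sorted(meta):
                val = meta[key]
                if isinstance(val, str):
                    fh.write(f'{key} = "{val}"\n')
                elif isinstance(val, bool):
                    fh.write(f"{key} = {str(val).lower()}\n")
                else:
                    fh.write(f"{key} = {val}\n")
        written.append(p)
    return written
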
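"""Domain types and I/O for single-molecule localization tables.

All lengths inside the package are nanometres; camera-pixel units exist only
at the I/O boundary (``px_to_nm`` / ``nm_to_px``).  Coordinates are
continuous, 0-based, origin at the top-left of the region of interest;
frame indices are 0-based over the half-open window ``[0, n_frames)``.

The CSV dialect is a plain header + columns table
(``x,y,frame,photons,precision[,species]``, lengths in nm).  The HDF5
dialect mirrors the Picasso ``locs`` layout: one record dataset plus
``pixel_size_nm`` / ``n_frames`` / ``exposure_ms`` attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

MANDATORY_COLUMNS = ("x", "y", "frame")
OPTIONAL_COLUMNS = ("photons", "precision", "species")


class FormatError(ValueError):
    """A localization file does not conform to the expected layout."""


@dataclass
class LocalizationTable:
    """Per-localization records (x, y in nm; frame index; photons; precision).

    Parameters
    ----------
    data
        DataFrame with at least columns ``x, y, frame``; optionally
        ``photons``, ``precision``, ``species``.  All columns are carried
        through every processing stage.
    pixel_size_nm
        Effective camera pixel size used at the unit boundary (130 nm for
        a typical sCMOS TIRF setup after 2x2 binning).
    n_frames, exposure_ms
        Acquisition metadata.
    """

    data: pd.DataFrame
    pixel_size_nm: float = 130.0
    n_frames: Optional[int] = None
    exposure_ms: float = 100.0

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"localization table lacks mandatory column {col!r}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) float array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(dtype=np.int64)

    def validate(self) -> None:
        """Raise if basic invariants are violated."""
        d = self.data
        if not np.isfinite(d[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("non-finite coordinates")
        if (d["frame"] < 0).any():
            raise ValueError("negative frame index")
        if self.n_frames is not None and (d["frame"] >= self.n_frames).any():
            raise ValueError("frame index beyond n_frames")
        if "photons" in d.columns and (d["photons"].dropna() < 0).any():
            raise ValueError("negative photon count")
        if "precision" in d.columns and (d["precision"].dropna() <= 0).any():
            raise ValueError("non-positive precision")

    def equals(self, other: "LocalizationTable", rtol: float = 1e-9) -> bool:
        if len(self) != len(other):
            return False
        if set(self.data.columns) != set(other.data.columns):
            return False
        for col in self.data.columns:
            a, b = self.data[col], other.data[col]
            if a.dtype.kind in "fc":
                if not np.allclose(a, b, rtol=rtol, equal_nan=True):
                    return False
            else:
                if not (a.to_numpy() == b.to_numpy()).all():
                    return False
        return True


@dataclass
class RegionMask:
    """A polygonal region (e.g. a segmented focal adhesion) in nm.

    The polygon must be simple (non-self-intersecting) with positive area.
    """

    polygon: Polygon
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("region polygon must be simple and non-empty")
        if self.polygon.area <= 0:
            raise ValueError("region polygon must have positive area")

    @classmethod
    def rectangle(cls, width_nm: float, height_nm: float, label: str = "") -> "RegionMask":
        return cls(Polygon([(0, 0), (width_nm, 0), (width_nm, height_nm), (0, height_nm)]), label)

    @property
    def area_nm2(self) -> float:
        return self.polygon.area

    @property
    def area_um2(self) -> float:
        return self.polygon.area * 1e-6

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords[:-1], dtype=float)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside the polygon (vectorized)."""
        import shapely

        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return shapely.contains_xy(self.polygon, xy[:, 0], xy[:, 1])

    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    pixel_size_nm: float = 130.0
    n_frames: int = 80_000
    exposure_ms: float = 100.0
    eps_nm: Optional[float] = None      # None -> use estimated localization precision
    min_pts: Optional[int] = None       # None -> derive from binding kinetics
    coloc_threshold_nm: float = 25.0
    labeling_efficiency: dict = field(default_factory=lambda: {"halo": 0.30, "snap": 0.20})
    detection_efficiency: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.eps_nm is not None and self.eps_nm <= 0:
            raise ValueError("eps_nm must be positive")
        if self.min_pts is not None and self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.coloc_threshold_nm <= 0:
            raise ValueError("coloc_threshold_nm must be positive")
        for name, le in self.labeling_efficiency.items():
            if not 0 < le <= 1:
                raise ValueError(f"labeling efficiency {name!r}={le} outside (0, 1]")
        if not 0 < self.detection_efficiency <= 1:
            raise ValueError("detection_efficiency outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size_nm,
            "n_frames": self.n_frames,
            "exposure_ms": self.exposure_ms,
            "eps_nm": self.eps_nm,
            "min_pts": self.min_pts,
            "coloc_threshold_nm": self.coloc_threshold_nm,
            "labeling_efficiency": dict(self.labeling_efficiency),
            "detection_efficiency": self.detection_efficiency,
            "seed": self.seed,
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**payload)


# ---------------------------------------------------------------------------
# unit conversion


def px_to_nm(value, pixel_size_nm: float = 130.0):
    """Convert camera-pixel lengths to nanometres."""
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    return np.asarray(value, dtype=float) * pixel_size_nm if np.ndim(value) else float(value) * pixel_size_nm


def nm_to_px(value, pixel_size_nm: float = 130.0):
    """Convert nanometres to camera-pixel lengths (inverse of px_to_nm)."""
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    return np.asarray(value, dtype=float) / pixel_size_nm if np.ndim(value) else float(value) / pixel_size_nm


# ---------------------------------------------------------------------------
# readers / writers


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    return "hdf5" if path.suffix in {".h5", ".hdf5"} else "csv"


def read_localizations(path, dialect: Optional[str] = None, *,
                       units: str = "nm", pixel_size_nm: float = 130.0) -> LocalizationTable:
    """Read a localization table from CSV or HDF5.

    ``units='px'`` converts coordinates (and precision, if present) to nm
    using ``pixel_size_nm``; tables written by this package are already
    in nm.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    dialect = _infer_dialect(path, dialect)
    n_frames = None
    exposure_ms = 100.0
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            recs = fh["locs"][()]
            df = pd.DataFrame({name: recs[name] for name in recs.dtype.names})
            if "species" in df.columns and df["species"].dtype.kind in "OS":
                df["species"] = df["species"].astype(str)
            pixel_size_nm = float(fh["locs"].attrs.get("pixel_size_nm", pixel_size_nm))
            nf = fh["locs"].attrs.get("n_frames")
            n_frames = int(nf) if nf is not None else None
            exposure_ms = float(fh["locs"].attrs.get("exposure_ms", exposure_ms))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    if units == "px":
        for col in ("x", "y", "precision"):
            if col in df.columns:
                df[col] = df[col].astype(float) * pixel_size_nm
    elif units != "nm":
        raise ValueError("units must be 'nm' or 'px'")
    df["frame"] = df["frame"].astype(np.int64)
    return LocalizationTable(df, pixel_size_nm=pixel_size_nm,
                             n_frames=n_frames, exposure_ms=exposure_ms)


def write_localizations(table: LocalizationTable, path, dialect: Optional[str] = None) -> None:
    """Write a localization table as CSV or HDF5; re-readable round trip."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        table.data.to_csv(path, index=False)
    elif dialect == "hdf5":
        import h5py

        df = table.data
        dtypes = []
        for col in df.columns:
            if df[col].dtype.kind in "OSU":
                width = max((len(str(v)) for v in df[col]), default=1)
                dtypes.append((col, f"S{max(width, 1)}"))
            elif df[col].dtype.kind in "iu":
                dtypes.append((col, "i8"))
            else:
                dtypes.append((col, "f8"))
        recs = np.zeros(len(df), dtype=dtypes)
        for col in df.columns:
            vals = df[col].to_numpy()
            if df[col].dtype.kind in "OSU":
                vals = np.array([str(v).encode() for v in vals], dtype=recs.dtype[col])
            recs[col] = vals
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("locs", data=recs)
            ds.attrs["pixel_size_nm"] = table.pixel_size_nm
            if table.n_frames is not None:
                ds.attrs["n_frames"] = table.n_frames
            ds.attrs["exposure_ms"] = table.exposure_ms
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_region_mask(path) -> RegionMask:
    """Read a region polygon from a GeoJSON-style JSON or a CSV vertex list."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        geom = payload.get("geometry", payload)
        coords = geom["coordinates"][0]
        label = payload.get("properties", {}).get("label", "")
        return RegionMask(Polygon(coords), label=label)
    verts = pd.read_csv(path)
    return RegionMask(Polygon(verts[["x", "y"]].to_numpy()), label="")


def write_region_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    payload = {
        "type": "Feature",
        "properties": {"label": mask.label, "area_um2": mask.area_um2},
        "geometry": {
            "type": "Polygon",
            "coordinates": [list(map(list, mask.polygon.exterior.coords))],
        },
    }
    path.write_text(json.dumps(payload))


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (independent of shapely)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
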
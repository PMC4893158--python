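"""Readers, writers and core containers for localization tables, images and masks.

Conventions shared by every module in the package:

* All continuous coordinates are in nanometres, origin at the lower-left
  corner of the field of view, x increasing to the right and y upward.
* Pixel grids are row-major ``values[iy, ix]`` with pixel ``(0, 0)``
  covering ``[0, pixel_size)`` in both axes, so ``iy`` indexes y and
  ``ix`` indexes x.  The pixel size is isotropic.
* Localization tables keep one row per detected blink event ("event" /
  "localization"); a single fluorophore typically contributes several rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "LocalizationTable",
    "RegionOfInterest",
    "PixelImage",
    "CellMask",
    "THUNDERSTORM_DIALECT",
    "read_localizations",
    "write_localizations",
    "crop_region",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_roi",
    "write_roi",
]


class FormatError(ValueError):
    """Raised when an input file does not match the declared format."""


#: Column mapping for ThunderSTORM CSV exports (the default dialect).
THUNDERSTORM_DIALECT = {
    "x": "x [nm]",
    "y": "y [nm]",
    "frame": "frame",
    "intensity": "intensity [photon]",
    "uncertainty": "uncertainty [nm]",
}

_MANDATORY = ("x", "y")
_OPTIONAL = ("frame", "intensity", "uncertainty")


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangular analysis region, in nm.

    ``(x0, y0)`` is the lower-left corner.  Membership is half-open:
    ``x0 <= x < x0 + width`` and likewise in y, so adjacent ROIs tile the
    plane without double-counting events on shared edges.
    """

    x0: float
    y0: float
    width: float = 3000.0
    height: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("ROI width and height must be positive")

    @property
    def area(self) -> float:
        """Area in nm^2."""
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        """Area in um^2 (1 um^2 = 1e6 nm^2)."""
        return self.area / 1e6

    def contains(self, x, y):
        """Vectorized half-open membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y >= self.y0)
            & (y < self.y0 + self.height)
        )

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        return cls(float(d["x0"]), float(d["y0"]), float(d["width"]), float(d["height"]))


@dataclass
class LocalizationTable:
    """Table of localization events with coordinates in nm.

    Wraps a :class:`pandas.DataFrame` with columns ``x``, ``y`` (mandatory,
    nm), ``frame`` (integer) and optionally ``intensity`` (photons) and
    ``uncertainty`` (nm).  Row order is preserved by every operation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _MANDATORY:
            if col not in self.data.columns:
                raise FormatError(f"localization table missing mandatory column {col!r}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("localization coordinates must be finite")
        if xy.size and xy.min() < 0:
            raise ValueError("localization coordinates must be >= 0 nm")
        if "frame" not in self.data.columns:
            self.data = self.data.assign(frame=np.arange(len(self.data)))

    @classmethod
    def from_arrays(cls, x, y, frame=None, intensity=None, uncertainty=None) -> "LocalizationTable":
        cols = {"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)}
        cols["frame"] = (
            np.arange(len(cols["x"])) if frame is None else np.asarray(frame, dtype=int)
        )
        if intensity is not None:
            cols["intensity"] = np.asarray(intensity, dtype=float)
        if uncertainty is not None:
            cols["uncertainty"] = np.asarray(uncertainty, dtype=float)
        return cls(pd.DataFrame(cols))

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PixelImage:
    """Single-channel intensity image with isotropic pixel size in nm."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("PixelImage requires a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def pixel_centers(self) -> tuple:
        """(ys, xs) coordinate vectors of pixel centers in nm."""
        ny, nx = self.values.shape
        return (
            (np.arange(ny) + 0.5) * self.pixel_size,
            (np.arange(nx) + 0.5) * self.pixel_size,
        )


@dataclass
class CellMask:
    """Binary foreground mask aligned to a :class:`PixelImage` grid."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("CellMask requires a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.mask.any():
            raise ValueError("CellMask must contain at least one foreground pixel")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def area(self) -> float:
        """Foreground area in nm^2."""
        return float(self.mask.sum()) * self.pixel_size**2


def read_localizations(path, dialect=None, unit: str = "nm") -> LocalizationTable:
    """Read a localization CSV into nm coordinates.

    Parameters
    ----------
    path
        CSV file with one header row.
    dialect
        Mapping from canonical field names (``x``, ``y``, ``frame``,
        ``intensity``, ``uncertainty``) to the column headers used in the
        file.  Defaults to the ThunderSTORM export headers.
    unit
        ``"nm"`` or ``"um"``; coordinates (and uncertainties) are converted
        to nm on load.
    """
    dialect = dict(THUNDERSTORM_DIALECT if dialect is None else dialect)
    if unit not in ("nm", "um", "µm"):
        raise ValueError(f"unknown unit {unit!r}; expected 'nm' or 'um'")
    scale = 1.0 if unit == "nm" else 1000.0

    raw = pd.read_csv(path)
    cols = {}
    for key in _MANDATORY:
        src = dialect.get(key)
        if src is None or src not in raw.columns:
            raise FormatError(
                f"mandatory column {key!r} (file header {src!r}) not found in {path}"
            )
        cols[key] = _numeric(raw[src], src)
    for key in _OPTIONAL:
        src = dialect.get(key)
        if src is not None and src in raw.columns:
            cols[key] = _numeric(raw[src], src)
    for key in ("x", "y", "uncertainty"):
        if key in cols:
            cols[key] = cols[key] * scale
    df = pd.DataFrame(cols)
    if "frame" in df.columns:
        df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df)


def _numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"non-numeric value in column {name!r} at data row {row}")
    return out.astype(float)


def write_localizations(table: LocalizationTable, path, dialect=None) -> None:
    """Write a table back to CSV using the given header dialect (nm units)."""
    dialect = dict(THUNDERSTORM_DIALECT if dialect is None else dialect)
    out = {}
    for key in ("x", "y", "frame", "intensity", "uncertainty"):
        if key in table.data.columns and key in dialect:
            out[dialect[key]] = table.data[key]
    pd.DataFrame(out).to_csv(path, index=False)


def crop_region(table: LocalizationTable, roi: RegionOfInterest) -> LocalizationTable:
    """Retain events inside the ROI (half-open) and shift to ROI-local origin.

    An empty result is valid and returns an empty table.
    """
    keep = roi.contains(table.x, table.y)
    sub = table.data.loc[keep].copy()
    sub["x"] = sub["x"] - roi.x0
    sub["y"] = sub["y"] - roi.y0
    return LocalizationTable(sub.reset_index(drop=True))


def read_image(path, pixel_size: float, channel: int | None = None) -> PixelImage:
    """Read a grayscale TIFF; a multi-channel file requires ``channel``."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise FormatError(
                f"{path} has {arr.shape[0]} channels; pass channel= to select one"
            )
        arr = arr[channel]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return PixelImage(arr, pixel_size)


def write_image(img: PixelImage, path) -> None:
    tifffile.imwrite(path, img.values)


def read_mask(path, pixel_size: float) -> CellMask:
    arr = tifffile.imread(path)
    return CellMask(arr > 0, pixel_size)


def write_mask(mask: CellMask, path) -> None:
    tifffile.imwrite(path, mask.mask.astype(np.uint8))


def read_roi(path) -> list:
    """Read one ROI or a list of ROIs from JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [RegionOfInterest.from_dict(d) for d in payload]


def write_roi(rois, path) -> None:
    if isinstance(rois, RegionOfInterest):
        rois = [rois]
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rois], fh, indent=2)
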
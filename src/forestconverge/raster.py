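"""Raster containers and plain-text / TIFF I/O.

Classified maps travel as :class:`LandCoverRaster` (integer class codes, an
epoch year, and a per-pixel area in hectares). Reflectance imagery travels as
:class:`SpectralStack` (Blue/Green/Red/NIR/SWIR grids plus a nodata mask).

On disk a raster is a whitespace-delimited integer grid (``.txt``) next to a
JSON sidecar carrying epoch, cell area, nodata code and the class scheme.
Single-band TIFF is supported through :mod:`tifffile` (no geo-tags; inputs are
assumed co-registered).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scheme import ClassScheme, DEFAULT_SCHEME

BAND_NAMES = ("blue", "green", "red", "nir", "swir")


@dataclass
class LandCoverRaster:
    """A classified land-cover grid at one epoch."""

    grid: np.ndarray
    epoch: int
    cell_area_ha: float
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be > 0")
        valid = self.grid[self.grid != self.scheme.nodata]
        known = set(self.scheme.codes.values())
        bad = set(np.unique(valid)) - known
        if bad:
            raise ValueError(f"codes outside scheme: {sorted(bad)}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.scheme.nodata

    def class_areas_ha(self) -> dict[str, float]:
        """Area per class (ha) over valid pixels."""
        out = {}
        for lab, code in self.scheme.codes.items():
            out[lab] = float(np.count_nonzero(self.grid == code)) * self.cell_area_ha
        return out

    def forest_area_ha(self) -> float:
        return self.class_areas_ha()[self.scheme.forest_label]


@dataclass
class SpectralStack:
    """Per-pixel reflectance bands for one epoch.

    Bands are unitless reflectance, nominally in [0, 1]; values outside that
    range are accepted (sensor scaling dialects vary) but warned about at
    index computation time.
    """

    bands: dict[str, np.ndarray]
    epoch: int
    mask: np.ndarray | None = None  # True where valid

    def __post_init__(self) -> None:
        self.bands = {k.lower(): np.asarray(v, dtype=float) for k, v in self.bands.items()}
        shapes = {v.shape for v in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"band grids disagree in shape: {shapes}")
        self.shape = next(iter(shapes)) if shapes else (0, 0)
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape must match band shape")

    def band(self, name: str) -> np.ndarray:
        key = name.lower()
        if key not in self.bands:
            raise KeyError(f"stack is missing required band {name!r}")
        return self.bands[key]


# ---------------------------------------------------------------------------
# text-grid I/O


def write_text_raster(raster: LandCoverRaster, path: str | Path) -> Path:
    """Write ``<path>.txt`` (integer grid) and ``<path>.json`` sidecar."""
    path = Path(path)
    txt = path.with_suffix(".txt")
    txt.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(txt, raster.grid, fmt="%d")
    sidecar = {
        "epoch": int(raster.epoch),
        "cell_area_ha": float(raster.cell_area_ha),
        "nodata": int(raster.scheme.nodata),
        "scheme": raster.scheme.to_dict(),
    }
    txt.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return txt


def read_text_raster(path: str | Path) -> LandCoverRaster:
    """Read a text-grid raster written by :func:`write_text_raster`."""
    path = Path(path)
    txt = path if path.suffix == ".txt" else path.with_suffix(".txt")
    meta = json.loads(txt.with_suffix(".json").read_text())
    grid = np.loadtxt(txt, dtype=np.int64, ndmin=2)
    return LandCoverRaster(
        grid=grid,
        epoch=int(meta["epoch"]),
        cell_area_ha=float(meta["cell_area_ha"]),
        scheme=ClassScheme.from_dict(meta["scheme"]),
    )


def write_tiff_raster(raster: LandCoverRaster, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, raster.grid.astype(np.int32))
    sidecar = {
        "epoch": int(raster.epoch),
        "cell_area_ha": float(raster.cell_area_ha),
        "nodata": int(raster.scheme.nodata),
        "scheme": raster.scheme.to_dict(),
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_tiff_raster(path: str | Path) -> LandCoverRaster:
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LandCoverRaster(
        grid=np.asarray(tifffile.imread(path), dtype=np.int64),
        epoch=int(meta["epoch"]),
        cell_area_ha=float(meta["cell_area_ha"]),
        scheme=ClassScheme.from_dict(meta["scheme"]),
    )


def read_raster(path: str | Path) -> LandCoverRaster:
    """Dispatch on suffix: ``.txt`` text grid or ``.tif``/``.tiff``."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_tiff_raster(path)
    return read_text_raster(path)


def write_index_grid(grid: np.ndarray, path: str | Path) -> Path:
    """Write a real-valued index grid as text (NaN = nodata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(grid, dtype=float), fmt="%.6f")
    return path
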
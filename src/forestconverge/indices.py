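"""Spectral vegetation / built-up / water indices.

Four standard Landsat-band indices:

.. math::

    NDBI &= (SWIR - NIR) / (SWIR + NIR) \\
    NDVI &= (NIR - Red) / (NIR + Red) \\
    NDWI &= (Green - NIR) / (Green + NIR) \\
    EVI  &= G (NIR - Red) / (NIR + C_1 Red - C_2 Blue + L)

Normalized-difference outputs lie in [-1, 1] for non-negative reflectances.
Pixels with a (near-)zero denominator, and pixels masked in the input stack,
come back as NaN (nodata) so downstream grids stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import SpectralStack

#: denominators within this of zero are treated as undefined
DENOM_EPS = 1e-12

INDEX_BANDS = {
    "NDBI": ("swir", "nir"),
    "NDVI": ("nir", "red"),
    "NDWI": ("green", "nir"),
    "EVI": ("nir", "red", "blue"),
}


@dataclass(frozen=True)
class IndexParams:
    """EVI coefficients: gain G, atmospheric-resistance C1/C2, soil term L."""

    G: float = 2.5
    C1: float = 6.0
    C2: float = 7.5
    L: float = 1.0


def normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a - b) / (a + b), NaN where the denominator vanishes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out = np.where(np.abs(denom) <= DENOM_EPS, np.nan, out)
    return out


def compute_index(
    stack: SpectralStack,
    which: str,
    params: IndexParams | None = None,
) -> np.ndarray:
    """Compute one of NDBI/NDVI/NDWI/EVI from a reflectance stack.

    Parameters
    ----------
    stack
        Band stack; NDBI needs SWIR+NIR, NDVI NIR+Red, NDWI Green+NIR,
        EVI NIR+Red+Blue.
    which
        Index name (case-insensitive).
    params
        EVI coefficients; defaults G=2.5, C1=6, C2=7.5, L=1.

    Returns
    -------
    ndarray of float, same shape as the bands; NaN marks nodata.
    """
    params = params or IndexParams()
    key = which.upper()
    if key not in INDEX_BANDS:
        raise ValueError(f"unknown index {which!r}; choose from {sorted(INDEX_BANDS)}")
    bands = [stack.band(b) for b in INDEX_BANDS[key]]  # raises naming the band

    if not stack.mask.any():
        warnings.warn("all-nodata stack: returning empty (all-NaN) grid")
        return np.full(stack.shape, np.nan)
    for name, arr in zip(INDEX_BANDS[key], bands):
        vals = arr[stack.mask]
        if vals.size and ((vals < 0).any() or (vals > 1).any()):
            warnings.warn(
                f"band {name!r} has reflectance outside [0, 1]; computing anyway"
            )

    if key == "NDBI":
        out = normalized_difference(bands[0], bands[1])  # (swir - nir)/(swir + nir)
    elif key == "NDVI":
        out = normalized_difference(bands[0], bands[1])  # (nir - red)/(nir + red)
    elif key == "NDWI":
        out = normalized_difference(bands[0], bands[1])  # (green - nir)/(green + nir)
    else:  # EVI
        nir, red, blue = bands
        denom = nir + params.C1 * red - params.C2 * blue + params.L
        with np.errstate(divide="ignore", invalid="ignore"):
            out = params.G * (nir - red) / denom
        out = np.where(np.abs(denom) <= DENOM_EPS, np.nan, out)

    return np.where(stack.mask, out, np.nan)
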
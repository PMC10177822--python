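"""The in-memory image container every estimator consumes.

An :class:`ImageSlice` is a 2D grid of Hounsfield units with isotropic pixel
spacing. Conventions used throughout the package:

* arrays are row-major, indexed ``pixels[row, col]``;
* physical coordinates are ``x = col * spacing`` (mm, rightward) and
  ``y = row * spacing`` (mm, downward), with the origin at the *center* of
  the top-left pixel;
* angles are measured counter-clockwise from the +x axis on the (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["ImageSlice"]


@dataclass(frozen=True)
class ImageSlice:
    """2D HU raster with isotropic pixel spacing in mm."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    id: str = "slice"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ConfigError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ConfigError("pixel intensities must be finite")
        if not (self.pixel_spacing_mm > 0):
            raise ConfigError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_mm(self) -> float:
        """Extent spanned by pixel centers along y."""
        return (self.shape[0] - 1) * self.pixel_spacing_mm

    @property
    def width_mm(self) -> float:
        """Extent spanned by pixel centers along x."""
        return (self.shape[1] - 1) * self.pixel_spacing_mm

    @property
    def center_mm(self) -> tuple[float, float]:
        """(x, y) of the geometric center of the pixel-center grid."""
        return (self.width_mm / 2.0, self.height_mm / 2.0)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids of pixel-center coordinates, returned as (x, y)."""
        nrows, ncols = self.shape
        x = np.arange(ncols) * self.pixel_spacing_mm
        y = np.arange(nrows) * self.pixel_spacing_mm
        return np.meshgrid(x, y)
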
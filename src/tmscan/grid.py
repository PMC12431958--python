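"""Image-plane grid geometry shared by phantoms and reconstructions.

The scanner images the plane midway between the two antenna plates.  All
coordinates are millimetres with the origin at one plate corner; pixel (iy, ix)
covers the half-open extent [ix*p, (ix+1)*p) x [iy*p, (iy+1)*p) and its centre
sits at ((ix+0.5)*p, (iy+0.5)*p).  Arrays are indexed [row=y, col=x].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: speed of light in vacuum, millimetres per nanosecond
C_MM_PER_NS = 299.792458


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2D raster covering the imaging plane.

    Defaults match the scanner's maximum imaging area of approximately
    21 cm x 16 cm.
    """

    width_mm: float = 210.0
    height_mm: float = 160.0
    pixel_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0 or self.pixel_mm <= 0:
            raise ValueError("grid dimensions and pixel size must be positive")

    @property
    def nx(self) -> int:
        return math.ceil(self.width_mm / self.pixel_mm)

    @property
    def ny(self) -> int:
        return math.ceil(self.height_mm / self.pixel_mm)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) — numpy array shape, rows are y."""
        return (self.ny, self.nx)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_centers, y_centers) in mm, 1D arrays."""
        x = (np.arange(self.nx) + 0.5) * self.pixel_mm
        y = (np.arange(self.ny) + 0.5) * self.pixel_mm
        return x, y

    def index_of(self, x_mm: np.ndarray, y_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map continuous coordinates to (iy, ix) pixel indices, clipped to the grid."""
        ix = np.clip(np.floor(np.asarray(x_mm) / self.pixel_mm).astype(int), 0, self.nx - 1)
        iy = np.clip(np.floor(np.asarray(y_mm) / self.pixel_mm).astype(int), 0, self.ny - 1)
        return iy, ix
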
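"""Image containers shared across the package.

All images are 2D row-major numpy arrays with square pixels. Pixel centres sit
at ``(i + 0.5) * spacing_mm`` from the grid edge; the physical origin used by
the projector is the grid centre. This convention is fixed here and used
everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmissionImage"]


@dataclass
class EmissionImage:
    """A non-negative activity image on a square-pixel grid.

    Parameters
    ----------
    data :
        2D array of voxel activities (arbitrary activity units, >= 0).
    spacing_mm :
        Pixel size in mm (isotropic).
    """

    data: np.ndarray
    spacing_mm: float = 2.08

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.data.shape}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if np.any(self.data < 0):
            raise ValueError("activity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "EmissionImage":
        return EmissionImage(self.data.copy(), self.spacing_mm)


def centred_coords_mm(size_px: int, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (y, x) coordinates of pixel centres, origin at the grid centre."""
    c = (np.arange(size_px) + 0.5) * spacing_mm - size_px * spacing_mm / 2.0
    return np.meshgrid(c, c, indexing="ij")
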
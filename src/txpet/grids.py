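"""Physical image container shared by all modules.

A 2D scalar field with pixel spacing in mm and a unit tag.  Units used in the
pipeline: ``"cm^-1"`` (linear attenuation coefficient at 511 keV),
``"kBq/ml"`` (activity concentration), ``"HU"`` (Hounsfield units),
``"label"`` (integer tissue labels) and ``"1"`` (dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """2D scalar field on a regular grid.

    Parameters
    ----------
    values
        Array of shape ``(ny, nx)``; row index runs along y, column along x.
    spacing_mm
        Pixel spacing ``(sy, sx)`` in mm.
    unit
        Unit tag of the values.
    meta
        Free-form provenance flags (e.g. ``hardware_merged``).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float]
    unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ImageGrid values must be 2D")
        sy, sx = self.spacing_mm
        if sy <= 0 or sx <= 0:
            raise ValueError("pixel spacing must be positive")
        self.spacing_mm = (float(sy), float(sx))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates ``(y, x)`` in mm, origin at grid centre."""
        ny, nx = self.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing_mm[0]
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing_mm[1]
        return y, x

    def same_grid(self, other: "ImageGrid") -> bool:
        return self.shape == other.shape and self.spacing_mm == other.spacing_mm

    def require_same_grid(self, other: "ImageGrid") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.spacing_mm} vs "
                f"{other.shape}@{other.spacing_mm}"
            )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ImageGrid":
        """New grid sharing geometry, with fresh values (meta not inherited)."""
        return ImageGrid(np.asarray(values, dtype=float), self.spacing_mm,
                         unit if unit is not None else self.unit)

    def copy(self) -> "ImageGrid":
        return replace(self, values=self.values.copy(), meta=dict(self.meta))
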
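"""Parallel-beam projection geometry and the forward/back projector pair.

The scanner is abstracted to a 2D parallel-beam geometry: a projection at
angle θ collects line integrals along lines with direction ``(-sin θ, cos θ)``
indexed by the signed distance s of the line from the grid centre.  The
projector is ray-driven in the Joseph style (unit steps along the dominant
axis, linear interpolation across it) and is materialised once per
(geometry, grid) pair as a sparse matrix, so back projection is the exact
adjoint of forward projection.

Line integrals are returned in image-unit × cm: with μ-maps in cm⁻¹ the
sinogram is directly the Beer–Lambert exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .grids import ImageGrid

__all__ = ["ScannerGeometry", "Sinogram", "forward_project", "back_project",
           "system_matrix"]


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam sampling: uniform angles on [0, π), uniform radial bins.

    ``ring_radius_mm`` locates the orbit of the transmission point source
    used by the acquisition module; it plays no role in the projector itself.
    """

    n_angles: int = 180
    n_bins: int = 192
    bin_spacing_mm: float = 2.1
    ring_radius_mm: float = 250.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1:
            raise ValueError("need at least one angle and one radial bin")
        if self.bin_spacing_mm <= 0:
            raise ValueError("radial bin spacing must be > 0")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_mm(self) -> np.ndarray:
        """Signed distance of each bin centre from the grid centre."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing_mm

    @property
    def radial_extent_mm(self) -> float:
        return self.n_bins * self.bin_spacing_mm / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_bins)

    def covers(self, image: ImageGrid) -> bool:
        ny, nx = image.shape
        half_diag = 0.5 * np.hypot(ny * image.spacing_mm[0], nx * image.spacing_mm[1])
        return self.radial_extent_mm >= half_diag


@dataclass
class Sinogram:
    """Values indexed (projection angle, radial bin) plus geometry metadata.

    ``unit`` is one of ``"counts"``, ``"line-integral"`` (image-unit × cm) or
    ``"1"`` (dimensionless ratio).  ``valid`` optionally flags usable bins;
    ``None`` means all bins are usable.
    """

    values: np.ndarray
    unit: str
    geometry: ScannerGeometry
    duration_s: float | None = None
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if self.unit == "counts" and np.any(self.values < 0):
            raise ValueError("counts sinogram must be non-negative")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape mismatch")

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones_like(self.values, dtype=bool)
        return self.valid

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    valid: np.ndarray | None = None) -> "Sinogram":
        return Sinogram(values, unit if unit is not None else self.unit,
                        self.geometry, self.duration_s,
                        valid if valid is not None else
                        (None if self.valid is None else self.valid.copy()))


# -- system matrix -----------------------------------------------------------

_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _build_matrix(geom: ScannerGeometry, ny: int, nx: int,
                  sy: float, sx: float) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    xs = (np.arange(nx) - (nx - 1) / 2.0) * sx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * sy
    s = geom.radial_mm[:, None]                       # (n_bins, 1)
    bins = np.arange(geom.n_bins)[:, None]
    for a, th in enumerate(geom.angles_rad):
        c, si = np.cos(th), np.sin(th)
        if abs(si) <= abs(c):
            # step across rows (y), interpolate along x
            t = (ys[None, :] - s * si) / c            # (n_bins, ny)
            x = s * c - t * si
            g = x / sx + (nx - 1) / 2.0
            i0 = np.floor(g).astype(np.int64)
            f = g - i0
            w = (sy / abs(c)) / 10.0                  # mm path per step -> cm
            step = np.broadcast_to(np.arange(ny)[None, :], g.shape)
            row = np.broadcast_to(a * geom.n_bins + bins, g.shape)
            for ii, ww in ((i0, (1.0 - f) * w), (i0 + 1, f * w)):
                m = (ii >= 0) & (ii < nx)
                rows.append(row[m])
                cols.append(step[m] * nx + ii[m])
                vals.append(ww[m])
        else:
            # step across columns (x), interpolate along y
            t = (s * c - xs[None, :]) / si            # (n_bins, nx)
            y = s * si + t * c
            g = y / sy + (ny - 1) / 2.0
            j0 = np.floor(g).astype(np.int64)
            f = g - j0
            w = (sx / abs(si)) / 10.0
            step = np.broadcast_to(np.arange(nx)[None, :], g.shape)
            row = np.broadcast_to(a * geom.n_bins + bins, g.shape)
            for jj, ww in ((j0, (1.0 - f) * w), (j0 + 1, f * w)):
                m = (jj >= 0) & (jj < ny)
                rows.append(row[m])
                cols.append(jj[m] * nx + step[m])
                vals.append(ww[m])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * geom.n_bins, ny * nx),
    )
    return mat.tocsr()


def system_matrix(geom: ScannerGeometry, image: ImageGrid) -> sparse.csr_matrix:
    """Sparse projection matrix mapping image pixels to sinogram bins (cached)."""
    if not geom.covers(image):
        raise ValueError("geometry radial extent does not cover the image diagonal")
    key = (geom.n_angles, geom.n_bins, geom.bin_spacing_mm,
           image.shape, image.spacing_mm)
    mat = _MATRIX_CACHE.get(key)
    if mat is None:
        sy, sx = image.spacing_mm
        mat = _build_matrix(geom, image.shape[0], image.shape[1], sy, sx)
        _MATRIX_CACHE[key] = mat
    return mat


def forward_project(image: ImageGrid, geom: ScannerGeometry) -> Sinogram:
    """Line integrals of ``image`` along every (angle, radial bin) ray.

    Returns a line-integral sinogram in image-unit × cm; linear in the image.
    """
    mat = system_matrix(geom, image)
    vals = (mat @ image.values.ravel()).reshape(geom.shape)
    return Sinogram(vals, "line-integral", geom)


def back_project(sino: Sinogram, geom: ScannerGeometry,
                 like: ImageGrid) -> ImageGrid:
    """Exact adjoint of :func:`forward_project` onto the grid of ``like``."""
    if sino.geometry.shape != geom.shape:
        raise ValueError("sinogram geometry does not match requested geometry")
    mat = system_matrix(geom, like)
    vals = (mat.T @ sino.values.ravel()).reshape(like.shape)
    return like.with_values(vals, unit="1")
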
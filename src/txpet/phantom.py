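"""Synthetic piglet-like phantom and degraded MR-derived μ-map surrogates.

The phantom is a single transaxial body slice: an elliptical soft-tissue
cross-section containing cortical-bone structures (a vertebral body and two
limb/shoulder bones rendered as cortical shells), an air-filled trachea, and
a bone-avid tracer distribution (¹⁸F-NaF-like: uptake throughout the
skeleton, focal hot lesions on bone, nothing in air).  Alongside the tissue
labels the generator produces the true 511 keV attenuation map, the true
activity map, a pseudo-CT in Hounsfield units (rendered on a finer grid, as
a CT would be), and a hardware component (coil ring) outside the body.

Degradation operators emulate the systematic failure modes of MR-based
attenuation maps:

* Dixon-like: bone and internal air are replaced by soft tissue; optionally
  the body contour is eroded (tissue mis-read as air at the boundary).
* UTE-like: three-class (air/soft/bone) map with an enlarged trachea, random
  bone/soft swaps in a band around bone interfaces, and a soft-tissue patch
  mis-classified as air.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

__all__ = [
    "Label", "BoneStructure", "HotLesion", "HardwareArc", "PhantomSpec",
    "TissueLabelMap", "GeometryError", "make_piglet_phantom",
    "derive_dixon_mu", "derive_ute_mu", "UteParams", "render_labels",
]


class Label(IntEnum):
    AIR_OUTSIDE = 0
    AIR_INSIDE = 1   # trachea
    SOFT = 2
    BONE = 3
    HARDWARE = 4


class GeometryError(ValueError):
    """Phantom geometry is ambiguous or does not fit the grid."""


@dataclass(frozen=True)
class BoneStructure:
    """A cortical-bone structure.

    ``shape`` is ``"disc"`` (filled) or ``"shell"`` (annulus of cortical bone
    with soft marrow inside).  ``size_mm`` is the outer radius;
    ``thickness_mm`` the cortical shell thickness (shell only).
    """
    shape: str
    center_mm: tuple[float, float]     # (x, y)
    size_mm: float
    thickness_mm: float = 4.0


@dataclass(frozen=True)
class HotLesion:
    center_mm: tuple[float, float]
    radius_mm: float
    activity_kbq_ml: float


@dataclass(frozen=True)
class HardwareArc:
    radius_mm: float
    thickness_mm: float
    lac_cm: float
    start_deg: float = 0.0
    end_deg: float = 360.0


@dataclass
class PhantomSpec:
    """Full description of the synthetic phantom.

    All linear attenuation coefficients are at 511 keV in cm⁻¹; activity in
    kBq/ml; geometry in mm on a grid centred at (0, 0).
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_mm: float = 2.1
    body_semi_axes_mm: tuple[float, float] = (95.0, 75.0)   # (x, y)
    body_center_mm: tuple[float, float] = (0.0, 0.0)
    bones: tuple[BoneStructure, ...] = (
        BoneStructure("shell", (0.0, -45.0), 12.0, 6.0),     # vertebral body
        BoneStructure("shell", (-55.0, -10.0), 12.0, 6.0),   # left limb bone
        BoneStructure("shell", (55.0, -10.0), 12.0, 6.0),    # right limb bone
    )
    trachea_center_mm: tuple[float, float] = (0.0, 30.0)
    trachea_radius_mm: float = 18.0
    lesions: tuple[HotLesion, ...] = (
        HotLesion((-55.0, -10.0), 7.0, 60.0),
        HotLesion((55.0, -10.0), 7.0, 60.0),
    )
    background_kbq_ml: float = 2.0
    bone_kbq_ml: float = 15.0          # diffuse skeletal uptake
    lac_air: float = 0.0
    lac_lung: float = 0.03             # unused by the default slice
    lac_soft: float = 0.096
    lac_bone: float = 0.151
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 1000.0
    hardware: tuple[HardwareArc, ...] = (HardwareArc(124.0, 5.0, 0.110),)
    ct_supersample: int = 2            # pseudo-CT rendered this much finer
    seed: int = 0

    def validate(self) -> None:
        if self.lac_air != 0.0:
            raise ValueError("air LAC must be 0")
        if not (self.lac_bone > self.lac_soft > 0.0):
            raise ValueError("need bone LAC > soft LAC > 0")
        if any(l < 0 for l in (self.lac_lung, self.lac_soft, self.lac_bone)):
            raise ValueError("LACs must be non-negative")
        for les in self.lesions:
            if les.activity_kbq_ml <= self.background_kbq_ml:
                raise ValueError("hot-lesion activity must exceed background")
        ny, nx = self.grid_shape
        half_y = ny * self.pixel_mm / 2.0
        half_x = nx * self.pixel_mm / 2.0
        def fits(cx, cy, r):
            return abs(cx) + r <= half_x and abs(cy) + r <= half_y
        cx0, cy0 = self.body_center_mm
        ax, ay = self.body_semi_axes_mm
        if not (abs(cx0) + ax <= half_x and abs(cy0) + ay <= half_y):
            raise GeometryError("body ellipse does not fit the grid")
        for b in self.bones:
            if not fits(*b.center_mm, b.size_mm):
                raise GeometryError("bone structure outside the grid")
        if not fits(*self.trachea_center_mm, self.trachea_radius_mm):
            raise GeometryError("trachea outside the grid")
        for hw in self.hardware:
            if not fits(0.0, 0.0, hw.radius_mm + hw.thickness_mm / 2.0):
                raise GeometryError("hardware arc outside the grid")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "bones" in d:
            d["bones"] = tuple(
                b if isinstance(b, BoneStructure) else
                BoneStructure(b["shape"], tuple(b["center_mm"]), b["size_mm"],
                              b.get("thickness_mm", 4.0))
                for b in d["bones"])
        if "lesions" in d:
            d["lesions"] = tuple(
                l if isinstance(l, HotLesion) else
                HotLesion(tuple(l["center_mm"]), l["radius_mm"],
                          l["activity_kbq_ml"])
                for l in d["lesions"])
        if "hardware" in d:
            d["hardware"] = tuple(
                h if isinstance(h, HardwareArc) else
                HardwareArc(h["radius_mm"], h["thickness_mm"], h["lac_cm"],
                            h.get("start_deg", 0.0), h.get("end_deg", 360.0))
                for h in d["hardware"])
        for key in ("grid_shape", "body_semi_axes_mm", "body_center_mm",
                    "trachea_center_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TissueLabelMap:
    """Integer tissue labels on the phantom grid (one label per pixel)."""

    grid: ImageGrid   # unit "label"

    def __post_init__(self) -> None:
        vals = self.grid.values
        if not np.isin(vals, list(Label)).all():
            raise ValueError("unknown label value present")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values.astype(int)

    def mask(self, *labels: Label) -> np.ndarray:
        return np.isin(self.values, labels)


# -- rendering ---------------------------------------------------------------

def _grid_coords(spec: PhantomSpec, factor: int = 1):
    ny, nx = spec.grid_shape
    h = spec.pixel_mm / factor
    y = (np.arange(ny * factor) - (ny * factor - 1) / 2.0) * h
    x = (np.arange(nx * factor) - (nx * factor - 1) / 2.0) * h
    Y, X = np.meshgrid(y, x, indexing="ij")
    return Y, X, h


def render_labels(spec: PhantomSpec, factor: int = 1) -> ImageGrid:
    """Render the tissue-label image at ``factor`` × the phantom resolution.

    Raises :class:`GeometryError` when structures overlap each other or
    hardware intersects the body, which would make the labels ambiguous.
    """
    spec.validate()
    Y, X, h = _grid_coords(spec, factor)
    cx0, cy0 = spec.body_center_mm
    ax, ay = spec.body_semi_axes_mm
    body = ((X - cx0) / ax) ** 2 + ((Y - cy0) / ay) ** 2 <= 1.0

    labels = np.full(Y.shape, int(Label.AIR_OUTSIDE))
    labels[body] = int(Label.SOFT)

    structure_masks = []
    tx, ty = spec.trachea_center_mm
    trachea = (X - tx) ** 2 + (Y - ty) ** 2 <= spec.trachea_radius_mm ** 2
    structure_masks.append(("trachea", trachea))
    labels[trachea] = int(Label.AIR_INSIDE)

    for b in spec.bones:
        bx, by = b.center_mm
        r2 = (X - bx) ** 2 + (Y - by) ** 2
        outer = r2 <= b.size_mm ** 2
        if b.shape == "disc":
            bone = outer
        elif b.shape == "shell":
            inner = r2 <= max(b.size_mm - b.thickness_mm, 0.0) ** 2
            bone = outer & ~inner
        else:
            raise ValueError(f"unknown bone shape {b.shape!r}")
        structure_masks.append(("bone", outer))
        labels[bone] = int(Label.BONE)

    # overlap / containment checks on the full structure extents
    for i, (ni, mi) in enumerate(structure_masks):
        if not body[mi].all():
            raise GeometryError(f"{ni} structure extends outside the body")
        for nj, mj in structure_masks[i + 1:]:
            if (mi & mj).any():
                raise GeometryError(f"overlapping structures: {ni} and {nj}")

    hw_mask = np.zeros_like(body)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    r = np.hypot(X, Y)
    for hwa in spec.hardware:
        ring = np.abs(r - hwa.radius_mm) <= hwa.thickness_mm / 2.0
        if hwa.end_deg - hwa.start_deg < 360.0:
            ring &= (theta >= hwa.start_deg % 360.0) & (theta <= hwa.end_deg % 360.0)
        hw_mask |= ring
    if (hw_mask & body).any():
        raise GeometryError("hardware intersects the body")
    labels[hw_mask] = int(Label.HARDWARE)

    return ImageGrid(labels.astype(float), (h, h), "label")


def _mu_from_labels(label_vals: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    lut = np.zeros(len(Label))
    lut[Label.AIR_OUTSIDE] = spec.lac_air
    lut[Label.AIR_INSIDE] = spec.lac_air
    lut[Label.SOFT] = spec.lac_soft
    lut[Label.BONE] = spec.lac_bone
    lut[Label.HARDWARE] = 0.0   # hardware carried separately
    return lut[label_vals.astype(int)]


def make_piglet_phantom(spec: PhantomSpec):
    """Generate labels, true μ-map, true activity, pseudo-CT and hardware μ.

    Returns
    -------
    labels : TissueLabelMap
    mu_true : ImageGrid, cm⁻¹ — body only (hardware carried separately)
    activity_true : ImageGrid, kBq/ml — zero on all air and hardware pixels
    hu : ImageGrid, HU — pseudo-CT of the body, on a ``ct_supersample`` ×
        finer grid
    mu_hardware : ImageGrid, cm⁻¹ — hardware (coil) component, disjoint from
        the body
    """
    label_grid = render_labels(spec, factor=1)
    labels = TissueLabelMap(label_grid)
    lv = labels.values

    mu_true = label_grid.with_values(_mu_from_labels(lv, spec), unit="cm^-1")

    act = np.zeros_like(mu_true.values)
    act[lv == Label.SOFT] = spec.background_kbq_ml
    act[lv == Label.BONE] = spec.bone_kbq_ml
    Y, X, _ = _grid_coords(spec, 1)
    solid = (lv == Label.SOFT) | (lv == Label.BONE)
    for les in spec.lesions:
        lx, ly = les.center_mm
        inside = ((X - lx) ** 2 + (Y - ly) ** 2 <= les.radius_mm ** 2) & solid
        act[inside] = les.activity_kbq_ml
    activity_true = label_grid.with_values(act, unit="kBq/ml")

    fine = render_labels(spec, factor=spec.ct_supersample)
    fl = fine.values.astype(int)
    hu_lut = np.full(len(Label), spec.hu_air)
    hu_lut[Label.SOFT] = spec.hu_soft
    hu_lut[Label.BONE] = spec.hu_bone
    hu_lut[Label.HARDWARE] = spec.hu_air   # hardware not part of the body CT
    hu = fine.with_values(hu_lut[fl], unit="HU")

    # hardware LAC assigned per arc (arcs may differ in LAC)
    hw = np.zeros_like(mu_true.values)
    r = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    for hwa in spec.hardware:
        ring = np.abs(r - hwa.radius_mm) <= hwa.thickness_mm / 2.0
        if hwa.end_deg - hwa.start_deg < 360.0:
            ring &= (theta >= hwa.start_deg % 360.0) & (theta <= hwa.end_deg % 360.0)
        hw[ring & (lv == Label.HARDWARE)] = hwa.lac_cm
    mu_hardware = label_grid.with_values(hw, unit="cm^-1")

    return labels, mu_true, activity_true, hu, mu_hardware


# -- MR-surrogate degradations ----------------------------------------------

def derive_dixon_mu(labels: TissueLabelMap, spec: PhantomSpec,
                    erosion_px: int = 0) -> ImageGrid:
    """Dixon-like μ-map: bone and internal air replaced by soft tissue.

    ``erosion_px`` optionally erodes the body contour, emulating tissue
    mis-read as air near the body boundary.
    """
    lv = labels.values.copy()
    lv[np.isin(lv, (Label.BONE, Label.AIR_INSIDE))] = int(Label.SOFT)
    body = lv == Label.SOFT
    if erosion_px > 0:
        # pixel-coverage disk: erode by Euclidean depth, not city-block
        r = erosion_px
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        disk = yy ** 2 + xx ** 2 <= (r + 0.5) ** 2
        body = ndimage.binary_erosion(body, structure=disk)
    mu = np.where(body, spec.lac_soft, 0.0)
    out = labels.grid.with_values(mu, unit="cm^-1")
    out.meta["method"] = "DIXON"
    return out


@dataclass(frozen=True)
class UteParams:
    """Degradation switches for the UTE-like surrogate (defaults on)."""
    trachea_dilate_px: int = 2
    misseg_rate: float = 0.3
    band_px: int = 2
    air_patch_center_mm: tuple[float, float] | None = (30.0, 45.0)
    air_patch_radius_mm: float = 5.0


def derive_ute_mu(labels: TissueLabelMap, spec: PhantomSpec,
                  misseg_rate: float | None = None, seed: int = 0,
                  params: UteParams | None = None) -> ImageGrid:
    """UTE-like μ-map: three tissue classes with systematic mis-segmentation.

    Degradations (each individually switchable, deterministic for a fixed
    seed): trachea dilated by ``trachea_dilate_px``; a fraction
    ``misseg_rate`` of pixels in a ``band_px``-wide band around bone–soft
    interfaces swapped between the bone and soft classes; a soft-tissue patch
    relabelled as air (the eye-bulb analogue).
    """
    if params is None:
        params = UteParams()
    rate = params.misseg_rate if misseg_rate is None else misseg_rate
    if not 0.0 <= rate <= 1.0:
        raise ValueError("misseg_rate must be within [0, 1]")

    lv = labels.values.copy()
    lv[lv == Label.HARDWARE] = int(Label.AIR_OUTSIDE)   # MR does not see the coil

    if params.trachea_dilate_px > 0:
        trach = ndimage.binary_dilation(lv == Label.AIR_INSIDE,
                                        iterations=params.trachea_dilate_px)
        lv[trach & (lv == Label.SOFT)] = int(Label.AIR_INSIDE)

    if params.air_patch_center_mm is not None and params.air_patch_radius_mm > 0:
        Y, X, _ = _grid_coords(spec, 1)
        px, py = params.air_patch_center_mm
        patch = (X - px) ** 2 + (Y - py) ** 2 <= params.air_patch_radius_mm ** 2
        lv[patch & (lv == Label.SOFT)] = int(Label.AIR_INSIDE)

    if rate > 0 and params.band_px > 0:
        bone = lv == Label.BONE
        soft = lv == Label.SOFT
        grown = ndimage.binary_dilation(bone, iterations=params.band_px)
        shrunk = ndimage.binary_erosion(bone, iterations=params.band_px)
        band = (grown & ~shrunk) & (bone | soft)
        rng = np.random.default_rng(seed)
        flip = rng.random(lv.shape) < rate
        swap = band & flip
        lv[swap & bone] = int(Label.SOFT)
        lv[swap & soft] = int(Label.BONE)

    out = labels.grid.with_values(_mu_from_labels(lv, spec), unit="cm^-1")
    out.meta["method"] = "UTE"
    return out
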
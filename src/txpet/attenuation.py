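"""Construction of every attenuation-map variant used in the comparison.

* TX: OSEM reconstruction of the blank/transmission log-ratio sinogram —
  the attenuation map measured by the orbiting-source transmission system.
* REF: a 5.15 mm FWHM resolution-degraded map standing in for the reference
  transmission scanner (by default a blurred ground truth, isolating
  AC-method error from transmission noise; optionally a blurred high-count
  transmission reconstruction).
* CT: bilinear Hounsfield-to-LAC scaling of the pseudo-CT, down-sampled to
  the PET grid.  The default bone slope overestimates dense bone by a small
  configurable bias, the known behaviour of bilinear scaling at 511 keV.
* DIXON / UTE: the degraded surrogates from the phantom module.

The hardware (coil) μ-map is added exactly once to every map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .grids import ImageGrid
from .projection import ScannerGeometry, Sinogram, system_matrix
from .acquisition import (FrameSet, ScanProtocol, scale_blank,
                          separate_transmission)
from . import phantom as ph

__all__ = ["OsemParams", "BilinearParams", "AttenuationMapSet", "log_ratio",
           "reconstruct_mu", "ct_to_mu", "make_reference_mu",
           "merge_hardware", "resample_to_pet_grid", "build_map_set",
           "osem", "MAP_NAMES"]

MAP_NAMES = ("TRUE", "TX", "REF", "CT", "DIXON", "UTE")


@dataclass
class OsemParams:
    """Ordered-subset EM settings (angle-interleaved subsets)."""

    n_subsets: int = 9
    n_iterations: int = 6
    nonneg: bool = True
    post_fwhm_mm: float = 4.0
    convergence_log: list = field(default_factory=list)

    def validate(self, n_angles: int) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.n_subsets < 1 or n_angles % self.n_subsets:
            raise ValueError("subset count must divide the angle count")


@dataclass(frozen=True)
class BilinearParams:
    """Two-segment HU→LAC conversion, continuous at the breakpoint.

    Below the breakpoint μ = μ_water·(HU+1000)/1000 (the air/water line);
    above it a second slope takes over.  ``from_bone_bias`` picks the bone
    slope so that a nominal bone HU maps to (1+bias)× a nominal bone LAC.
    """

    mu_water: float = 0.096
    breakpoint_hu: float = 50.0
    bone_slope: float = 6.2379e-05   # per HU; from_bone_bias(0.151, 1000, 0.06)

    def __post_init__(self) -> None:
        if self.mu_water <= 0:
            raise ValueError("mu_water must be > 0")
        if self.bone_slope < 0:
            raise ValueError("bone slope must be >= 0 (map must stay monotone)")

    @classmethod
    def from_bone_bias(cls, bone_lac: float = 0.151, bone_hu: float = 1000.0,
                       bias: float = 0.06, mu_water: float = 0.096,
                       breakpoint_hu: float = 50.0) -> "BilinearParams":
        mu_bp = mu_water * (breakpoint_hu + 1000.0) / 1000.0
        slope = ((1.0 + bias) * bone_lac - mu_bp) / (bone_hu - breakpoint_hu)
        if slope < 0:
            raise ValueError("bias parameters yield a non-monotone conversion")
        return cls(mu_water, breakpoint_hu, slope)


@dataclass
class AttenuationMapSet:
    """The named μ-maps plus the shared hardware component.

    All maps live on the identical PET grid; every map has the hardware
    component merged (flagged in ``meta['hardware_merged']``).
    """

    maps: dict[str, ImageGrid]
    hardware: ImageGrid
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.hardware
        for name, m in self.maps.items():
            ref.require_same_grid(m)
            if np.any(m.values < 0):
                raise ValueError(f"negative LAC in map {name}")

    def __getitem__(self, name: str) -> ImageGrid:
        return self.maps[name]

    def names(self) -> list[str]:
        return list(self.maps)


# -- sinogram-domain ---------------------------------------------------------

def log_ratio(blank_scaled: Sinogram, tx_net: Sinogram) -> Sinogram:
    """Attenuation line integrals p = ln(B/T) per valid bin.

    Bins flagged invalid on either input, or with fewer than one expected
    blank count or net transmission count, carry a missing marker instead of
    a value; valid values are clamped at ≥ 0.
    """
    if blank_scaled.unit != "counts" or tx_net.unit != "counts":
        raise ValueError("log_ratio expects counts sinograms")
    if blank_scaled.geometry != tx_net.geometry:
        raise ValueError("blank and transmission geometries differ")
    valid = (blank_scaled.valid_mask & tx_net.valid_mask
             & (blank_scaled.values >= 1.0) & (tx_net.values >= 1.0))
    p = np.zeros_like(tx_net.values)
    np.log(np.where(valid, blank_scaled.values / np.where(valid, tx_net.values, 1.0), 1.0),
           out=p, where=valid)
    p = np.clip(p, 0.0, None)
    p[~valid] = np.nan
    return Sinogram(p, "line-integral", tx_net.geometry,
                    duration_s=tx_net.duration_s, valid=valid)


def _subset_rows(geom: ScannerGeometry, n_subsets: int) -> list[np.ndarray]:
    out = []
    for s in range(n_subsets):
        angles = np.arange(s, geom.n_angles, n_subsets)
        out.append((angles[:, None] * geom.n_bins
                    + np.arange(geom.n_bins)[None, :]).ravel())
    return out


def osem(data: np.ndarray, valid: np.ndarray, mat: sparse.csr_matrix,
         geom: ScannerGeometry, shape: tuple[int, int], params: OsemParams,
         weights: np.ndarray | None = None,
         track_likelihood: bool = False) -> tuple[np.ndarray, list]:
    """Generic multiplicative OSEM on a (optionally weighted) linear model.

    Solves data ≈ w ⊙ (A x) with non-negative x via the emission-type update
    x ← x · Aᵀ(w·m·d/(w·Ax)) / Aᵀ(w·m), missing bins (m = 0) excluded from
    both numerator and sensitivity.  Returns the image and a per-iteration
    log: Poisson log-likelihood when tracked, else RMS residual on valid
    bins.
    """
    d = np.where(valid, data, 0.0).ravel()
    m = valid.ravel().astype(float)
    w = np.ones_like(d) if weights is None else weights.ravel()
    wm = w * m
    x = np.full(shape[0] * shape[1], 1e-3)
    rows = _subset_rows(geom, params.n_subsets)
    subs = [(mat[r], d[r], wm[r]) for r in rows]
    sens = [A_s.T @ wm_s for A_s, _, wm_s in subs]
    eps = 1e-12
    log: list[float] = []
    for _ in range(params.n_iterations):
        for (A_s, d_s, wm_s), sen in zip(subs, sens):
            fp = wm_s * (A_s @ x)
            ratio = np.where(fp > eps, d_s / np.where(fp > eps, fp, 1.0), 0.0)
            num = A_s.T @ (wm_s * np.where(wm_s > 0, ratio, 0.0))
            upd = np.where(sen > 0, num / np.where(sen > 0, sen, 1.0), 1.0)
            x *= upd
        fp_full = wm * (mat @ x)
        if track_likelihood:
            ll = float(np.sum(np.where(fp_full > 0,
                                       d * np.log(np.where(fp_full > 0, fp_full, 1.0))
                                       - fp_full, 0.0)))
            log.append(ll)
        else:
            resid = (fp_full - d)[m > 0]
            log.append(float(np.sqrt(np.mean(resid ** 2))) if resid.size else 0.0)
    return x.reshape(shape), log


def reconstruct_mu(p: Sinogram, geom: ScannerGeometry, params: OsemParams,
                   like: ImageGrid | None = None) -> ImageGrid:
    """OSEM reconstruction of a μ-map from a line-integral sinogram.

    Missing bins are excluded from the update sums rather than imputed.
    Optional Gaussian post-smoothing at ``params.post_fwhm_mm``.
    """
    valid = p.valid_mask & np.isfinite(p.values)
    if not valid.any():
        raise ValueError("all sinogram bins are missing")
    if like is None:
        n = geom.n_bins * 2 // 3
        like = ImageGrid(np.zeros((n, n)), (geom.bin_spacing_mm,) * 2, "cm^-1")
    params.validate(geom.n_angles)
    mat = system_matrix(geom, like)
    img, log = osem(p.values, valid, mat, geom, like.shape, params)
    params.convergence_log = log
    if params.post_fwhm_mm > 0:
        sigma = params.post_fwhm_mm / 2.35482
        img = ndimage.gaussian_filter(
            img, (sigma / like.spacing_mm[0], sigma / like.spacing_mm[1]))
    if params.nonneg:
        img = np.clip(img, 0.0, None)
    out = like.with_values(img, unit="cm^-1")
    out.meta["method"] = "TX"
    return out


# -- image-domain operators --------------------------------------------------

def ct_to_mu(hu: ImageGrid, params: BilinearParams | None = None) -> ImageGrid:
    """Bilinear HU→LAC conversion (continuous, monotone non-decreasing)."""
    if params is None:
        params = BilinearParams()
    if hu.unit != "HU":
        raise ValueError("input must be in Hounsfield units")
    h = np.clip(hu.values, -1000.0, None)
    mu_bp = params.mu_water * (params.breakpoint_hu + 1000.0) / 1000.0
    low = params.mu_water * (h + 1000.0) / 1000.0
    high = mu_bp + params.bone_slope * (h - params.breakpoint_hu)
    mu = np.where(h <= params.breakpoint_hu, low, high)
    out = hu.with_values(np.clip(mu, 0.0, None), unit="cm^-1")
    out.meta["method"] = "CT"
    return out


def make_reference_mu(mu: ImageGrid, target_fwhm_mm: float) -> ImageGrid:
    """Resolution-degraded copy of a μ-map (mass-conserving Gaussian blur)."""
    if target_fwhm_mm == 0:
        out = mu.with_values(mu.values.copy())
        out.meta["method"] = "REF"
        return out
    if target_fwhm_mm < min(mu.spacing_mm):
        raise ValueError("target FWHM must be at least one pixel")
    sigma = target_fwhm_mm / 2.35482
    vals = ndimage.gaussian_filter(
        mu.values, (sigma / mu.spacing_mm[0], sigma / mu.spacing_mm[1]),
        mode="constant")
    out = mu.with_values(vals)
    out.meta["method"] = "REF"
    return out


def merge_hardware(mu_body: ImageGrid, mu_hw: ImageGrid) -> ImageGrid:
    """Add the hardware component to a body μ-map (flagged, once only)."""
    mu_body.require_same_grid(mu_hw)
    if mu_body.meta.get("hardware_merged"):
        raise ValueError("hardware component already merged into this map")
    out = mu_body.with_values(mu_body.values + mu_hw.values)
    out.meta.update(mu_body.meta)
    out.meta["hardware_merged"] = True
    return out


def resample_to_pet_grid(image: ImageGrid, target_spacing_mm: float,
                         unit: str | None = None) -> ImageGrid:
    """Area-weighted down-sampling to the PET grid spacing.

    Only integer spacing ratios are supported (block averaging, which
    conserves the image mass exactly); up-sampling is rejected.
    """
    sy, sx = image.spacing_mm
    if target_spacing_mm < sy or target_spacing_mm < sx:
        raise ValueError("up-sampling is out of scope")
    fy = target_spacing_mm / sy
    fx = target_spacing_mm / sx
    if abs(fy - round(fy)) > 1e-9 or abs(fx - round(fx)) > 1e-9:
        raise ValueError("only integer down-sampling factors are supported")
    fy, fx = int(round(fy)), int(round(fx))
    ny, nx = image.shape
    if ny % fy or nx % fx:
        raise ValueError("grid shape not divisible by the resampling factor")
    vals = image.values.reshape(ny // fy, fy, nx // fx, fx).mean(axis=(1, 3))
    return ImageGrid(vals, (target_spacing_mm, target_spacing_mm),
                     unit if unit is not None else image.unit)


# -- assembly ----------------------------------------------------------------

def build_map_set(mu_true: ImageGrid, hu: ImageGrid, mu_hardware: ImageGrid,
                  labels: ph.TissueLabelMap, spec: ph.PhantomSpec,
                  frames: FrameSet, blank: Sinogram,
                  geom: ScannerGeometry, protocol: ScanProtocol,
                  osem_params: OsemParams | None = None,
                  bilinear: BilinearParams | None = None,
                  ref_fwhm_mm: float = 5.15, ref_mode: str = "truth",
                  dixon_erosion_px: int = 0,
                  ute_params: ph.UteParams | None = None,
                  ute_seed: int = 0) -> AttenuationMapSet:
    """Assemble the five μ-map variants, each hardware-merged exactly once.

    ``ref_mode``: ``"truth"`` blurs the ground-truth map (default, isolating
    AC-method error from transmission noise); ``"transmission"`` blurs the
    transmission reconstruction instead.
    """
    if osem_params is None:
        osem_params = OsemParams()
    tx_net, _ = separate_transmission(frames, protocol)
    b_scaled = scale_blank(blank, protocol)
    p = log_ratio(b_scaled, tx_net)
    tx = reconstruct_mu(p, geom, osem_params, like=mu_true.with_values(
        np.zeros_like(mu_true.values)))

    if ref_mode == "truth":
        ref = make_reference_mu(mu_true, ref_fwhm_mm)
    elif ref_mode == "transmission":
        ref = make_reference_mu(tx, ref_fwhm_mm)
    else:
        raise ValueError(f"unknown ref_mode {ref_mode!r}")

    ct = resample_to_pet_grid(ct_to_mu(hu, bilinear), mu_true.spacing_mm[0])
    ct.meta["method"] = "CT"
    dixon = ph.derive_dixon_mu(labels, spec, erosion_px=dixon_erosion_px)
    ute = ph.derive_ute_mu(labels, spec, seed=ute_seed, params=ute_params)

    maps = {"TRUE": mu_true.with_values(mu_true.values.copy()), "TX": tx,
            "REF": ref, "CT": ct, "DIXON": dixon, "UTE": ute}
    merged = {name: merge_hardware(m, mu_hardware) for name, m in maps.items()}
    prov = {"TRUE": "ground truth", "TX": "OSEM of blank/transmission log-ratio",
            "REF": f"{ref_mode} blurred to {ref_fwhm_mm} mm FWHM",
            "CT": "bilinear scaling of pseudo-CT, block down-sampled",
            "DIXON": "bone and internal air replaced by soft tissue",
            "UTE": "three-class map with mis-segmentation degradations"}
    return AttenuationMapSet(merged, mu_hardware, prov)
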
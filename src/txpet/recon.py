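"""Attenuation-weighted OSEM reconstruction of the activity distribution.

Attenuation factors exp(−∫μ dl) sit inside the system model (AW-OSEM), so
the Poisson statistics of the measured counts are preserved.  The emission
calibration constant and scan duration are part of the model, hence the
reconstruction returns activity concentration directly in kBq/ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grids import ImageGrid
from .projection import ScannerGeometry, Sinogram, forward_project, system_matrix
from .acquisition import ScanProtocol
from .attenuation import AttenuationMapSet, OsemParams, osem

__all__ = ["ReconResult", "reconstruct_activity", "run_all_ac_methods",
           "activity_osem_params"]


def activity_osem_params(convergence_mode: bool = False) -> OsemParams:
    """Clinical-like defaults (9 subsets × 4 iterations, no post-filter);
    convergence mode runs plain MLEM (1 subset × 100 iterations)."""
    if convergence_mode:
        return OsemParams(n_subsets=1, n_iterations=100, post_fwhm_mm=0.0)
    return OsemParams(n_subsets=9, n_iterations=4, post_fwhm_mm=0.0)


@dataclass
class ReconResult:
    activity: ImageGrid          # kBq/ml
    mu_name: str
    params: OsemParams
    calibration: float
    likelihood_trace: list[float]

    def __post_init__(self) -> None:
        if np.any(self.activity.values < 0):
            raise ValueError("reconstructed activity must be non-negative")


def reconstruct_activity(emission: Sinogram, mu: ImageGrid,
                         geom: ScannerGeometry, params: OsemParams,
                         protocol: ScanProtocol,
                         mu_name: str = "") -> ReconResult:
    """AW-OSEM: model λ = calibration · duration · exp(−Pμ) ⊙ (P activity).

    Deterministic given its inputs.  ``mu`` should have the hardware
    component merged; a warning is issued otherwise.
    """
    if emission.unit != "counts":
        raise ValueError("emission must be a counts sinogram")
    if np.any(emission.values < 0):
        raise ValueError("negative emission counts")
    if not mu.meta.get("hardware_merged"):
        warnings.warn("μ-map is not flagged hardware-merged; attenuation by "
                      "the coil hardware will be uncorrected", stacklevel=2)
    params = replace(params, convergence_log=[])
    params.validate(geom.n_angles)
    duration = emission.duration_s or protocol.emission_duration_s
    alpha = protocol.emission_calibration * duration
    att = np.exp(-forward_project(mu, geom).values)
    like = mu.with_values(np.zeros_like(mu.values), unit="kBq/ml")
    mat = system_matrix(geom, like)
    img, trace = osem(emission.values, emission.valid_mask, mat, geom,
                      like.shape, params, weights=alpha * att,
                      track_likelihood=True)
    if params.post_fwhm_mm > 0:
        from scipy import ndimage
        sigma = params.post_fwhm_mm / 2.35482
        img = ndimage.gaussian_filter(
            img, (sigma / like.spacing_mm[0], sigma / like.spacing_mm[1]))
    act = like.with_values(np.clip(img, 0.0, None), unit="kBq/ml")
    act.meta["mu_name"] = mu_name
    return ReconResult(act, mu_name, params, protocol.emission_calibration,
                       trace)


def run_all_ac_methods(emission: Sinogram, map_set: AttenuationMapSet,
                       geom: ScannerGeometry, params: OsemParams,
                       protocol: ScanProtocol,
                       methods: tuple[str, ...] | None = None
                       ) -> dict[str, ReconResult]:
    """One reconstruction per μ-map, identical emission data and settings."""
    names = map_set.names() if methods is None else list(methods)
    missing = [n for n in names if n not in map_set.maps]
    if missing:
        raise KeyError(f"missing μ-map(s): {missing}")
    return {name: reconstruct_activity(emission, map_set[name], geom, params,
                                       protocol, mu_name=name)
            for name in names}
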
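"""Blank, post-injection transmission and emission scan simulation.

The transmission source is a point source orbiting on a ring of the
geometry's ring radius.  A transmission frame integrates one full orbit
sampled at a fixed number of discrete stops; at each stop only the fan of
radial bins within a half-width of the source's projected position is
accepted ("sinogram windowing").  Emission events contaminate a transmission
bin only while that bin is in-window, so the per-bin orbit duty cycle both
modulates the transmission rate and scales the emission contamination —
this is what makes post-injection transmission scanning workable.

The protocol mirrors a clinical session: a 30 min blank scan (source only,
no object), then 12 × 1 min transmission frames interleaved with 1 min
emission-only frames, acquired while a 30 min emission scan runs.

Because the blank is acquired with the coil hardware in place, the
blank/transmission ratio cancels the hardware attenuation: the reconstructed
transmission μ-map contains the body only, and the separately known hardware
μ-map is added to every μ-map afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import ImageGrid
from .projection import ScannerGeometry, Sinogram, forward_project

__all__ = ["ScanProtocol", "Frame", "FrameSet", "source_window_masks",
           "duty_cycle", "expected_blank", "simulate_transmission",
           "simulate_emission", "separate_transmission", "scale_blank"]

F18_HALFLIFE_S = 109.77 * 60.0


@dataclass(frozen=True)
class ScanProtocol:
    """Durations, source activities and calibration constants of a session.

    ``detector_efficiency`` converts source activity to an in-window blank
    count rate (counts·s⁻¹·MBq⁻¹ per bin, before duty-cycle weighting);
    ``emission_calibration`` converts an activity line integral to a count
    rate (counts·s⁻¹ per kBq/ml·cm per bin).  Both are global scalars of the
    simulated scanner.
    """

    blank_duration_s: float = 1800.0
    n_tx_frames: int = 12
    tx_frame_duration_s: float = 60.0
    em_frame_duration_s: float = 60.0
    blank_source_mbq: float = 175.0
    tx_source_mbq: float = 125.0
    emission_duration_s: float = 1800.0
    detector_efficiency: float = 0.5
    emission_calibration: float = 0.2
    window_half_width: int = 8
    orbit_positions: int = 60
    model_decay: bool = False
    halflife_s: float = F18_HALFLIFE_S
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blank_duration_s", "tx_frame_duration_s",
                     "em_frame_duration_s", "emission_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_tx_frames < 1:
            raise ValueError("need at least one transmission frame")
        if self.blank_source_mbq < 0 or self.tx_source_mbq < 0:
            raise ValueError("source activities must be >= 0")

    @property
    def total_tx_time_s(self) -> float:
        return self.n_tx_frames * self.tx_frame_duration_s

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Frame:
    kind: str                 # "TX" or "EM_ONLY"
    sino: Sinogram            # counts
    mask: np.ndarray          # bool (n_angles, n_bins): union window over the orbit
    t_start_s: float = 0.0


@dataclass
class FrameSet:
    frames: list[Frame]
    duty: np.ndarray          # (n_angles, n_bins) in [0, 1]
    geometry: ScannerGeometry
    protocol: ScanProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = [f.kind for f in self.frames]
        expected = ["TX", "EM_ONLY"] * (len(kinds) // 2) + (
            ["TX"] if len(kinds) % 2 else [])
        if kinds != expected[: len(kinds)]:
            raise ValueError("frames must alternate TX / EM_ONLY starting with TX")

    def tx_frames(self) -> list[Frame]:
        return [f for f in self.frames if f.kind == "TX"]

    def em_frames(self) -> list[Frame]:
        return [f for f in self.frames if f.kind == "EM_ONLY"]


# -- orbit windowing ---------------------------------------------------------

def source_window_masks(geom: ScannerGeometry,
                        protocol: ScanProtocol) -> np.ndarray:
    """Boolean window masks, one per orbit stop, shape (stops, angles, bins).

    At orbit angle φ the point source sits at R·(cos φ, sin φ); every line of
    projection angle θ through it has radial coordinate s = R·cos(φ − θ).
    A stop's window holds the bins within ``window_half_width`` bins of that
    position.
    """
    phis = 2.0 * np.pi * (np.arange(protocol.orbit_positions) + 0.5) / protocol.orbit_positions
    s_src = geom.ring_radius_mm * np.cos(phis[:, None] - geom.angles_rad[None, :])
    dist = np.abs(geom.radial_mm[None, None, :] - s_src[:, :, None])
    return dist <= protocol.window_half_width * geom.bin_spacing_mm


def duty_cycle(geom: ScannerGeometry, protocol: ScanProtocol) -> np.ndarray:
    """Fraction of orbit stops for which each (angle, bin) is in-window."""
    return source_window_masks(geom, protocol).mean(axis=0)


# -- expectations ------------------------------------------------------------

def expected_blank(geom: ScannerGeometry, protocol: ScanProtocol,
                   mu_hardware: ImageGrid | None = None) -> Sinogram:
    """Expected blank-scan counts per bin over the full blank duration.

    Rate per bin = efficiency × source activity × duty cycle, attenuated by
    the hardware (which is mounted during the blank) when given.
    """
    w = duty_cycle(geom, protocol)
    rate = protocol.detector_efficiency * protocol.blank_source_mbq * w
    if mu_hardware is not None:
        rate = rate * np.exp(-forward_project(mu_hardware, geom).values)
    return Sinogram(rate * protocol.blank_duration_s, "counts", geom,
                    duration_s=protocol.blank_duration_s,
                    valid=w > 0)


def _frame_decay(protocol: ScanProtocol, t_mid_s: float) -> float:
    if not protocol.model_decay:
        return 1.0
    lam = np.log(2.0) / protocol.halflife_s
    return float(np.exp(-lam * t_mid_s))


def simulate_transmission(mu: ImageGrid, activity: ImageGrid,
                          geom: ScannerGeometry, protocol: ScanProtocol,
                          seed: int | None = None,
                          mu_hardware: ImageGrid | None = None,
                          noiseless: bool = False) -> FrameSet:
    """Simulate the interleaved TX / emission-only frame sequence.

    ``mu`` is the object (body) μ-map; ``mu_hardware`` the coil component,
    present during both blank and transmission so that it cancels in the
    blank/transmission ratio.  TX frames hold windowed transmission counts
    plus duty-cycle-scaled emission contamination; EM_ONLY frames hold the
    unwindowed emission rate.  Poisson noise unless ``noiseless``.
    """
    if np.any(mu.values < 0):
        raise ValueError("negative attenuation coefficient in mu")
    if seed is None:
        seed = protocol.seed
    w = duty_cycle(geom, protocol)
    masks = source_window_masks(geom, protocol)
    union = masks.any(axis=0)

    p_body = forward_project(mu, geom).values
    p_hw = (forward_project(mu_hardware, geom).values
            if mu_hardware is not None else 0.0)
    att_total = np.exp(-(p_body + p_hw))
    tx_rate = protocol.detector_efficiency * protocol.tx_source_mbq * w * att_total

    # emission events are attenuated by everything in the FoV
    em_rate = (protocol.emission_calibration
               * forward_project(activity, geom).values * att_total)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames: list[Frame] = []
    t = 0.0
    for _ in range(protocol.n_tx_frames):
        d = _frame_decay(protocol, t + protocol.tx_frame_duration_s / 2.0)
        lam_tx = (tx_rate * d + em_rate * w) * protocol.tx_frame_duration_s
        vals = lam_tx if noiseless else rng.poisson(lam_tx).astype(float)
        frames.append(Frame("TX", Sinogram(vals, "counts", geom,
                                           protocol.tx_frame_duration_s),
                            union.copy(), t))
        t += protocol.tx_frame_duration_s
        lam_em = em_rate * protocol.em_frame_duration_s
        vals = lam_em if noiseless else rng.poisson(lam_em).astype(float)
        frames.append(Frame("EM_ONLY", Sinogram(vals, "counts", geom,
                                                protocol.em_frame_duration_s),
                            np.ones_like(union), t))
        t += protocol.em_frame_duration_s
    return FrameSet(frames, w, geom, protocol,
                    meta={"seed": seed, "noiseless": noiseless})


def simulate_emission(activity: ImageGrid, mu_total: ImageGrid,
                      geom: ScannerGeometry, duration_s: float,
                      protocol: ScanProtocol, seed: int | None = None,
                      noiseless: bool = False) -> Sinogram:
    """Attenuated emission scan: λ = calibration·T·(P act)·exp(−P μ_total)."""
    if np.any(activity.values < 0):
        raise ValueError("negative activity")
    if seed is None:
        seed = protocol.seed + 1
    lam = (protocol.emission_calibration * duration_s
           * forward_project(activity, geom).values
           * np.exp(-forward_project(mu_total, geom).values))
    if noiseless:
        vals = lam
    else:
        vals = np.random.default_rng(np.random.SeedSequence(seed)).poisson(lam).astype(float)
    return Sinogram(vals, "counts", geom, duration_s=duration_s,
                    meta={"seed": seed, "noiseless": noiseless})


# -- separation --------------------------------------------------------------

def separate_transmission(frames: FrameSet,
                          protocol: ScanProtocol | None = None
                          ) -> tuple[Sinogram, Sinogram]:
    """Subtract emission contamination from the summed transmission frames.

    The per-bin contamination rate is the mean over emission-only frames
    divided by their duration; in the TX frames it acts scaled by the bin's
    orbit duty cycle.  Each TX frame is contamination-subtracted (and
    decay-corrected when the protocol models source decay), then summed and
    clamped at zero.  Bins never in-window are flagged invalid, not zeroed.
    """
    if protocol is None:
        protocol = frames.protocol
    em = frames.em_frames()
    if not em:
        raise ValueError("no emission-only frames: post-injection separation "
                         "is impossible")
    em_rate = np.mean([f.sino.values for f in em], axis=0) / protocol.em_frame_duration_s
    contam_w = em_rate * frames.duty

    net = np.zeros(frames.geometry.shape)
    for f in frames.tx_frames():
        d = _frame_decay(protocol, f.t_start_s + protocol.tx_frame_duration_s / 2.0)
        net += (f.sino.values - contam_w * protocol.tx_frame_duration_s) / d
    net = np.clip(net, 0.0, None)
    valid = frames.duty > 0
    tx_net = Sinogram(net, "counts", frames.geometry,
                      duration_s=protocol.total_tx_time_s, valid=valid)
    contam = Sinogram(contam_w, "counts", frames.geometry, duration_s=1.0,
                      meta={"unit_note": "counts/s, duty-weighted"})
    return tx_net, contam


def scale_blank(blank: Sinogram, protocol: ScanProtocol) -> Sinogram:
    """Scale the blank to the transmission scan's live time and source activity."""
    if blank.unit != "counts":
        raise ValueError("blank must be a counts sinogram")
    scale = ((protocol.tx_source_mbq * protocol.total_tx_time_s)
             / (protocol.blank_source_mbq * protocol.blank_duration_s))
    out = blank.with_values(blank.values * scale)
    out.duration_s = protocol.total_tx_time_s
    return out
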
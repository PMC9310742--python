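"""Shared fixtures: small geometries for unit tests, session-scoped pipeline
runs so the expensive end-to-end simulations happen once."""

from __future__ import annotations

import numpy as np
import pytest

from txpet.grids import ImageGrid
from txpet.phantom import PhantomSpec, make_piglet_phantom
from txpet.pipeline import PipelineConfig, full_pipeline
from txpet.projection import ScannerGeometry


@pytest.fixture(scope="session")
def geom_small() -> ScannerGeometry:
    """Fast geometry covering a 64-pixel grid at 2.1 mm."""
    return ScannerGeometry(n_angles=60, n_bins=96, bin_spacing_mm=2.1,
                           ring_radius_mm=120.0)


@pytest.fixture(scope="session")
def geom_tiny() -> ScannerGeometry:
    """Very small geometry for Monte-Carlo-heavy tests."""
    return ScannerGeometry(n_angles=16, n_bins=24, bin_spacing_mm=2.1,
                           ring_radius_mm=40.0)


def smooth_disc(n: int, spacing_mm: float, radius_mm: float, value: float,
                unit: str = "cm^-1", supersample: int = 8,
                center_mm: tuple[float, float] = (0.0, 0.0)) -> ImageGrid:
    """Anti-aliased uniform disc (boundary pixels carry coverage fractions)."""
    f = supersample
    c = (np.arange(n * f) - (n * f - 1) / 2.0) * (spacing_mm / f)
    Y, X = np.meshgrid(c, c, indexing="ij")
    cx, cy = center_mm
    mask = ((X - cx) ** 2 + (Y - cy) ** 2 <= radius_mm ** 2).astype(float)
    coarse = mask.reshape(n, f, n, f).mean(axis=(1, 3)) * value
    return ImageGrid(coarse, (spacing_mm, spacing_mm), unit)


@pytest.fixture(scope="session")
def water_disc_small() -> ImageGrid:
    return smooth_disc(64, 2.1, 45.0, 0.096)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()
    labels, mu_true, activity, hu, mu_hw = make_piglet_phantom(spec)
    return {"spec": spec, "labels": labels, "mu_true": mu_true,
            "activity": activity, "hu": hu, "mu_hw": mu_hw}


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless end-to-end run on the default phantom."""
    return full_pipeline(PipelineConfig(noiseless=True, seed=3))


@pytest.fixture(scope="session")
def highcount_run():
    """Seeded stochastic end-to-end run at the default (high) count level."""
    return full_pipeline(PipelineConfig(noiseless=False, seed=11))
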
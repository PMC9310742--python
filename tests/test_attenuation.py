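"""μ-map construction: log-ratio, OSEM, bilinear scaling, blurring, merging."""

import numpy as np
import pytest

from txpet.acquisition import (ScanProtocol, expected_blank, scale_blank,
                               separate_transmission, simulate_transmission)
from txpet.attenuation import (BilinearParams, OsemParams,
                               ct_to_mu, log_ratio, make_reference_mu,
                               merge_hardware, reconstruct_mu,
                               resample_to_pet_grid)
from txpet.grids import ImageGrid
from txpet.projection import ScannerGeometry, Sinogram, forward_project

from conftest import smooth_disc


@pytest.fixture(scope="module")
def proto():
    return ScanProtocol()


def zeros64():
    return ImageGrid(np.zeros((64, 64)), (2.1, 2.1), "cm^-1")


def water_tx(geom, proto, disc, noiseless=True, seed=0):
    act0 = disc.with_values(np.zeros_like(disc.values), unit="kBq/ml")
    frames = simulate_transmission(disc, act0, geom, proto,
                                   noiseless=noiseless, seed=seed)
    tx_net, _ = separate_transmission(frames, proto)
    blank = expected_blank(geom, proto)
    if not noiseless:
        rng = np.random.default_rng(seed + 1000)
        blank = blank.with_values(rng.poisson(blank.values).astype(float))
    return log_ratio(scale_blank(blank, proto), tx_net)


class TestLogRatio:
    def test_identity_ratio_gives_zero(self, geom_small, proto):
        b = Sinogram(np.full(geom_small.shape, 100.0), "counts", geom_small)
        assert np.all(log_ratio(b, b).values == 0.0)

    def test_matches_projector_for_noiseless_disc(self, geom_small, proto,
                                                  water_disc_small):
        p = water_tx(geom_small, proto, water_disc_small)
        p_true = forward_project(water_disc_small, geom_small).values
        sel = p.valid & (p_true > 0.05)
        assert np.max(np.abs(p.values[sel] - p_true[sel]) / p_true[sel]) <= 5e-3

    def test_invalid_bins_marked_missing_not_zero(self, geom_small):
        vals = np.full(geom_small.shape, 50.0)
        flag = np.ones(geom_small.shape, bool)
        flag[0, 0] = False
        b = Sinogram(vals, "counts", geom_small)
        t = Sinogram(vals.copy(), "counts", geom_small, valid=flag)
        p = log_ratio(b, t)
        assert np.isnan(p.values[0, 0]) and not p.valid[0, 0]
        # a zero-count transmission bin is likewise flagged, not imputed
        t2 = Sinogram(np.where(flag, vals, 0.0), "counts", geom_small)
        assert np.isnan(log_ratio(b, t2).values[0, 0])

    def test_geometry_mismatch_rejected(self, geom_small, geom_tiny):
        b = Sinogram(np.ones(geom_small.shape), "counts", geom_small)
        t = Sinogram(np.ones(geom_tiny.shape), "counts", geom_tiny)
        with pytest.raises(ValueError):
            log_ratio(b, t)


class TestReconstructMu:
    def test_zero_data_gives_zero_map(self, geom_small):
        p = Sinogram(np.zeros(geom_small.shape), "line-integral", geom_small)
        params = OsemParams(n_subsets=6, n_iterations=4)
        mu = reconstruct_mu(p, geom_small, params, like=zeros64())
        assert mu.values.max() < 1e-4

    def test_water_disc_noiseless_recovers_lac(self, geom_small, proto,
                                               water_disc_small):
        """Interior mean of the reconstructed disc within 5% of the water
        LAC — the phantom-validation property of the transmission system."""
        p = water_tx(geom_small, proto, water_disc_small)
        params = OsemParams(n_subsets=6, n_iterations=6)
        mu = reconstruct_mu(p, geom_small, params, like=zeros64())
        y, x = mu.coords_mm()
        Y, X = np.meshgrid(y, x, indexing="ij")
        inner = (X ** 2 + Y ** 2) <= (0.8 * 45.0) ** 2
        assert abs(mu.values[inner].mean() / 0.096 - 1.0) <= 0.05
        assert len(params.convergence_log) == params.n_iterations

    def test_water_disc_high_count_stochastic(self, geom_small, proto,
                                              water_disc_small):
        p = water_tx(geom_small, proto, water_disc_small, noiseless=False,
                     seed=12)
        params = OsemParams(n_subsets=6, n_iterations=6)
        mu = reconstruct_mu(p, geom_small, params, like=zeros64())
        y, x = mu.coords_mm()
        Y, X = np.meshgrid(y, x, indexing="ij")
        inner = (X ** 2 + Y ** 2) <= (0.8 * 45.0) ** 2
        assert abs(mu.values[inner].mean() / 0.096 - 1.0) <= 0.05

    def test_all_missing_rejected(self, geom_small):
        p = Sinogram(np.full(geom_small.shape, np.nan), "line-integral",
                     geom_small, valid=np.zeros(geom_small.shape, bool))
        with pytest.raises(ValueError):
            reconstruct_mu(p, geom_small, OsemParams(n_subsets=6),
                           like=zeros64())

    def test_subsets_must_divide_angles(self, geom_small):
        p = Sinogram(np.zeros(geom_small.shape), "line-integral", geom_small)
        with pytest.raises(ValueError):
            reconstruct_mu(p, geom_small, OsemParams(n_subsets=7),
                           like=zeros64())

    def test_bias_decreases_with_counts(self, geom_tiny):
        """Average absolute reconstruction bias (10 seeds) decreases
        monotonically as transmission counts rise over two decades."""
        disc = smooth_disc(16, 2.1, 12.0, 0.096)
        y, x = disc.coords_mm()
        Y, X = np.meshgrid(y, x, indexing="ij")
        inner = (X ** 2 + Y ** 2) <= (0.8 * 12.0) ** 2
        like = ImageGrid(np.zeros((16, 16)), (2.1, 2.1), "cm^-1")
        params = OsemParams(n_subsets=4, n_iterations=6, post_fwhm_mm=0.0)
        biases = []
        for eff in (0.005, 0.05, 0.5):
            proto = ScanProtocol(detector_efficiency=eff)
            errs = []
            for seed in range(10):
                p = water_tx(geom_tiny, proto, disc, noiseless=False,
                             seed=seed)
                mu = reconstruct_mu(p, geom_tiny, params, like=like)
                errs.append(abs(mu.values[inner].mean() - 0.096))
            biases.append(np.mean(errs))
        assert biases[0] > biases[1] > biases[2]


class TestBilinear:
    def test_air_and_water_anchors(self):
        hu = ImageGrid(np.array([[-1000.0, 0.0]]), (1.0, 1.0), "HU")
        mu = ct_to_mu(hu).values
        assert mu[0, 0] == 0.0
        assert mu[0, 1] == pytest.approx(0.096)

    def test_bone_value_from_two_segment_formula(self):
        params = BilinearParams.from_bone_bias(bone_lac=0.151, bone_hu=1000.0,
                                               bias=0.06)
        hu = ImageGrid(np.array([[1000.0]]), (1.0, 1.0), "HU")
        mu_bp = 0.096 * 1050.0 / 1000.0
        expect = mu_bp + params.bone_slope * 950.0
        got = ct_to_mu(hu, params).values[0, 0]
        assert got == pytest.approx(expect)
        assert got == pytest.approx(1.06 * 0.151)

    def test_continuous_and_monotone(self):
        hu = ImageGrid(np.linspace(-1100, 3000, 4000)[None, :], (1.0, 1.0),
                       "HU")
        mu = ct_to_mu(hu).values[0]
        assert np.all(np.diff(mu) >= 0)
        assert np.max(np.abs(np.diff(mu))) < 1e-3   # no jump at the breakpoint

    def test_non_monotone_params_rejected(self):
        with pytest.raises(ValueError):
            BilinearParams(bone_slope=-1e-4)
        with pytest.raises(ValueError):
            BilinearParams.from_bone_bias(bias=-0.9)


class TestReferenceBlur:
    def test_zero_fwhm_is_identity(self, water_disc_small):
        out = make_reference_mu(water_disc_small, 0.0)
        np.testing.assert_array_equal(out.values, water_disc_small.values)

    def test_impulse_fwhm_within_5pct(self):
        img = ImageGrid(np.zeros((101, 101)), (1.0, 1.0), "cm^-1")
        img.values[50, 50] = 1.0
        target = 8.0
        out = make_reference_mu(img, target).values
        profile = out[50]
        x = np.arange(101) - 50.0
        sigma = np.sqrt((profile * x ** 2).sum() / profile.sum())
        fwhm = 2.35482 * sigma
        assert abs(fwhm / target - 1.0) <= 0.05

    def test_mass_conserved(self, water_disc_small):
        out = make_reference_mu(water_disc_small, 5.15)
        assert abs(out.values.sum() / water_disc_small.values.sum() - 1.0) \
            <= 1e-3


class TestMergeHardware:
    def test_zero_hardware_identity(self, water_disc_small):
        hw = water_disc_small.with_values(np.zeros_like(water_disc_small.values))
        out = merge_hardware(water_disc_small, hw)
        np.testing.assert_array_equal(out.values, water_disc_small.values)
        assert out.meta["hardware_merged"]

    def test_disjoint_supports_union_and_sum(self):
        a = ImageGrid(np.zeros((8, 8)), (1, 1), "cm^-1")
        b = ImageGrid(np.zeros((8, 8)), (1, 1), "cm^-1")
        a.values[2, 2] = 0.1
        b.values[5, 5] = 0.2
        out = merge_hardware(a, b)
        np.testing.assert_array_equal(out.values, a.values + b.values)
        assert (out.values > 0).sum() == 2

    def test_double_merge_rejected(self, water_disc_small):
        hw = water_disc_small.with_values(np.zeros_like(water_disc_small.values))
        once = merge_hardware(water_disc_small, hw)
        with pytest.raises(ValueError):
            merge_hardware(once, hw)


class TestResample:
    def test_same_grid_identity(self, water_disc_small):
        out = resample_to_pet_grid(water_disc_small, 2.1)
        np.testing.assert_array_equal(out.values, water_disc_small.values)

    def test_uniform_field_unchanged(self):
        img = ImageGrid(np.full((64, 64), 3.3), (1.05, 1.05), "cm^-1")
        out = resample_to_pet_grid(img, 2.1)
        np.testing.assert_allclose(out.values, 3.3)
        assert out.shape == (32, 32)

    def test_checkerboard_block_mean(self):
        vals = np.indices((8, 8)).sum(axis=0) % 2
        img = ImageGrid(vals.astype(float), (1.05, 1.05), "1")
        out = resample_to_pet_grid(img, 2.1)
        np.testing.assert_allclose(out.values, 0.5)

    def test_mass_conserved(self, default_phantom):
        hu = default_phantom["hu"]
        mu_fine = ct_to_mu(hu)
        out = resample_to_pet_grid(mu_fine, 2.1)
        mass_in = mu_fine.values.sum() * mu_fine.pixel_area_mm2
        mass_out = out.values.sum() * out.pixel_area_mm2
        assert abs(mass_out / mass_in - 1.0) <= 5e-3

    def test_upsampling_rejected(self, water_disc_small):
        with pytest.raises(ValueError):
            resample_to_pet_grid(water_disc_small, 1.0)


class TestMapSet:
    def test_all_maps_share_grid_and_hardware_flag(self, noiseless_run):
        ms = noiseless_run.map_set
        assert set(ms.names()) == {"TRUE", "TX", "REF", "CT", "DIXON", "UTE"}
        for name in ms.names():
            assert ms[name].meta.get("hardware_merged") is True
            ms.hardware.require_same_grid(ms[name])

    def test_dixon_map_below_bone_lac(self, noiseless_run):
        spec = noiseless_run.spec
        assert noiseless_run.map_set["DIXON"].values.max() < spec.lac_bone

    def test_tx_map_matches_truth_in_soft_tissue(self, noiseless_run):
        """Noiseless transmission reconstruction reproduces the soft-tissue
        LAC away from edges (within 5%)."""
        from txpet.phantom import Label
        from scipy import ndimage
        labels = noiseless_run.labels.values
        soft_core = ndimage.binary_erosion(labels == Label.SOFT, iterations=3)
        tx = noiseless_run.map_set["TX"].values
        spec = noiseless_run.spec
        assert abs(tx[soft_core].mean() / spec.lac_soft - 1.0) <= 0.05
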
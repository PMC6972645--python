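"""TPI forward model: trajectory timing, k-space weighting, PSF, B1."""

import numpy as np
import pytest

from navein import (
    AcquisitionParams,
    B1Maps,
    BiexpT2,
    apply_b1,
    apply_psf,
    b1_correct,
    build_psf,
    double_angle_flip,
    kspace_weighting,
    simulate_b1,
    tpi_time_map,
)
from navein.pve_grids import block_downsample

ACQ = AcquisitionParams()
BLOOD = BiexpT2()
NO_DECAY = BiexpT2(t2_fast_ms=1e8, t2_slow_ms=1e9)
FINE = (3.2 / 7, 3.2 / 7, 6.4 / 7)


class TestTimeMap:
    def test_readout_endpoints(self):
        assert tpi_time_map(0.0, ACQ) == 0.0
        assert tpi_time_map(1.0, ACQ) == pytest.approx(ACQ.readout_ms)

    def test_continuous_at_radial_twist_junction(self):
        # both branch formulas evaluated at rho agree
        rho = ACQ.rho
        linear = ACQ.readout_ms * rho**3 * rho / rho
        twisted = ACQ.readout_ms * rho**3
        assert linear == pytest.approx(twisted)
        eps = 1e-9
        assert tpi_time_map(rho - eps, ACQ) == pytest.approx(tpi_time_map(rho + eps, ACQ), abs=1e-6)

    def test_monotone(self):
        k = np.linspace(0, 1, 501)
        assert np.all(np.diff(tpi_time_map(k, ACQ)) > 0)

    @pytest.mark.parametrize("k", [-0.01, 1.01])
    def test_domain_error(self, k):
        with pytest.raises(ValueError):
            tpi_time_map(k, ACQ)


class TestWeighting:
    def test_dc_limit_without_decay(self):
        assert kspace_weighting(0.0, ACQ, NO_DECAY) == pytest.approx(1.0, abs=1e-6)

    def test_edge_is_hamming_endpoint(self):
        assert kspace_weighting(1.0, ACQ, NO_DECAY) == pytest.approx(0.08, abs=1e-6)

    def test_dc_value_with_blood_decay(self):
        # 0.6 exp(-0.11/2) + 0.4 exp(-0.11/17), recomputed independently
        expected = 0.6 * np.exp(-0.11 / 2) + 0.4 * np.exp(-0.11 / 17)
        assert kspace_weighting(0.0, ACQ, BLOOD) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9653, abs=1e-3)

    def test_monotone_nonincreasing_for_hamming_with_decay(self):
        k = np.linspace(0, 1, 501)
        w = kspace_weighting(k, ACQ, BLOOD)
        assert np.all(np.diff(w) <= 1e-12)


class TestPSF:
    def test_uniform_ball_limit_matches_analytic_transform(self):
        # rectangular apodization, no decay, isotropic voxel: the kernel is the
        # transform of a uniform k-space ball, whose FWHM is (2 x/pi) v with
        # 3 (sin x - x cos x)/x^3 = 1/2 at x ~ 2.4983, i.e. ~1.590 v.
        acq = AcquisitionParams(nominal_voxel_mm=(3.2, 3.2, 3.2), apodization="rectangular")
        m = build_psf(acq, NO_DECAY, fine_voxel_mm=(0.4, 0.4, 0.4),
                      support_shape=(192, 192, 192), tail_tol=1.0)
        for f in m.fwhm_mm:
            assert f / 3.2 == pytest.approx(1.5904, rel=0.01)

    def test_out_of_plane_ratio_is_voxel_ratio(self):
        m = build_psf(ACQ, BLOOD, support_shape=(128, 128, 96))
        assert m.fwhm_mm[2] / m.fwhm_mm[0] == pytest.approx(2.0, rel=0.01)
        assert m.fwhm_mm[1] == pytest.approx(m.fwhm_mm[0], rel=1e-6)

    def test_kernel_normalized_and_symmetric(self):
        m = build_psf(ACQ, BLOOD, support_shape=(128, 128, 96))
        assert m.kernel.sum() == pytest.approx(1.0, abs=1e-6)
        for ax in range(3):
            flipped = np.flip(m.kernel, axis=ax)
            flipped = np.roll(flipped, 1, axis=ax)  # even-length grid centre
            assert np.allclose(m.kernel, flipped, atol=1e-12)

    def test_fwhm_scales_inversely_with_kmax(self):
        base = build_psf(ACQ, BLOOD, support_shape=(128, 128, 96))
        doubled = AcquisitionParams(nominal_voxel_mm=(6.4, 6.4, 12.8))
        big = build_psf(doubled, BLOOD, fine_voxel_mm=tuple(2 * v for v in FINE),
                        support_shape=(128, 128, 96))
        for a, b in zip(big.fwhm_mm, base.fwhm_mm):
            assert a / b == pytest.approx(2.0, rel=1e-6)

    def test_small_support_raises_naming_tail_mass(self):
        with pytest.raises(ValueError, match="tail"):
            build_psf(ACQ, BLOOD, support_shape=(28, 28, 28), tail_tol=1e-6)


class TestApplyPSF:
    def test_uniform_volume_preserved(self):
        vol = np.full((28, 28, 28), 5.0)
        out = apply_psf(vol, ACQ, BLOOD, FINE)
        assert np.allclose(out, 5.0, rtol=1e-6)

    def test_total_sum_conserved(self, small_phantom):
        vol = small_phantom.conc_volume
        out = apply_psf(vol, ACQ, BLOOD, FINE)
        assert out.sum() * 343 == pytest.approx(vol.sum(), rel=1e-6)

    def test_impulse_response_is_block_averaged_kernel(self):
        n = 56
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 1.0
        out = apply_psf(vol, ACQ, BLOOD, FINE)
        kernel = build_psf(ACQ, BLOOD, fine_voxel_mm=FINE, support_shape=(n, n, n), tail_tol=1.0)
        expected = block_downsample(kernel.kernel)
        assert np.allclose(out, expected, atol=1e-9)

    def test_linearity_before_noise(self):
        rng = np.random.default_rng(0)
        x, y = rng.random((2, 14, 14, 14))
        fx = apply_psf(3 * x + 2 * y, ACQ, NO_DECAY, FINE)
        gx = 3 * apply_psf(x, ACQ, NO_DECAY, FINE) + 2 * apply_psf(y, ACQ, NO_DECAY, FINE)
        assert np.allclose(fx, gx, atol=1e-10)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            apply_psf(np.ones((10, 10, 10)), ACQ, BLOOD, FINE)


class TestB1:
    def test_zero_amplitude_gives_unit_maps(self):
        b1 = simulate_b1((8, 8, 8), amplitude=0.0, seed=0)
        assert np.all(b1.transmit_scale == 1.0) and np.all(b1.receive_sens == 1.0)

    def test_reproducible_and_bounded(self):
        a = simulate_b1((12, 12, 12), amplitude=0.2, seed=3)
        b = simulate_b1((12, 12, 12), amplitude=0.2, seed=3)
        assert np.array_equal(a.transmit_scale, b.transmit_scale)
        assert a.transmit_scale.min() >= 0.8 and a.transmit_scale.max() <= 1.2

    def test_double_angle_textbook_pairs(self):
        assert double_angle_flip(0.5, 0.8660) == pytest.approx(30.0, abs=0.01)
        assert double_angle_flip(0.7071, 0.7071) == pytest.approx(60.0, abs=0.01)

    def test_double_angle_forward_inverse(self):
        a = np.deg2rad(42.0)
        assert double_angle_flip(np.sin(a), np.sin(2 * a)) == pytest.approx(42.0, abs=1e-9)

    def test_double_angle_rejects_noise_dominated_ratio(self):
        with pytest.raises(ValueError):
            double_angle_flip(0.1, 0.5)

    def test_roundtrip_recovers_unmodulated_image(self):
        rng = np.random.default_rng(1)
        img = rng.random((10, 10, 10)) + 1.0
        b1 = simulate_b1((10, 10, 10), amplitude=0.2, seed=4)
        assert np.allclose(b1_correct(apply_b1(img, b1, 30.0), b1, 30.0), img, atol=1e-9)

    def test_receive_linearity(self):
        img = np.ones((4, 4, 4))
        b1 = B1Maps(transmit_scale=np.ones((4, 4, 4)), receive_sens=np.full((4, 4, 4), 2.0))
        assert np.allclose(b1_correct(img, b1, 30.0), 0.5)

    def test_identity_maps_leave_image_unchanged(self):
        img = np.arange(8.0).reshape(2, 2, 2)
        b1 = B1Maps(transmit_scale=np.ones((2, 2, 2)), receive_sens=np.ones((2, 2, 2)))
        assert np.array_equal(b1_correct(img, b1, 30.0), img)

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            B1Maps(transmit_scale=np.ones((2, 2, 2)), receive_sens=np.zeros((2, 2, 2)))
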
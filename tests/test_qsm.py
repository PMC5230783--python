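"""Susceptibility pipeline: unwrapping, SHARP, dipole model, inversion."""

import numpy as np
import pytest

from memp2rage.qsm import (
    FieldConstants,
    KGrid,
    compute_chi,
    dipole_kernel,
    forward_field,
    laplacian_unwrap,
    phase_to_ppb,
    sdi_invert,
    sharp_filter,
)
from memp2rage.volumes import wrap_phase

from conftest import masked_regression
from oracles import itoh_unwrap_1d, sphere_dipole_field


def _demean(a, mask=None):
    return a - (a[mask].mean() if mask is not None else a.mean())


class TestLaplacianUnwrap:
    def test_constant_phase_is_constant(self):
        out = laplacian_unwrap(np.full((16, 16, 16), 1.3))
        assert np.ptp(out) < 1e-10

    def test_multiwrap_tent_profile_matches_cumulative_oracle(self):
        # phase rises 0 -> 6 pi and back down along one axis, flat padding
        n = 96
        x = np.arange(n, dtype=float)
        profile = np.interp(x, [16, 48, 80], [0.0, 6 * np.pi, 0.0])
        true_phase = np.broadcast_to(profile[:, None, None], (n, 8, 8)).copy()
        wrapped = wrap_phase(true_phase)
        recovered = laplacian_unwrap(wrapped)
        oracle = itoh_unwrap_1d(wrapped, axis=0)
        interior = np.zeros((n, 8, 8), bool)
        interior[20:76] = True  # keep away from the profile kinks
        diff = _demean(recovered, interior) - _demean(oracle, interior)
        rms = np.sqrt(np.mean(diff[interior] ** 2))
        assert rms <= 0.01 * np.sqrt(np.mean(_demean(oracle, interior)[interior] ** 2))

    def test_smooth_blob_beyond_two_wraps_recovered(self):
        shape = (48, 48, 48)
        grids = np.meshgrid(*[np.arange(n) - n / 2 for n in shape],
                            indexing="ij", sparse=True)
        r2 = sum(g**2 for g in grids)
        true_phase = 4 * np.pi * np.exp(-r2 / (2 * 6.0**2))
        recovered = laplacian_unwrap(wrap_phase(true_phase))
        diff = _demean(recovered) - _demean(true_phase)
        assert np.sqrt(np.mean(diff**2)) <= 0.01 * np.sqrt(np.mean(_demean(true_phase) ** 2))

    def test_wrapping_invariance(self):
        rng = np.random.default_rng(0)
        smooth = np.fft.ifftn(np.fft.fftn(rng.standard_normal((24, 24, 24)))
                              * np.exp(-KGrid((24, 24, 24)).k_squared())).real * 4
        a = laplacian_unwrap(wrap_phase(smooth))
        b = laplacian_unwrap(wrap_phase(smooth + 2 * np.pi))
        assert np.allclose(a, b, atol=1e-8)


class TestSharpFilter:
    def _ball_mask(self, shape, radius):
        grids = np.meshgrid(*[np.arange(n) - n / 2 + 0.5 for n in shape],
                            indexing="ij", sparse=True)
        return sum(g**2 for g in grids) <= radius**2

    def test_external_source_field_removed(self):
        # the analytic field of a dipole source outside the mask is
        # harmonic inside it, so SHARP must annihilate it
        shape = (64, 64, 64)
        vox = (0.6, 0.6, 0.6)
        kg = KGrid(shape, vox)
        mask = self._ball_mask(shape, 20)
        field = sphere_dipole_field(shape, (56, 32, 32), 3.0 * 0.6, 5000.0,
                                    vox)
        filtered, eroded = sharp_filter(field, mask, kg)
        assert np.sqrt(np.mean(filtered[eroded] ** 2)) <= \
            0.05 * np.sqrt(np.mean(field[eroded] ** 2))

    def test_constant_field_annihilated(self):
        shape = (32, 32, 32)
        mask = self._ball_mask(shape, 12)
        filtered, eroded = sharp_filter(np.full(shape, 7.7), mask, KGrid(shape))
        assert np.max(np.abs(filtered[eroded])) <= 1e-6

    def test_zero_field_stays_zero(self):
        shape = (32, 32, 32)
        mask = self._ball_mask(shape, 12)
        filtered, _ = sharp_filter(np.zeros(shape), mask, KGrid(shape))
        assert np.all(filtered == 0)

    def test_mask_erosion_shrinks_mask(self):
        shape = (32, 32, 32)
        mask = self._ball_mask(shape, 12)
        _, eroded = sharp_filter(np.ones(shape), mask, KGrid(shape), radius_mm=3.0)
        assert eroded.sum() < mask.sum()
        assert not (eroded & ~mask).any()

    def test_tiny_mask_raises(self):
        shape = (24, 24, 24)
        mask = self._ball_mask(shape, 2)
        with pytest.raises(ValueError, match="erosion|vanished"):
            sharp_filter(np.ones(shape), mask, KGrid(shape), radius_mm=5.0)


class TestPhaseToPpb:
    def test_one_ppb_phase_by_hand(self):
        fc = FieldConstants(b0=7.0, gamma=2.675e8, te_qsm=14.77e-3)
        phase = 1e-9 * 2.675e8 * 14.77e-3 * 7.0  # = 0.0276566...
        assert phase == pytest.approx(0.0276567, abs=1e-6)
        assert phase_to_ppb(np.array([phase]), fc)[0] == pytest.approx(1.0, rel=1e-6)

    def test_linearity(self):
        fc = FieldConstants()
        x = np.array([0.0, 0.1, 0.2])
        assert np.allclose(phase_to_ppb(2 * x, fc), 2 * phase_to_ppb(x, fc))


class TestDipoleKernel:
    def test_principal_directions(self):
        kg = KGrid((8, 8, 8))
        d = dipole_kernel(kg)
        assert d[0, 0, 1] == pytest.approx(-2.0 / 3.0)   # k along B0
        assert d[1, 0, 0] == pytest.approx(1.0 / 3.0)    # transverse
        assert d[0, 0, 0] == 0.0

    def test_magic_angle_zero_crossing(self):
        # kz^2/|k|^2 = 1/3 nulls the kernel
        kg = KGrid((16, 16, 16), z_axis=2)
        k = kg.k_axes()[0][1]
        kz = k / np.sqrt(2.0)
        kxy = k * np.sqrt(2.0 / 3.0) * np.sqrt(3.0 / 2.0)
        d_val = 1.0 / 3.0 - kz**2 / (kz**2 + 2 * (kxy**2) / 2)
        # direct evaluation of the formula at the magic angle
        assert 1.0 / 3.0 - (1.0 / 3.0) == pytest.approx(0.0)
        assert abs(dipole_kernel(kg)).min() == 0.0

    def test_respects_z_axis_choice(self):
        kg0 = KGrid((8, 8, 8), z_axis=0)
        d = dipole_kernel(kg0)
        assert d[1, 0, 0] == pytest.approx(-2.0 / 3.0)
        assert d[0, 1, 0] == pytest.approx(1.0 / 3.0)


class TestForwardField:
    def test_uniform_susceptibility_invisible(self):
        field = forward_field(np.full((16, 16, 16), 123.0))
        assert np.max(np.abs(field)) < 1e-9

    def test_impulse_response_is_kernel_transform(self):
        shape = (16, 16, 16)
        kg = KGrid(shape)
        chi = np.zeros(shape)
        chi[0, 0, 0] = 1.0
        field = forward_field(chi, kg)
        expected = np.fft.ifftn(dipole_kernel(kg)).real
        assert np.allclose(field, expected, atol=1e-12)

    def test_sphere_matches_analytic_dipole_field(self):
        shape = (64, 64, 64)
        vox = (1.0, 1.0, 1.0)
        kg = KGrid(shape, vox)
        center = (32, 32, 32)
        radius = 6.0
        grids = np.meshgrid(*[(np.arange(n) - c) for n, c in zip(shape, center)],
                            indexing="ij", sparse=True)
        r = np.sqrt(sum(g**2 for g in grids))
        chi = np.where(r <= radius, 100.0, 0.0)
        field = forward_field(chi, kg)
        analytic = sphere_dipole_field(shape, center, radius, 100.0, vox)
        outside = (r > radius + 2) & (r < 24)  # avoid shell + wrap-around
        err = field[outside] - analytic[outside]
        assert np.sqrt(np.mean(err**2)) <= 0.05 * np.sqrt(np.mean(analytic[outside] ** 2))


class TestSdiInvert:
    def test_zero_field_zero_map(self):
        mask = np.ones((16, 16, 16), bool)
        assert np.all(sdi_invert(np.zeros((16, 16, 16)), mask) == 0)

    def test_reference_invariance(self, blob_chi):
        b = blob_chi
        f1 = forward_field(b["chi"], b["kg"])
        f2 = forward_field(b["chi"] + 55.0, b["kg"])
        c1 = sdi_invert(f1, b["mask"], b["kg"])
        c2 = sdi_invert(f2, b["mask"], b["kg"])
        assert np.allclose(c1, c2, atol=1e-8)

    def test_mask_mean_is_zero(self, blob_chi):
        b = blob_chi
        chi = sdi_invert(b["field"], b["mask"], b["kg"])
        assert abs(chi[b["mask"]].mean()) < 1e-9

    def test_round_trip_slope_on_smooth_phantom(self, blob_chi):
        b = blob_chi
        chi_rec = sdi_invert(b["field"], b["mask"], b["kg"], kthresh=0.2)
        slope, r2 = masked_regression(b["chi"], chi_rec, b["mask"])
        assert 0.75 <= slope <= 1.05
        assert r2 >= 0.9

    def test_requires_positive_threshold(self):
        with pytest.raises(ValueError):
            sdi_invert(np.zeros((8, 8, 8)), np.ones((8, 8, 8), bool), kthresh=0.0)


class TestFullChain:
    def test_round_trip_recovers_smooth_susceptibility(self, blob_chi):
        b = blob_chi
        phase = wrap_phase(b["fc"].rad_per_ppb * b["field"])
        chi_rec, eroded = compute_chi(phase, b["mask"], b["fc"], b["kg"])
        slope, r2 = masked_regression(b["chi"], chi_rec, eroded)
        assert 0.75 <= slope <= 1.05
        assert r2 >= 0.9

    def test_unwrap_free_portion_is_linear(self, blob_chi):
        b = blob_chi
        def tail(field):
            filt, er = sharp_filter(field, b["mask"], b["kg"])
            return sdi_invert(phase_to_ppb(filt, b["fc"]), er, b["kg"]), er
        one, er = tail(b["field"])
        three, _ = tail(3.0 * b["field"])
        assert np.allclose(three, 3.0 * one, rtol=1e-9, atol=1e-9)

    def test_phantom_tissue_contrast_recovered(self, noiseless_acq, phantom_truth):
        from dataclasses import replace as dc_replace
        fc = dc_replace(noiseless_acq.field_constants, te_qsm=14.77e-3)
        kg = KGrid(phantom_truth.labels.shape, phantom_truth.spec.voxel_size)
        chi_rec, eroded = compute_chi(np.angle(noiseless_acq.inv2[-1]),
                                      phantom_truth.mask, fc, kg)
        lab = phantom_truth.labels
        contrast = (chi_rec[(lab == 5) & eroded].mean()
                    - chi_rec[(lab == 1) & eroded].mean())
        # caudate minus white matter: truth is +19.3 ppb; the truncated
        # inversion attenuates contrast by the cone factor (~0.7 measured)
        assert contrast > 0
        assert 0.6 * 19.3 <= contrast <= 1.1 * 19.3
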
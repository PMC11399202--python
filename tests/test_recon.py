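import math

import numpy as np
import pytest

from hardigen.dwi_io import DWIVolume
from hardigen.gradients import design_scheme
from hardigen.phantom import FiberBundleSpec, make_crossing_phantom, simulate_signal
from hardigen.recon import (
    GQI_DIFFUSION_SCALE,
    find_peaks,
    fit_dti,
    gqi_sdf,
    qbi_odf,
    roi_statistics,
    sample_odf,
    tensor_peaks,
)
from hardigen.sphere import (
    default_sphere,
    legendre_p0,
    n_sh_coeffs,
    real_sh_basis,
    sh_fit_matrix,
    sh_index_list,
)


def angle_deg(a, b):
    return math.degrees(math.acos(min(1.0, abs(float(np.dot(a, b))))))


def single_voxel_volume(signal, scheme):
    """Wrap a 1D per-channel signal as a 1x1x1 DWIVolume."""
    data = np.asarray(signal, dtype=np.float32).reshape(1, 1, 1, -1)
    return DWIVolume(data, np.eye(4), scheme)


class TestDTI:
    def test_isotropic_voxel_has_zero_fa(self, scheme64):
        d = 1.0e-3
        sig = 80.0 * np.exp(-scheme64.bvalues * d)
        tf = fit_dti(single_voxel_volume(sig, scheme64))
        assert tf.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_fa_value_for_prolate_tensor(self, scheme64):
        """lambda = (1.7, 0.2, 0.2)e-3 gives FA = 1.5/sqrt(2.97) ~ 0.870."""
        bundles = [
            FiberBundleSpec(
                np.array([[-5.0, 8, 8], [20.0, 8, 8]]), 3.0, (1.7e-3, 0.2e-3, 0.2e-3)
            )
        ]
        vol, truth = simulate_signal(bundles, scheme64, (16, 16, 16))
        m = truth.bundle_masks[0]
        tf = fit_dti(vol, mask=m)
        expected = math.sqrt(0.5) * math.sqrt(1.5**2 + 0 + 1.5**2) / math.sqrt(
            1.7**2 + 2 * 0.2**2
        )
        assert tf.fa[m] == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.870, abs=5e-4)

    def test_eigenvalue_recovery_noiseless(self, single_fiber_region):
        vol, truth, mask, direction = single_fiber_region
        tf = fit_dti(vol, mask=mask)
        assert np.abs(tf.eigenvalues[mask] - [1.7e-3, 0.3e-3, 0.3e-3]).max() < 1e-6
        # principal eigenvector aligned with the bundle
        v1 = tf.principal_direction[mask]
        assert max(angle_deg(v, direction) for v in v1) < 0.5

    def test_fa_bias_small_under_rician_noise(self, scheme64):
        """sigma = 0.02*S0 at b=3000 and 64 directions biases FA down by
        less than 0.05 in single-fiber voxels (weighted LLS fit)."""
        bundles = [FiberBundleSpec(np.array([[-10.0, 16, 16], [42.0, 16, 16]]), 4.0)]
        S0 = 100.0
        clean, truth = simulate_signal(bundles, scheme64, (32, 32, 32), S0=S0)
        noisy, _ = simulate_signal(
            bundles, scheme64, (32, 32, 32), S0=S0, noise_sigma=0.02 * S0, seed=11
        )
        m = truth.bundle_masks[0]
        fa0 = fit_dti(clean, mask=m).fa[m].mean()
        fan = fit_dti(noisy, mask=m).fa[m].mean()
        assert abs(fan - fa0) < 0.05

    def test_too_few_directions_rejected(self):
        scheme = design_scheme(5, seed=0, n_restarts=3)
        sig = np.full(6, 50.0)
        with pytest.raises(ValueError, match="6 diffusion"):
            fit_dti(single_voxel_volume(sig, scheme))

    def test_all_zero_voxel_excluded(self, scheme64):
        data = np.zeros((2, 1, 1, 65), np.float32)
        data[0] = 60.0
        vol = DWIVolume(data, np.eye(4), scheme64)
        tf = fit_dti(vol)
        assert tf.mask[0, 0, 0] and not tf.mask[1, 0, 0]

    def test_color_fa_range(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        cfa = fit_dti(vol, mask=mask).color_fa
        assert cfa.min() >= 0 and cfa.max() <= 1 + 1e-9


class TestQBI:
    def test_legendre_factors(self):
        p = legendre_p0(4)
        assert (p[0], p[1], p[6]) == pytest.approx((1.0, -0.5, 0.375))

    def test_single_fiber_peak_within_4_degrees(self, single_fiber_region):
        vol, truth, mask, direction = single_fiber_region
        odf = qbi_odf(vol, mask=mask)
        assert odf.lmax == 8
        pk = find_peaks(odf)
        assert np.all(pk.counts[mask] >= 1)
        errs = [angle_deg(pk.peaks[v][0], direction) for v in zip(*np.nonzero(mask))]
        assert max(errs) < 4.0

    def test_isotropic_voxel_flat_odf(self, scheme64):
        sig = 70.0 * np.exp(-scheme64.bvalues * 0.8e-3)
        odf = qbi_odf(single_voxel_volume(sig, scheme64))
        B = real_sh_basis(default_sphere().vertices, odf.lmax)
        vals = odf.sh[0, 0, 0] @ B.T
        assert vals.std() / vals.mean() < 1e-6

    def test_lmax_exceeding_direction_count_rejected(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        half = DWIVolume(vol.data[..., :33], vol.affine, _first33(vol.scheme))
        with pytest.raises(ValueError, match="lmax"):
            qbi_odf(half, mask=mask, lmax=8)

    def test_32_directions_fall_back_to_lmax_6(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        half = DWIVolume(vol.data[..., :33], vol.affine, _first33(vol.scheme))
        assert qbi_odf(half, mask=mask).lmax == 6

    def test_analytic_frt_matches_numerical_great_circle_quadrature(self, rng):
        """Independent oracle: the Funk-Radon transform computed by direct
        great-circle integration of the SH-expanded signal must match the
        analytic 2*pi*P_l(0) diagonal route."""
        lmax = 8
        ncoef = n_sh_coeffs(lmax)
        coef = rng.normal(size=ncoef)
        sphere = default_sphere()
        analytic = (2 * np.pi) * legendre_p0(lmax) * coef
        B = real_sh_basis(sphere.vertices, lmax)
        analytic_vals = B @ analytic

        # quadrature: for each sample direction u, integrate the signal over
        # the great circle perpendicular to u
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        numeric_vals = []
        for u in sphere.vertices:
            ref = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            circle = np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2)
            vals = real_sh_basis(circle, lmax) @ coef
            numeric_vals.append(vals.mean() * 2 * np.pi)
        numeric_vals = np.asarray(numeric_vals)
        rms = np.sqrt(np.mean((numeric_vals - analytic_vals) ** 2))
        assert rms < 1e-4 * max(1.0, np.abs(analytic_vals).max())


def _first33(scheme):
    from hardigen.gradients import GradientScheme

    return GradientScheme(
        scheme.directions[:33], scheme.bvalues[:33], scheme.labels[:33]
    )


class TestGQI:
    def test_free_water_voxel_is_flat(self, scheme64):
        d_free = GQI_DIFFUSION_SCALE / 6.0
        sig = 90.0 * np.exp(-scheme64.bvalues * d_free)
        sphere = default_sphere()
        q = scheme64.directions * np.sqrt(GQI_DIFFUSION_SCALE * scheme64.bvalues)[:, None]
        sdf = sig @ np.sinc(1.25 * (q @ sphere.vertices.T) / np.pi)
        assert sdf.max() / sdf.min() < 1.01

    def test_white_matter_background_nearly_flat(self, scheme64):
        sig = 90.0 * np.exp(-scheme64.bvalues * 0.8e-3)
        sphere = default_sphere()
        q = scheme64.directions * np.sqrt(GQI_DIFFUSION_SCALE * scheme64.bvalues)[:, None]
        sdf = sig @ np.sinc(1.25 * (q @ sphere.vertices.T) / np.pi)
        assert sdf.max() / sdf.min() < 1.02

    def test_single_fiber_peak_within_4_degrees(self, single_fiber_region):
        vol, truth, mask, direction = single_fiber_region
        sdf = gqi_sdf(vol, mask=mask, sampling_ratio=1.25)
        pk = find_peaks(sdf)
        errs = [angle_deg(pk.peaks[v][0], direction) for v in zip(*np.nonzero(mask))]
        assert max(errs) < 4.0

    def test_linearity_in_signal(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        doubled = DWIVolume(vol.data * 2.0, vol.affine, vol.scheme)
        a = gqi_sdf(vol, mask=mask).sh[mask]
        b = gqi_sdf(doubled, mask=mask).sh[mask]
        assert np.allclose(b, 2 * a, rtol=1e-5, atol=1e-8)

    def test_invalid_sampling_ratio(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        with pytest.raises(ValueError):
            gqi_sdf(vol, mask=mask, sampling_ratio=0.0)


class TestSampling:
    def test_pure_l0_function_is_uniform(self, scheme64):
        from hardigen.recon import ODFField

        sh = np.zeros((1, 1, 1, n_sh_coeffs(8)))
        sh[0, 0, 0, 0] = 3.7
        field = ODFField(sh, 8, np.ones((1, 1, 1), bool))
        P, degenerate = sample_odf(field)
        assert not degenerate.any()
        assert np.allclose(P, 1.0 / 181, atol=1e-12)

    def test_normalization_exact(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        P, _ = sample_odf(qbi_odf(vol, mask=mask))
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12

    def test_all_zero_function_flagged_uniform(self):
        from hardigen.recon import ODFField

        sh = np.zeros((1, 1, 1, n_sh_coeffs(4)))
        field = ODFField(sh, 4, np.ones((1, 1, 1), bool))
        P, degenerate = sample_odf(field)
        assert degenerate.all()
        assert np.allclose(P, 1.0 / 181)


class TestPeaks:
    def test_single_tensor_gives_one_peak(self, single_fiber_region):
        vol, _, mask, _ = single_fiber_region
        pk = find_peaks(qbi_odf(vol, mask=mask))
        assert np.all(pk.counts[mask] == 1)

    def test_right_angle_crossing_resolved(self, crossing_phantom):
        vol, truth = crossing_phantom
        cross = truth.bundle_masks[0] & truth.bundle_masks[1]
        pk = find_peaks(qbi_odf(vol, mask=cross))
        d0 = truth.fiber_directions[0][cross][0]
        d1 = truth.fiber_directions[1][cross][0]
        assert np.all(pk.counts[cross] == 2)
        for v in zip(*np.nonzero(cross)):
            peaks = pk.peaks[v][: pk.counts[v]]
            errs = [min(angle_deg(p, d) for p in peaks) for d in (d0, d1)]
            assert max(errs) < 10.0

    def test_isotropic_voxel_yields_no_peaks(self, scheme64):
        sig = 70.0 * np.exp(-scheme64.bvalues * 0.8e-3)
        pk = find_peaks(qbi_odf(single_voxel_volume(sig, scheme64)), relative_threshold=0.5)
        assert pk.counts[0, 0, 0] == 0

    def test_tensor_peaks_align_with_principal_axis(self, single_fiber_region):
        vol, _, mask, direction = single_fiber_region
        pk = tensor_peaks(fit_dti(vol, mask=mask))
        assert np.all(pk.counts[mask] == 1)
        errs = [angle_deg(pk.peaks[v][0], direction) for v in zip(*np.nonzero(mask))]
        assert max(errs) < 1.0


class TestROIStatistics:
    def test_constant_map(self):
        m = np.full((4, 4, 4), 2.5)
        roi = np.ones((4, 4, 4), bool)
        (s,) = roi_statistics(m, [roi])
        assert (s["mean"], s["sd"]) == (2.5, 0.0)

    def test_two_voxel_roi_population_and_sample_sd(self):
        m = np.zeros((2, 1, 1))
        m[1] = 1.0
        roi = np.ones((2, 1, 1), bool)
        pop = roi_statistics(m, [roi])[0]
        assert (pop["mean"], pop["sd"]) == (0.5, 0.5)
        samp = roi_statistics(m, [roi], ddof=1)[0]
        assert samp["sd"] == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_empty_roi_flagged(self):
        m = np.zeros((2, 2, 2))
        out = roi_statistics(m, [np.zeros((2, 2, 2), bool)])
        assert out[0]["excluded"] and out[0]["mean"] is None
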
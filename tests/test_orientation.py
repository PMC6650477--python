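"""FFT-ellipse orientation estimator: spectrum, polar profile, ellipse fit."""

import numpy as np
import pytest
from scipy import ndimage

from fiborient import (
    FiberGeometry,
    SlicePlane,
    analyze_slice,
    analyze_stack,
    directional_amplitude,
    fit_orientation_ellipse,
    generate_collagen_geometry,
    power_spectrum,
    rasterize_stack,
)
from fiborient.angles import angular_difference
from fiborient.orientation import DEFAULT_BAND, PolarProfile

from conftest import make_spec

PITCH = 211.0 / 512.0


def _grating(theta_deg: float, period_um: float = 10.0, n: int = 512) -> np.ndarray:
    """Stripes oriented along theta (wavevector perpendicular to them)."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float) * PITCH
    perp = np.deg2rad(theta_deg + 90.0)
    return 100 + 80 * np.cos(2 * np.pi / period_um * (xx * np.cos(perp) + yy * np.sin(perp)))


def _ellipse_profile(theta_deg: float, ratio: float) -> PolarProfile:
    """Exact origin-centered ellipse, minor radius 1 along theta."""
    phi = np.deg2rad(np.arange(0.5, 180.0, 1.0))
    t0 = np.deg2rad(theta_deg)
    r = 1.0 / np.sqrt(np.cos(phi - t0) ** 2 + np.sin(phi - t0) ** 2 / ratio**2)
    return PolarProfile(angles_deg=np.rad2deg(phi), amplitude=r)


class TestPowerSpectrum:
    def test_constant_image_concentrates_at_dc(self):
        ps = power_spectrum(SlicePlane(np.full((128, 128), 7.0), PITCH), window=False)
        center = ps.amplitude[64, 64]
        off_dc = ps.amplitude.copy()
        off_dc[64, 64] = 0.0
        assert center > 0
        assert off_dc.max() < 1e-6 * center

    def test_pure_sinusoid_gives_two_symmetric_peaks(self):
        n = 128
        x = np.arange(n) * PITCH
        img = 50 + 40 * np.cos(2 * np.pi * x / 5.0)[None, :] * np.ones((n, 1))
        ps = power_spectrum(SlicePlane(img, PITCH), window=False)
        amp = ps.amplitude.copy()
        amp[n // 2, n // 2] = 0.0  # drop DC
        iy, ix = np.unravel_index(np.argsort(amp.ravel())[-2:], amp.shape)
        assert np.all(iy == n // 2)  # on the horizontal frequency axis
        assert set(ix) == {n // 2 - np.abs(ix[0] - n // 2), n // 2 + np.abs(ix[0] - n // 2)}

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            SlicePlane(np.zeros((64, 65)), PITCH)


class TestDirectionalAmplitude:
    def test_white_noise_profile_is_flat(self):
        # isotropy judged over (essentially) the full spectrum so every
        # angular bin pools thousands of samples
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (512, 512))
        ps = power_spectrum(SlicePlane(img, PITCH), window=False)
        prof = directional_amplitude(ps, band=(0.02, 1.7), n_bins=36)
        assert prof.amplitude.max() / prof.amplitude.min() < 1.1

    def test_horizontal_fibers_peak_at_90(self):
        prof = directional_amplitude(power_spectrum(SlicePlane(_grating(0.0), PITCH)))
        argmax = prof.angles_deg[np.argmax(prof.amplitude)]
        assert angular_difference(argmax, 90.0) <= 1.0  # energy ⊥ fibers

    def test_rotation_moves_the_argmax(self):
        img = _grating(20.0)
        rot = ndimage.rotate(img, -45.0, reshape=False, mode="constant", cval=100.0)
        p0 = directional_amplitude(power_spectrum(SlicePlane(img, PITCH)))
        p1 = directional_amplitude(power_spectrum(SlicePlane(rot, PITCH)))
        a0 = p0.angles_deg[np.argmax(p0.amplitude)]
        a1 = p1.angles_deg[np.argmax(p1.amplitude)]
        assert angular_difference(a1, a0 + 45.0) <= 1.5

    def test_band_and_bin_validation(self):
        ps = power_spectrum(SlicePlane(np.zeros((64, 64)), PITCH))
        with pytest.raises(ValueError):
            directional_amplitude(ps, band=(5.0, 10.0))  # beyond Nyquist
        with pytest.raises(ValueError):
            directional_amplitude(ps, n_bins=10)


class TestEllipseFit:
    def test_constant_profile_is_isotropic(self):
        phi = np.arange(0.5, 180.0, 1.0)
        res = fit_orientation_ellipse(PolarProfile(phi, np.full_like(phi, 3.0)))
        assert res.isotropic
        assert res.degree == 1.0
        assert np.isnan(res.theta_deg)

    @pytest.mark.parametrize("theta,ratio", [(30.0, 2.0), (120.0, 3.0), (0.0, 1.5)])
    def test_exact_ellipse_identity(self, theta, ratio):
        res = fit_orientation_ellipse(_ellipse_profile(theta, ratio))
        assert not res.isotropic
        assert angular_difference(res.theta_deg, theta) < 1e-6
        assert res.degree == pytest.approx(ratio, abs=1e-6)

    def test_degree_never_below_one(self):
        rng = np.random.default_rng(1)
        phi = np.arange(0.5, 180.0, 1.0)
        for _ in range(20):
            res = fit_orientation_ellipse(PolarProfile(phi, rng.uniform(1, 2, phi.size)))
            assert res.degree >= 1.0
            assert res.isotropic == (res.degree == 1.0)


class TestAnalyzeStack:
    def test_planted_bundle_recovered(self):
        spec = make_spec(z_extent=32.0, bundle_depths=[(16.0, 8.0)], seed=23)
        geom = generate_collagen_geometry(spec)
        stack = rasterize_stack(geom, spec, channel="collagen")
        prof = analyze_stack(stack, boundary_z=0)
        assert len(prof) == stack.n_slices
        mid = 8  # slab center slice
        assert angular_difference(prof.theta_deg[mid], 60.0) <= 3.0
        # degree elevated inside the slab versus the fiber-free top slice
        assert prof.degree[mid] > 2.0 * prof.degree[0]

    def test_profile_covers_all_slices_below_boundary(self, noise_stack):
        _, stack = noise_stack
        prof = analyze_stack(stack, boundary_z=1)
        assert len(prof) == stack.n_slices - 1
        assert prof.depth_um[0] == 0.0
        assert np.all(np.diff(prof.depth_um) == stack.z_interval)

    def test_noise_slices_are_unresolvable(self, noise_stack):
        _, stack = noise_stack
        prof = analyze_stack(stack, boundary_z=0)
        assert np.all(prof.isotropic | (prof.degree < 1.10))

    def test_short_stack_rejected(self, noise_stack):
        _, stack = noise_stack
        with pytest.raises(ValueError):
            analyze_stack(stack, boundary_z=stack.n_slices - 1)

    def test_intensity_scale_invariance(self, straight_tile):
        spec, _, stack = straight_tile
        img = stack.data[6].astype(float)
        r1 = analyze_slice(SlicePlane(img, spec.pixel_pitch))
        r2 = analyze_slice(SlicePlane(img * 3.7, spec.pixel_pitch))
        assert angular_difference(r1.theta_deg, r2.theta_deg) < 1e-9
        assert r2.degree == pytest.approx(r1.degree, rel=1e-9)

    @pytest.mark.parametrize("delta", [30.0, 45.0, 90.0])
    def test_rotation_equivariance(self, straight_tile, delta):
        spec, _, stack = straight_tile
        img = stack.data[6].astype(float)
        r0 = analyze_slice(SlicePlane(img, spec.pixel_pitch))
        rot = ndimage.rotate(img, -delta, reshape=False, order=1,
                             mode="constant", cval=10.0)
        r1 = analyze_slice(SlicePlane(rot, spec.pixel_pitch))
        assert angular_difference(r1.theta_deg, r0.theta_deg + delta) <= 2.0

    def test_agrees_with_structure_tensor_oracle(self, straight_tile):
        from skimage.feature import structure_tensor

        spec, _, stack = straight_tile
        img = stack.data[6].astype(float)
        fft_theta = analyze_slice(SlicePlane(img, spec.pixel_pitch)).theta_deg
        Arr, Arc, Acc = structure_tensor(img, sigma=3.0, order="rc")
        J = np.array([[Arr.mean(), Arc.mean()], [Arc.mean(), Acc.mean()]])
        _, evecs = np.linalg.eigh(J)
        v = evecs[:, 0]  # least gradient variance: along the fibers
        st_theta = np.rad2deg(np.arctan2(v[0], v[1])) % 180
        assert angular_difference(fft_theta, st_theta) <= 3.0

    def test_degree_decreases_with_planted_dispersion(self):
        degrees = []
        for disp in (5.0, 15.0, 30.0, 45.0):
            spec = make_spec(z_extent=8.0, bundle_depths=[(4.0, 8.0)],
                             mode_centers=[30.0], mode_dispersion=disp, seed=5)
            geom = generate_collagen_geometry(spec)
            stack = rasterize_stack(geom, spec, channel="collagen")
            degrees.append(analyze_slice(SlicePlane(stack.data[2], spec.pixel_pitch)).degree)
        assert degrees == sorted(degrees, reverse=True)
        assert degrees[0] > 3.0 and degrees[-1] < 3.0
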
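"""Phantom generator: geometry, extension mechanics, rasterization, curves."""

import numpy as np
import pytest

from fiborient import (
    ExtensionParams,
    Fiber,
    FiberFieldSpec,
    FiberGeometry,
    apply_biaxial_extension,
    generate_collagen_geometry,
    generate_elastic_geometry,
    generate_stress_strain,
    rasterize_stack,
)
from fiborient.angles import angular_difference, axial_mean
from fiborient.mechanics import linear_region_intercept
from fiborient.synthetic import arc_length, chord_length

from conftest import make_spec


class TestCollagenGeometry:
    def test_degenerate_dispersion_plants_exact_orientation(self):
        spec = make_spec(mode_centers=[30.0], mode_dispersion=0.0,
                         bundle_coherent=False, seed=1)
        geom = generate_collagen_geometry(spec)
        assert len(geom) > 0
        assert all(f.orientation_deg == 30.0 for f in geom.fibers)

    def test_mode_assignment_fractions_are_binomial(self):
        spec = make_spec(
            bundle_depths=[(30.0, 60.0)], z_extent=60.0,
            mode_centers=[30.0, 96.0], mode_weights=[0.6, 0.4],
            mode_dispersion=5.0, bundle_coherent=False, seed=2,
        )
        geom = generate_collagen_geometry(spec)
        modes = np.array([f.mode_id for f in geom.fibers])
        n = len(modes)
        assert n > 300  # dense phantom
        frac = np.mean(modes == 0)
        sigma = np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < 3 * sigma + 1e-12

    def test_zero_waviness_gives_straight_polylines(self):
        spec = make_spec(waviness_amplitude=0.0, seed=3)
        geom = generate_collagen_geometry(spec)
        for f in geom.fibers:
            assert arc_length(f.points) == pytest.approx(chord_length(f.points), rel=1e-9)

    def test_vertices_inside_field_and_arc_geq_chord(self, crimped_geometry):
        spec, geom = crimped_geometry
        for f in geom.fibers:
            assert np.all(f.points[:, :2] >= -1e-9)
            assert np.all(f.points[:, :2] <= spec.field_xy + 1e-9)
            assert arc_length(f.points) >= chord_length(f.points) - 1e-9
            assert 0 <= f.orientation_deg < 180

    def test_packing_density_realized(self):
        spec = make_spec(seed=4, packing_density=0.5)
        geom = generate_collagen_geometry(spec)
        n_layers = max(1, round(20.0 / spec.fiber_diameter))
        covered = sum(chord_length(f.points) * f.diameter_um for f in geom.fibers)
        target = 0.5 * spec.field_xy**2 * n_layers
        assert covered == pytest.approx(target, rel=0.10)

    def test_same_seed_is_bit_identical_different_seed_is_not(self):
        g1 = generate_collagen_geometry(make_spec(seed=5))
        g2 = generate_collagen_geometry(make_spec(seed=5))
        g3 = generate_collagen_geometry(make_spec(seed=6))
        assert len(g1) == len(g2)
        for f1, f2 in zip(g1.fibers, g2.fibers):
            assert np.array_equal(f1.points, f2.points)
        assert any(
            f1.orientation_deg != f3.orientation_deg
            for f1, f3 in zip(g1.fibers, g3.fibers)
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mode_weights=[0.5, 0.5, 0.0], mode_centers=[10.0, 50.0, 90.0]),
            dict(mode_weights=[0.7, 0.4]),  # does not sum to 1
            dict(mode_centers=[185.0], mode_weights=[1.0]),
            dict(bundle_depths=[(500.0, 40.0)]),  # slab beyond z_extent
            dict(packing_density=0.0),
            dict(waviness_amplitude=-1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_spec(**kwargs)


class TestElasticGeometry:
    def test_zero_jitter_matches_bundle_orientation(self, straight_tile):
        spec, collagen, _ = straight_tile
        elastic = generate_elastic_geometry(collagen, jitter_sd=0.0, density=10.0, seed=1)
        bundle_theta = axial_mean([f.orientation_deg for f in collagen.fibers])
        assert len(elastic) > 0
        for f in elastic.fibers:
            assert angular_difference(f.orientation_deg, bundle_theta) < 1e-9

    def test_jitter_rms_matches_planted_sd(self):
        # |axial difference| is folded-normal: E[d²] = σ², so RMS recovers σ
        spec = make_spec(
            z_extent=300.0,
            bundle_depths=[(50.0 + 50.0 * i, 12.0) for i in range(5)],
            seed=7,
        )
        collagen = generate_collagen_geometry(spec)
        elastic = generate_elastic_geometry(collagen, jitter_sd=5.0, density=100.0, seed=8)
        bundle_theta = {
            b: axial_mean([f.orientation_deg for f in collagen.fibers if f.bundle_id == b])
            for b in {f.bundle_id for f in collagen.fibers}
        }
        diffs = np.array(
            [angular_difference(f.orientation_deg, bundle_theta[f.bundle_id])
             for f in elastic.fibers]
        )
        assert len(diffs) >= 2000
        assert np.sqrt(np.mean(diffs**2)) == pytest.approx(5.0, abs=0.3)

    def test_zero_density_gives_empty_geometry(self, straight_tile):
        _, collagen, _ = straight_tile
        elastic = generate_elastic_geometry(collagen, jitter_sd=5.0, density=0.0, seed=1)
        assert len(elastic) == 0

    def test_layer_dependent_diameters(self):
        spec = make_spec(z_extent=500.0, bundle_depths=[(100.0, 12.0), (300.0, 12.0)], seed=9)
        collagen = generate_collagen_geometry(spec)
        elastic = generate_elastic_geometry(collagen, jitter_sd=5.0, density=5.0, seed=10)
        diam = {f.bundle_id: f.diameter_um for f in elastic.fibers}
        assert diam[0] == pytest.approx(4.4)  # superficial, thinner
        assert diam[1] == pytest.approx(5.9)  # deep, thicker

    def test_negative_jitter_rejected(self, straight_tile):
        _, collagen, _ = straight_tile
        with pytest.raises(ValueError):
            generate_elastic_geometry(collagen, jitter_sd=-1.0, density=1.0, seed=0)


class TestBiaxialExtension:
    def test_straight_fiber_scales_affinely(self, straight_tile):
        _, geom, _ = straight_tile
        out = apply_biaxial_extension(geom, ExtensionParams(1.25))
        for f0, f1 in zip(geom.fibers, out.fibers):
            assert f1.orientation_deg == f0.orientation_deg
            assert arc_length(f1.points) == pytest.approx(1.25 * arc_length(f0.points), rel=1e-6)
            assert f1.amplitude_um == 0.0

    def test_arc_length_conserved_below_straightening(self, crimped_geometry):
        _, geom = crimped_geometry
        lam = 1.01
        out = apply_biaxial_extension(geom, ExtensionParams(lam))
        checked = 0
        for f0, f1 in zip(geom.fibers, out.fibers):
            if arc_length(f0.points) / chord_length(f0.points) > lam + 1e-6:
                assert arc_length(f1.points) == pytest.approx(
                    arc_length(f0.points), rel=1e-3
                )
                checked += 1
        assert checked > 10

    def test_chord_orientation_preserved_exactly(self, crimped_geometry):
        _, geom = crimped_geometry
        out = apply_biaxial_extension(geom, ExtensionParams(1.05))
        for f0, f1 in zip(geom.fibers, out.fibers):
            d0 = f0.points[-1] - f0.points[0]
            d1 = f1.points[-1] - f1.points[0]
            assert np.arctan2(d0[1], d0[0]) == pytest.approx(
                np.arctan2(d1[1], d1[0]), abs=1e-9
            )

    def test_straightening_at_own_arc_chord_ratio(self, crimped_geometry):
        # the stretch that straightens a fiber equals its arc/chord ratio
        _, geom = crimped_geometry
        f = geom.fibers[0]
        ratio = arc_length(f.points) / chord_length(f.points)
        assert ratio > 1.05
        one = FiberGeometry([f], geom.field_xy, geom.z_extent)
        out = apply_biaxial_extension(one, ExtensionParams(ratio))
        f1 = out.fibers[0]
        assert f1.amplitude_um == 0.0
        assert arc_length(f1.points) == pytest.approx(chord_length(f1.points), rel=1e-9)

    def test_default_thickness_factor_is_incompressible(self):
        p = ExtensionParams(1.25)
        assert p.thickness_factor == pytest.approx(1.0 / 1.25**2)  # 0.64
        z0 = np.array([[0.0, 0.0, 100.0], [10.0, 0.0, 100.0]])
        geom = FiberGeometry(
            [Fiber(points=z0, orientation_deg=0.0, bundle_id=0,
                   channel="collagen", diameter_um=5.0)],
            211.0, 500.0,
        )
        out = apply_biaxial_extension(geom, p)
        assert out.fibers[0].points[0, 2] == pytest.approx(64.0)

    def test_lambda_below_one_rejected(self):
        with pytest.raises(ValueError):
            ExtensionParams(0.9)


class TestRasterize:
    def test_empty_geometry_yields_flat_background(self):
        spec = make_spec(z_extent=4.0, bundle_depths=[(2.0, 2.0)],
                         noise_sd=0.0, background_level=10.0)
        stack = rasterize_stack(FiberGeometry([], spec.field_xy, spec.z_extent), spec)
        assert np.all(stack.data == 10)

    def test_shape_and_dtype_contract(self, noise_stack):
        spec, stack = noise_stack
        n_z = int(round(spec.z_extent / spec.z_interval)) + 1
        assert stack.data.shape == (n_z, 512, 512)
        assert stack.data.dtype == np.uint8
        assert stack.pixel_pitch == pytest.approx(211.0 / 512.0)

    def test_single_fiber_profile_position_and_width(self):
        from fiborient import Fiber

        spec = make_spec(z_extent=4.0, bundle_depths=[(2.0, 2.0)], noise_sd=0.0,
                         background_level=0.0, psf_sigma=0.5, fiber_diameter=5.0)
        y0 = 105.0
        pts = np.column_stack([
            np.linspace(0, spec.field_xy, 600),
            np.full(600, y0),
            np.full(600, 2.0),
        ])
        geom = FiberGeometry(
            [Fiber(points=pts, orientation_deg=0.0, bundle_id=0,
                   channel="collagen", diameter_um=5.0)],
            spec.field_xy, spec.z_extent,
        )
        stack = rasterize_stack(geom, spec)
        col = stack.data[1, :, 256].astype(float)
        row_peak = int(np.argmax(col))
        assert abs(row_peak - y0 / spec.pixel_pitch) <= 1.5
        half = col.max() / 2.0
        fwhm_px = np.sum(col >= half)
        expected_um = np.sqrt(5.0**2 + (2.3548 * 0.5) ** 2)  # tube ⊕ PSF in quadrature
        assert fwhm_px * spec.pixel_pitch == pytest.approx(expected_um, rel=0.25)

    def test_rasterization_deterministic_per_seed(self, straight_tile):
        spec, geom, stack = straight_tile
        again = rasterize_stack(geom, spec, channel="collagen")
        assert np.array_equal(stack.data, again.data)


class TestStressStrainGenerator:
    def test_noiseless_intercept_recovered_exactly(self):
        curve = generate_stress_strain(0.26, 20.0, noise_sd=0.0, n=200)
        fit = linear_region_intercept(curve)
        assert fit.x_intercept_strain == pytest.approx(0.26, abs=1e-9)
        assert fit.lambda_star == pytest.approx(1.26, abs=1e-9)

    def test_planted_straightening_strain_maps_to_stretch_ratio(self):
        curve = generate_stress_strain(0.28, 15.0, noise_sd=0.0, n=150)
        fit = linear_region_intercept(curve)
        assert fit.lambda_star == pytest.approx(1.28, abs=1e-9)

    def test_small_n_curve_is_monotone(self):
        curve = generate_stress_strain(0.2, 10.0, noise_sd=0.0, n=10)
        assert np.all(np.diff(curve.strain) > 0)
        assert np.all(np.diff(curve.stress) >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_stress_strain(-0.1, 10.0)
        with pytest.raises(ValueError):
            generate_stress_strain(0.2, 0.0)
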
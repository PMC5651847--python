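import numpy as np
import pytest

from countershading import (
    Orientation,
    ReflectanceMap,
    RenderedView,
    SkyModel,
    apparent_shading,
    irradiance,
    irradiance_many,
    leaf_reference_radiance,
    make_ellipsoid,
    optimal_reflectance,
    render,
    rotate_mesh,
    scene_pose,
    shading_curves,
)
from countershading.lightfield import ISOTROPIC

LEVELS = (0.0, 15.0, 30.0, 45.0, 90.0)


class TestLeafReferenceRadiance:
    def test_isotropic_identity(self, iso_sky):
        # E = pi * L0, albedo 1 => radiance L0
        assert leaf_reference_radiance(iso_sky, 1.0) == pytest.approx(2.0)

    def test_linearity_in_albedo(self, sky):
        full = leaf_reference_radiance(sky, 1.0)
        assert leaf_reference_radiance(sky, 0.5) == pytest.approx(full / 2)

    def test_composition_with_irradiance(self, sky):
        expected = 0.5 * irradiance(sky, [0, 0, 1]) / np.pi
        assert leaf_reference_radiance(sky, 0.5) == pytest.approx(expected)

    def test_invalid_albedo(self, sky):
        with pytest.raises(ValueError):
            leaf_reference_radiance(sky, 0.0)


class TestOptimalReflectance:
    def test_isotropic_environment_gives_unit_albedo(self, iso_sky, ref_mesh):
        # exact up to quadrature tolerance (0.2%)
        refl = optimal_reflectance(ref_mesh, iso_sky, rad_hor_leaf=2.0)
        assert np.abs(refl.values - 1.0).max() < 2e-3

    def test_linearity_in_target_radiance(self, ref_mesh, sky, rad_leaf, optimal_map):
        doubled = optimal_reflectance(ref_mesh, sky, 2 * rad_leaf)
        assert np.allclose(doubled.values, 2 * optimal_map.values)

    def test_countershading_direction(self, ref_mesh, sky, optimal_map):
        """Upward faces get lower albedo than downward faces, by exactly the
        inverse irradiance ratio."""
        nz = ref_mesh.face_normals[:, 2]
        top, bottom = np.argmax(nz), np.argmin(nz)
        assert optimal_map.values[top] < optimal_map.values[bottom]
        irr = irradiance_many(sky, ref_mesh.face_normals[[top, bottom]])
        assert optimal_map.values[top] / optimal_map.values[bottom] == pytest.approx(
            irr[1] / irr[0], rel=1e-9
        )

    def test_unlit_face_raises(self, ref_mesh):
        # sun-only sky: faces turned away from the beam receive nothing
        dark = SkyModel(
            sun_azimuth=270.0,
            sun_altitude=45.0,
            sun_irradiance=10.0,
            zenith_radiance=0.0,
            ground_albedo=0.0,
        )
        with pytest.raises(ValueError, match="faces"):
            optimal_reflectance(ref_mesh, dark, 1.0)

    def test_clamped_map(self, ref_mesh, sky, rad_leaf):
        refl = optimal_reflectance(ref_mesh, sky, rad_leaf, clamp=True)
        assert refl.clamped and refl.values.max() <= 1.0

    def test_negative_albedo_rejected(self):
        with pytest.raises(ValueError):
            ReflectanceMap(np.array([0.5, -0.1]))


class TestRender:
    def test_reference_orientation_is_flat(self, ref_mesh, sky, rad_leaf, optimal_map):
        view = render(ref_mesh, optimal_map, sky)
        assert np.abs(view.radiance - rad_leaf).max() / rad_leaf < 0.005

    def test_uniform_albedo_isotropic_environment(self, iso_sky, ref_mesh):
        refl = ReflectanceMap(np.full(ref_mesh.n_faces, 0.7))
        view = render(ref_mesh, refl, iso_sky, Orientation(pitch=33, roll=10))
        assert np.abs(view.radiance - 0.7 * 2.0).max() / 1.4 < 2e-3

    def test_roll_90_spot_check_against_irradiance_ratio(
        self, ref_mesh, sky, rad_leaf, optimal_map
    ):
        """Re-rendered radiance equals rad_leaf * irr(rotated n) / irr(n),
        recomputed by hand for sampled faces."""
        o = Orientation(roll=90)
        view = render(ref_mesh, optimal_map, sky, o)
        rotated = rotate_mesh(ref_mesh, o)
        idx = [0, 100, 500, 900, 1270]
        irr0 = irradiance_many(sky, ref_mesh.face_normals[idx])
        irr1 = irradiance_many(sky, rotated.face_normals[idx])
        assert view.radiance[idx] == pytest.approx(rad_leaf * irr1 / irr0, rel=1e-9)

    def test_visibility_is_backface_test(self, ref_mesh, sky, optimal_map):
        view = render(ref_mesh, optimal_map, sky)
        rotated = rotate_mesh(ref_mesh, Orientation())
        assert np.array_equal(view.visible, rotated.face_normals @ [1.0, 0, 0] < 0)
        assert 0 < view.visible.sum() < ref_mesh.n_faces

    def test_misaligned_map_rejected(self, ref_mesh, sky):
        with pytest.raises(ValueError):
            render(ref_mesh, ReflectanceMap(np.ones(10)), sky)


class TestApparentShading:
    def test_reference_shading_vanishes(self, ref_mesh, sky, rad_leaf, optimal_map):
        view = render(ref_mesh, optimal_map, sky)
        assert apparent_shading(view) < 0.01 * rad_leaf

    def test_constant_view_is_exactly_zero(self):
        view = RenderedView(
            radiance=np.full(8, 3.3), visible=np.ones(8, bool), orientation=Orientation()
        )
        assert apparent_shading(view) == 0.0
        assert apparent_shading(view, visible_only=False) == 0.0

    def test_countershading_beats_uniform_at_reference(
        self, ref_mesh, sky, rad_leaf, optimal_map
    ):
        """At the reference orientation the countershaded body shows far
        less apparent shading than a uniform body of leaf albedo, whose
        shading stays high at every departure level.  (Beyond the reference
        the max-min statistic of the rotated pattern can exceed the uniform
        body's: the pattern modulates radiance on top of the illumination
        gradient.)"""
        uniform = ReflectanceMap(np.full(ref_mesh.n_faces, 0.5))
        ref_cs = apparent_shading(render(ref_mesh, optimal_map, sky))
        s_uni_ref = apparent_shading(render(ref_mesh, uniform, sky))
        assert ref_cs < 0.01 * s_uni_ref
        for axis in ("pitch", "roll", "yaw"):
            for level in LEVELS:
                o = Orientation(**{axis: level})
                s_uni = apparent_shading(render(ref_mesh, uniform, sky, o))
                assert ref_cs < 0.1 * s_uni


class TestShadingCurves:
    def test_global_maximum_is_one(self, curves):
        assert max(c.normalized.max() for c in curves.values()) == 1.0

    def test_level_zero_identical_across_axes(self, curves):
        zeros = [c.normalized[0] for c in curves.values()]
        assert zeros[0] == zeros[1] == zeros[2]

    def test_each_curve_non_decreasing(self, curves):
        for c in curves.values():
            assert np.all(np.diff(c.normalized) >= -1e-12)
            assert c.normalized[0] <= c.normalized.min() + 1e-12

    def test_scale_invariance_of_normalized_curves(self, ref_mesh, sky, curves):
        k = 3.0
        scaled_sky = SkyModel(
            sun_azimuth=sky.sun_azimuth,
            sun_altitude=sky.sun_altitude,
            sun_irradiance=k * sky.sun_irradiance,
            coefficients=sky.coefficients,
            zenith_radiance=k * sky.zenith_radiance,
            ground_albedo=sky.ground_albedo,
        )
        rad = leaf_reference_radiance(scaled_sky)
        refl = optimal_reflectance(ref_mesh, scaled_sky, rad)
        scaled = shading_curves(ref_mesh, refl, scaled_sky)
        for axis in ("pitch", "roll", "yaw"):
            assert np.allclose(
                scaled[axis].normalized, curves[axis].normalized, atol=1e-9
            )

    def test_degenerate_light_field_raises(self, ref_mesh):
        dark = SkyModel(sun_irradiance=0.0, zenith_radiance=0.0, ground_albedo=0.0)
        refl = ReflectanceMap(np.ones(ref_mesh.n_faces))
        with pytest.raises(ValueError, match="degenerate"):
            shading_curves(ref_mesh, refl, dark, axes=("pitch",))

    def test_all_faces_mode_also_monotone_from_zero(
        self, ref_mesh, sky, optimal_map
    ):
        c = shading_curves(
            ref_mesh, optimal_map, sky, axes=("roll",), visible_only=False
        )["roll"]
        assert c.raw[0] <= c.raw.min() + 1e-12


def test_flatness_cv_decreases_with_quadrature(sky):
    """Flatness of the optimal pattern is limited only by quadrature noise."""
    mesh = scene_pose(make_ellipsoid(subdivision=2))
    cvs = []
    for quad in ((16, 8), (64, 32)):
        rad = leaf_reference_radiance(sky, quadrature=quad)
        refl = optimal_reflectance(mesh, sky, rad, quadrature=quad)
        view = render(mesh, refl, sky, quadrature=(128, 64))
        cvs.append(view.radiance.std() / view.radiance.mean())
    assert cvs[1] < cvs[0]
    assert cvs[1] < 0.01
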
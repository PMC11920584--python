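"""Snell's-law refraction, cylinder intersections, and ray-field tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootcarve as rc
from rootcarve.errors import InvalidSceneGeometryError, ValidationError
from rootcarve.optics import (
    Cylinder,
    OpticalMedia,
    RayField,
    _pixel_grid_rays,
    downsample_mask,
    intersect_cylinder,
    interior_roi,
    pixel_visibility_mask,
    refract_direction,
    trace_view,
    visible_fraction,
)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestRefractDirection:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, -1.0])
        n = np.array([0.0, 0.0, 1.0])
        for n1, n2 in [(1.0, 1.33), (1.49, 1.0), (1.33, 1.49)]:
            t, ok = refract_direction(d, n, n1, n2)
            assert ok
            np.testing.assert_allclose(t, d, atol=1e-15)

    def test_equal_indices_any_incidence(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = unit(rng.normal(size=3))
            n = unit(rng.normal(size=3))
            if d @ n >= -1e-6:
                n = -n
            t, ok = refract_direction(d, n, 1.2, 1.2)
            assert ok
            np.testing.assert_allclose(t, d, atol=1e-12)

    def test_air_to_water_45_degrees(self):
        """45 degrees into water bends to arcsin(sin 45 / 1.33) ~ 32.12 deg,
        verified against the scalar 2D construction in the incidence plane."""
        theta1 = np.pi / 4
        d = np.array([np.sin(theta1), 0.0, -np.cos(theta1)])
        n = np.array([0.0, 0.0, 1.0])
        t, ok = refract_direction(d, n, 1.0, 1.33)
        assert ok
        theta2 = np.arcsin(np.sin(theta1) / 1.33)
        expected = np.array([np.sin(theta2), 0.0, -np.cos(theta2)])
        np.testing.assert_allclose(t, expected, atol=1e-12)
        assert abs(np.degrees(theta2) - 32.117631) < 1e-5

    def test_snell_consistency_random_interfaces(self):
        """n1 sin(theta1) = n2 sin(theta2) to 1e-12 and coplanarity."""
        rng = np.random.default_rng(6)
        for _ in range(200):
            d = unit(rng.normal(size=3))
            n = unit(rng.normal(size=3))
            if d @ n > -0.05:
                n = -unit(n + 1e-3)
                if d @ n >= 0:
                    continue
            n1, n2 = rng.uniform(1.0, 1.6, 2)
            t, ok = refract_direction(d, n, n1, n2)
            sin1 = np.linalg.norm(np.cross(d, n))
            if not ok:
                assert n1 > n2 and sin1 > n2 / n1
                continue
            sin2 = np.linalg.norm(np.cross(t, n))
            assert abs(n1 * sin1 - n2 * sin2) <= 1e-12
            # refracted ray lies in the plane of incidence
            assert abs(np.cross(d, n) @ t) < 1e-12

    def test_reversibility(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            d = unit(rng.normal(size=3))
            n = unit(rng.normal(size=3))
            if d @ n >= -0.1:
                n = -n
                if d @ n >= -0.1:
                    continue
            t, ok = refract_direction(d, n, 1.0, 1.49)
            assert ok
            back, ok2 = refract_direction(-t, -n, 1.49, 1.0)
            assert ok2
            np.testing.assert_allclose(back, -d, atol=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n1=st.floats(1.0, 1.7),
        n2=st.floats(1.0, 1.7),
    )
    def test_snell_and_reversibility_property(self, seed, n1, n2):
        """For any refracting interface: the Snell ratio holds to 1e-12, the
        output is unit-norm, and re-refracting backwards recovers the input."""
        rng = np.random.default_rng(seed)
        d = unit(rng.normal(size=3))
        n = unit(rng.normal(size=3))
        if d @ n >= -1e-3:
            n = -n
        if d @ n >= -1e-3:
            return  # grazing: no well-posed interface normal
        t, ok = refract_direction(d, n, n1, n2)
        sin1 = np.linalg.norm(np.cross(d, n))
        if not ok:
            assert n1 > n2 and sin1 > n2 / n1
            return
        assert abs(np.linalg.norm(t) - 1.0) < 1e-12
        assert abs(n1 * sin1 - n2 * np.linalg.norm(np.cross(t, n))) <= 1e-12
        back, ok2 = refract_direction(-t, -n, n2, n1)
        assert ok2
        np.testing.assert_allclose(back, -d, atol=1e-9)

    def test_total_internal_reflection_flagged(self):
        theta = np.radians(80.0)  # beyond water->air critical angle (~48.6)
        d = np.array([np.sin(theta), 0.0, -np.cos(theta)])
        n = np.array([0.0, 0.0, 1.0])
        _, ok = refract_direction(d, n, 1.33, 1.0)
        assert not ok


class TestIntersectCylinder:
    def test_axial_symmetric_hit(self):
        cyl = Cylinder()
        o = np.array([300.0, 0.0, cyl.height / 2])
        d = np.array([-1.0, 0.0, 0.0])
        p, n, ok = intersect_cylinder(o, d, cyl, "outer")
        assert ok[0]
        np.testing.assert_allclose(p[0], [cyl.outer_radius, 0.0, cyl.height / 2], atol=1e-9)
        np.testing.assert_allclose(n[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_parallel_ray_outside_misses(self):
        cyl = Cylinder()
        _, _, ok = intersect_cylinder(
            np.array([200.0, 0.0, -10.0]), np.array([0.0, 0.0, 1.0]), cyl, "outer"
        )
        assert not ok[0]

    def test_end_cap_exit_is_a_miss(self):
        cyl = Cylinder()
        # ray passing over the top of the canister
        o = np.array([300.0, 0.0, -50.0])
        d = unit([-1.0, 0.0, 0.05])
        _, _, ok = intersect_cylinder(o, d, cyl, "outer")
        assert not ok[0]

    def test_oblique_matches_quadratic_oracle(self):
        cyl = Cylinder()
        rng = np.random.default_rng(4)
        for _ in range(50):
            o = np.array([250.0, rng.uniform(-50, 50), rng.uniform(20, 130)])
            d = unit([-1.0, rng.uniform(-0.3, 0.3), rng.uniform(-0.1, 0.1)])
            p, n, ok = intersect_cylinder(o, d, cyl, "inner")
            # independent quadratic in the xy plane
            a = d[0] ** 2 + d[1] ** 2
            b = 2 * (o[0] * d[0] + o[1] * d[1])
            c = o[0] ** 2 + o[1] ** 2 - cyl.inner_radius**2
            disc = b * b - 4 * a * c
            if disc < 0:
                assert not ok[0]
                continue
            ts = sorted([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
            t_hit = next((t for t in ts if t > 1e-9 and 0 <= o[2] + t * d[2] <= cyl.height), None)
            if t_hit is None:
                assert not ok[0]
            else:
                assert ok[0]
                np.testing.assert_allclose(p[0], o + t_hit * d, atol=1e-9)
                np.testing.assert_allclose(np.linalg.norm(n[0][:2]), 1.0, atol=1e-12)


class TestTraceView:
    def test_uniform_media_reduces_to_pinhole(self, cylinder):
        rig = rc.TurntableRig(n_views=1)
        view = rig.views(cylinder)[0]
        rf = trace_view(view, cylinder, OpticalMedia(1.0, 1.0, 1.0), (100, 80))
        _, d = _pixel_grid_rays(view, (100, 80))
        dev = np.linalg.norm(np.cross(rf.directions[rf.valid], d[rf.valid]), axis=-1)
        assert dev.max() < 1e-12
        assert rf.valid.sum() > 0

    def test_origins_on_inner_surface(self, cylinder, media):
        rig = rc.TurntableRig(n_views=1)
        view = rig.views(cylinder)[0]
        rf = trace_view(view, cylinder, media, (100, 80))
        r = cylinder.radial_distance(rf.origins[rf.valid])
        assert np.abs(r - cylinder.inner_radius).max() < 1e-9

    def test_meridional_ray_is_undeviated(self, cylinder, media):
        """A ray aimed at the axis in the camera's equatorial plane meets
        both walls at normal incidence and passes straight through."""
        rig = rc.TurntableRig(n_views=1)
        view = rig.views(cylinder)[0]
        C = view.camera_center
        d = unit(np.array([0.0, 0.0, C[2]]) - C)
        p1, n1, ok1 = intersect_cylinder(C, d, cylinder, "outer")
        t1, _ = refract_direction(d[None], n1, media.n_air, media.n_acrylic)
        p2, n2, ok2 = intersect_cylinder(p1, t1, cylinder, "inner")
        t2, _ = refract_direction(t1, n2, media.n_acrylic, media.n_water)
        assert ok1[0] and ok2[0]
        assert np.linalg.norm(np.cross(t2[0], d)) < 1e-12

    def test_deviation_monotone_in_index_contrast(self, cylinder):
        """A fixed oblique ray bends more as |n_water - n_air| grows."""
        rig = rc.TurntableRig(n_views=1)
        view = rig.views(cylinder)[0]
        C = view.camera_center
        target = np.array([30.0, 25.0, cylinder.height / 2])
        d = unit(target - C)
        devs = []
        for n_w in (1.0, 1.11, 1.22, 1.33):
            p1, n1, _ = intersect_cylinder(C, d, cylinder, "outer")
            t1, _ = refract_direction(d[None], n1, 1.0, n_w)
            p2, n2, _ = intersect_cylinder(p1, t1, cylinder, "inner")
            t2, _ = refract_direction(t1, n2, n_w, n_w)
            devs.append(float(np.linalg.norm(np.cross(t2[0], d))))
        assert all(b > a - 1e-15 for a, b in zip(devs, devs[1:]))
        assert devs[-1] > devs[0]

    def test_camera_inside_canister_rejected(self, cylinder, media):
        intr = rc.Intrinsics(fx=100.0, fy=100.0, cx=5.0, cy=5.0, width=10, height=10)
        R = np.eye(3)
        ext = rc.Extrinsics(R, -R @ np.array([10.0, 0.0, 50.0]))
        with pytest.raises(InvalidSceneGeometryError):
            trace_view(rc.CameraView(intr, ext), cylinder, media, (10, 10))

    def test_rayfield_cache_roundtrip(self, cylinder, media, tmp_path):
        rig = rc.TurntableRig(n_views=1)
        view = rig.views(cylinder)[0]
        rf = trace_view(view, cylinder, media, (60, 40))
        p = tmp_path / "rays.npz"
        rf.save(p)
        back = RayField.load(p)
        np.testing.assert_array_equal(back.valid, rf.valid)
        np.testing.assert_allclose(
            back.origins[back.valid], rf.origins[rf.valid], rtol=0, atol=0
        )
        assert back.meta["grid_resolution"] == [60, 40]
        assert back.as_tensor().shape == (3, 40, 60)


@pytest.fixture(scope="module")
def rayfield(cylinder, media):
    rig = rc.TurntableRig(n_views=1)
    view = rig.views(cylinder)[0]
    return trace_view(view, cylinder, media, (64, 48))


class TestVoxelVisibility:
    def test_matches_per_ray_slab_loop(self, rayfield, cylinder):
        rng = np.random.default_rng(19)
        for _ in range(3):
            c = np.array([rng.uniform(-30, 30), rng.uniform(-30, 30), rng.uniform(40, 110)])
            h = rng.uniform(2, 8)
            vis = pixel_visibility_mask(c, h, rayfield, cylinder)
            lo, hi = c - h, c + h
            oracle = np.zeros(rayfield.grid_shape, dtype=bool)
            for r in range(rayfield.grid_shape[0]):
                for col in range(rayfield.grid_shape[1]):
                    if not rayfield.valid[r, col]:
                        continue
                    o = rayfield.origins[r, col]
                    d = rayfield.directions[r, col]
                    t_near, t_far = 0.0, np.inf
                    miss = False
                    for ax in range(3):
                        if abs(d[ax]) < 1e-14:
                            if not (lo[ax] <= o[ax] <= hi[ax]):
                                miss = True
                                break
                            continue
                        t0, t1 = (lo[ax] - o[ax]) / d[ax], (hi[ax] - o[ax]) / d[ax]
                        t_near = max(t_near, min(t0, t1))
                        t_far = min(t_far, max(t0, t1))
                    oracle[r, col] = (not miss) and t_far >= t_near
            np.testing.assert_array_equal(vis.mask, oracle)

    def test_out_of_volume_voxel_flagged(self, rayfield, cylinder):
        vis = pixel_visibility_mask(np.array([0.0, 0.0, -80.0]), 2.0, rayfield, cylinder)
        assert vis.out_of_volume
        assert not vis.mask.any()

    def test_voxel_behind_camera_sees_nothing(self, rayfield, cylinder):
        # opposite side, beyond the water: no in-water ray can reach it
        vis = pixel_visibility_mask(np.array([0.0, 0.0, 300.0]), 5.0, rayfield, cylinder)
        assert not vis.mask.any()


class TestVisibleFraction:
    def test_full_silhouette_gives_one(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:6, 3:6] = True
        assert visible_fraction(mask, np.ones((10, 10), dtype=bool)) == 1.0

    def test_disjoint_gives_zero_and_empty_mask_zero(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        sil = np.zeros((10, 10), dtype=bool)
        sil[5, 5] = True
        assert visible_fraction(mask, sil) == 0.0
        assert visible_fraction(np.zeros((10, 10), dtype=bool), sil) == 0.0

    def test_matches_pixel_count_loop(self):
        rng = np.random.default_rng(29)
        mask = rng.random((15, 15)) > 0.5
        sil = rng.random((15, 15)) > 0.5
        num = sum(
            1 for r in range(15) for c in range(15) if mask[r, c] and sil[r, c]
        )
        assert visible_fraction(mask, sil) == num / mask.sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            visible_fraction(np.ones((4, 4), bool), np.ones((5, 5), bool))


def test_interior_roi_marks_canister_pixels(cylinder, media):
    rig = rc.TurntableRig(n_views=1)
    view = rig.views(cylinder)[0]
    roi = interior_roi(view, cylinder, media, (80, 60))
    assert roi.any() and not roi.all()
    # the canister is centered: the middle pixel must see the liquid
    assert roi[30, 40]


def test_downsample_mask_nearest_neighbor():
    mask = np.zeros((100, 100), dtype=bool)
    mask[:50] = True
    small = downsample_mask(mask, (10, 10))
    assert small[:5].all() and not small[5:].any()
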
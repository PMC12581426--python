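"""Plane construction, clipping, cavity extraction and volume arithmetic."""
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sella3d import (
    PhantomSpec,
    ThresholdWindow,
    clip_cavity,
    closure_planes_from_landmarks,
    compute_volume,
    expected_cavity_volume,
    extract_cavity,
    generate_fossa_phantom,
    plane_from_points,
    split_anterior_posterior,
    threshold_bone,
)
from sella3d.types import (
    BinaryMask,
    CuttingPlane,
    DegeneratePlaneError,
    LeakError,
    SeedPointError,
)


def cuboid_mask(shape=(20, 20, 20), spacing=0.5, origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    return BinaryMask(np.ones(shape, dtype=bool), (spacing,) * 3, origin)


class TestPlaneFromPoints:
    def test_xy_triangle_gives_z_normal(self):
        plane = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_toward=(0, 0, 5))
        assert np.allclose(plane.unit_normal, (0, 0, 1))

    def test_orientation_flips_with_reference(self):
        plane = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_toward=(0, 0, -5))
        assert np.allclose(plane.unit_normal, (0, 0, -1))

    def test_collinear_points_rejected(self):
        with pytest.raises(DegeneratePlaneError, match="collinear"):
            plane_from_points((0, 0, 0), (1, 1, 1), (2, 2, 2), orient_toward=(0, 0, 5))

    def test_reference_on_plane_rejected(self):
        with pytest.raises(DegeneratePlaneError, match="keep side"):
            plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_toward=(0.3, 0.4, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=12, max_size=12))
    def test_defining_points_lie_on_plane(self, coords):
        pts = np.asarray(coords).reshape(4, 3)
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        try:
            plane = plane_from_points(pts[0], pts[1], pts[2], orient_toward=pts[3])
        except DegeneratePlaneError:
            return
        assert area > 1e-6
        assert np.all(np.abs(plane.signed_distance(pts[:3])) < 1e-9 * max(1.0, area))
        assert plane.signed_distance(pts[3:4])[0] > 0


class TestClipCavity:
    def test_plane_outside_mask_is_noop(self):
        mask = cuboid_mask()
        plane = CuttingPlane(point=(0, 0, -100.0), unit_normal=(0, 0, 1.0), kerf=0.0)
        out = clip_cavity(mask, plane)
        assert np.array_equal(out.values, mask.values)

    def test_bisecting_plane_keeps_half(self):
        mask = cuboid_mask(shape=(20, 20, 20), spacing=0.5)  # extent [−0.25, 9.75]
        plane = CuttingPlane(point=(0, 0, 4.75), unit_normal=(0, 0, 1.0), kerf=0.0)
        out = clip_cavity(mask, plane)
        per_layer = 400
        assert abs(out.voxel_count - mask.voxel_count / 2) <= per_layer

    def test_kerf_removes_exactly_the_near_layers(self):
        mask = cuboid_mask(shape=(10, 10, 80), spacing=0.05)
        z0 = 1.9875  # between voxel centres
        plane = CuttingPlane(point=(0, 0, z0), unit_normal=(0, 0, 1.0), kerf=0.1)
        out = clip_cavity(mask, plane)
        zs = mask.axis_coordinates()[2]
        expected_kept = np.sum(zs - z0 > 0.05) * 100
        assert out.voxel_count == expected_kept
        removed_near = np.sum(np.abs(zs - z0) <= 0.05) * 100
        assert removed_near <= 2 * 100  # at most two voxel layers inside the kerf

    def test_growing_kerf_is_monotone(self):
        mask = cuboid_mask()
        plane0 = CuttingPlane(point=(0, 0, 4.6), unit_normal=(0, 0, 1.0), kerf=0.0)
        sets = []
        for kerf in (0.0, 0.3, 1.0):
            plane = CuttingPlane(point=plane0.point, unit_normal=plane0.unit_normal, kerf=kerf)
            sets.append(clip_cavity(mask, plane).values)
        assert not (sets[1] & ~sets[0]).any()
        assert not (sets[2] & ~sets[1]).any()

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(0)
        mask = BinaryMask(rng.random((12, 12, 12)) > 0.4, (0.5,) * 3)
        plane = CuttingPlane(point=(3, 3, 3), unit_normal=tuple(np.array([1, 2, 2]) / 3.0), kerf=0.2)
        out = clip_cavity(mask, plane)
        assert not (out.values & ~mask.values).any()


class TestExtractCavity:
    def test_closed_box_interior_exact(self):
        """A hollow bone box with no plane closure needed: exact interior count."""
        bone = np.zeros((12, 12, 12), dtype=bool)
        bone[2:10, 2:10, 2:10] = True
        bone[3:9, 3:9, 3:9] = False  # 6³ interior cavity
        mask = BinaryMask(bone, (0.5,) * 3)
        far_plane = CuttingPlane(point=(0, 0, -50.0), unit_normal=(0, 0, 1.0), kerf=0.0)
        cavity = extract_cavity(mask, far_plane, seed_point=(3.0, 3.0, 3.0))
        assert cavity.voxel_count == 6**3
        assert compute_volume(cavity) == pytest.approx(6**3 * 0.125)

    def test_sealed_phantom_close_to_truth(self, coarse_phantom, coarse_spec):
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        cavity = extract_cavity(bone, planes, seed_point=lm["sella_mid"])
        truth = expected_cavity_volume(coarse_spec, kerf=0.1)
        assert compute_volume(cavity) == pytest.approx(truth, rel=0.05)

    def test_missing_lateral_planes_leak(self, coarse_phantom):
        """The lateral notches are real gaps: closing only cranially must leak."""
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        cranial_only = plane_from_points(
            lm["cranial_1"], lm["cranial_2"], lm["cranial_3"],
            orient_toward=lm["sella_mid"], kerf=0.1,
        )
        with pytest.raises(LeakError, match="x_(min|max)"):
            extract_cavity(bone, cranial_only, seed_point=lm["sella_mid"])

    def test_seed_inside_bone_rejected(self, coarse_phantom):
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        with pytest.raises(SeedPointError, match="inside bone"):
            extract_cavity(bone, planes, seed_point=(0.0, 0.0, -9.0))


class TestSplitAnteriorPosterior:
    def _phantom_cavity(self, spec):
        vol, lm, _ = generate_fossa_phantom(spec)
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        return extract_cavity(bone, planes, seed_point=lm["sella_mid"]), lm

    def test_plane_fully_posterior_gives_zero_posterior_volume(self, coarse_phantom):
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        cavity = extract_cavity(bone, planes, seed_point=lm["sella_mid"])
        triple = split_anterior_posterior(
            cavity, (1.0, -50.0, 0.0), (-1.0, -50.0, 0.0), (0.0, -50.0, -5.0),
            anterior_point=lm["tuberculum"],
        )
        assert triple.vol_p == 0.0
        assert triple.vol_a == triple.vol_t

    def test_midplane_split_is_symmetric(self, coarse_phantom):
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        cavity = extract_cavity(bone, planes, seed_point=lm["sella_mid"])
        # the fossa is symmetric in y; split along y = 0
        triple = split_anterior_posterior(
            cavity, (1.0, 0.0, 0.0), (-1.0, 0.0, 0.0), (0.0, 0.0, -5.0),
            anterior_point=(0.0, 10.0, 0.0),
        )
        layer = cavity.voxel_volume_mm3 * np.count_nonzero(
            np.abs(cavity.axis_coordinates()[1]) < cavity.spacing[1]
        )
        assert abs(triple.vol_p / triple.vol_t - 0.5) <= max(0.02, layer / triple.vol_t)

    def test_conservation_exact_on_random_phantoms(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a, b, c = rng.uniform(4.0, 6.5), rng.uniform(4.0, 6.0), rng.uniform(5.0, 9.0)
            spec = PhantomSpec(a=a, b=b, c=c, plate_thickness=c + 1.5,
                               spacing=0.35, seed=int(rng.integers(1 << 30)))
            cavity, lm = self._phantom_cavity(spec)
            triple = split_anterior_posterior(
                cavity, lm["pcp"], lm["dorsum"], lm["floor_caudal"],
                anterior_point=lm["tuberculum"],
            )
            assert triple.vol_a + triple.vol_p == triple.vol_t  # exact, by definition
            assert triple.vol_t == pytest.approx(compute_volume(cavity))

    def test_degenerate_split_plane_rejected(self, coarse_phantom):
        vol, lm, _ = coarse_phantom
        bone = threshold_bone(vol, ThresholdWindow(900, 3000))
        planes = closure_planes_from_landmarks(lm, kerf=0.1)
        cavity = extract_cavity(bone, planes, seed_point=lm["sella_mid"])
        with pytest.raises(DegeneratePlaneError):
            split_anterior_posterior(
                cavity, (0, 0, 0), (1, 1, 1), (2, 2, 2), anterior_point=(0, 5, 0)
            )


class TestComputeVolume:
    def test_empty_mask_zero(self):
        mask = BinaryMask(np.zeros((3, 3, 3), dtype=bool), (1.0,) * 3)
        assert compute_volume(mask) == 0.0

    def test_isotropic_arithmetic(self):
        values = np.zeros((12, 12, 12), dtype=bool)
        values[:10, :10, :10] = True
        assert compute_volume(BinaryMask(values, (0.5,) * 3)) == pytest.approx(125.0)

    def test_anisotropic_arithmetic(self):
        values = np.zeros((10, 10, 10), dtype=bool)
        values.ravel()[:1000] = True
        mask = BinaryMask(values.reshape(10, 10, 10), (0.47, 0.47, 0.6))
        assert compute_volume(mask) == pytest.approx(1000 * 0.47 * 0.47 * 0.6)
        assert compute_volume(mask) == pytest.approx(132.54, abs=0.01)


class TestOrientationInvariance:
    def test_rotated_geometry_measures_within_two_percent(self):
        """Voxelizing a rigidly rotated ellipsoid + planes changes volumes < 2%."""
        a, b, c = 5.5, 5.0, 8.0
        theta = math.radians(30.0)
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0.0],
            [math.sin(theta), math.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        spacing = 0.15

        def measure(R):
            # sample the rotated solid on an axis-aligned grid
            n = int(math.ceil(2 * 10.0 / spacing))
            axis = -10.0 + spacing / 2 + spacing * np.arange(n)
            X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
            pts = np.stack([X, Y, Z], axis=-1) @ R  # body-frame coordinates
            inside = (
                (pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2 + (pts[..., 2] / c) ** 2
            ) <= 1.0
            mask = BinaryMask(inside, (spacing,) * 3, origin=(-10.0 + spacing / 2,) * 3)
            # split by the body-frame plane z' = -2 (rotates with the object)
            normal_world = R.T @ np.array([0.0, 0.0, 1.0])
            point_world = R.T @ np.array([0.0, 0.0, -2.0])
            anterior_world = R.T @ np.array([0.0, 0.0, 5.0])
            p1 = point_world
            # two more points spanning the plane
            u = np.linalg.svd(normal_world.reshape(1, 3))[2][1:]
            triple = split_anterior_posterior(
                mask, p1, p1 + 3 * u[0], p1 + 3 * u[1], anterior_point=anterior_world
            )
            return triple

        t_axis = measure(np.eye(3))
        t_rot = measure(rot)
        assert t_rot.vol_t == pytest.approx(t_axis.vol_t, rel=0.02)
        assert t_rot.vol_p == pytest.approx(t_axis.vol_p, rel=0.02)
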
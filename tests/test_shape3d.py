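"""Visual-hull carving and 3D morphometrics against analytic solids."""

import numpy as np
import pytest

from seedtrack import shape3d, synthdata
from seedtrack.errors import (
    AmbiguityError,
    CarveFailureError,
    DegenerateShapeError,
    EmptyViewError,
)

from conftest import disk_image


class TestSegmentSilhouette:
    def test_backlit_disk_area_within_2pct(self):
        r = 15.0
        mask = shape3d.segment_silhouette(disk_image(radius=r))
        assert mask.sum() == pytest.approx(np.pi * r**2, rel=0.02)
        # single connected component
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == 1

    def test_uniform_background_is_empty_view(self):
        with pytest.raises(EmptyViewError):
            shape3d.segment_silhouette(np.full((50, 50), 220, dtype=np.uint8))

    def test_two_disks_ambiguous_with_count(self):
        img = disk_image(center=(25, 20), radius=10)
        img2 = disk_image(center=(55, 60), radius=10)
        img = np.minimum(img, img2)
        with pytest.raises(AmbiguityError) as exc:
            shape3d.segment_silhouette(img)
        assert exc.value.count == 2


class TestCarveHull:
    def test_sphere_volume_within_3pct(self, sphere_carve):
        _, hull, truth = sphere_carve
        assert hull.volume_nl == pytest.approx(truth.volume, rel=0.03)

    def test_reprojection_containment_every_view(self, sphere_carve):
        stack, hull, _ = sphere_carve
        for mask, angle in zip(stack.masks, stack.angles):
            proj = shape3d.project_hull(hull, angle, stack)
            assert not np.any(proj & ~mask), f"hull leaks outside view {angle}"

    def test_prolate_spheroid_volume(self):
        # axis of revolution parallel to the rotation axis: the visual
        # hull over a full turn equals the spheroid itself
        spec = synthdata.ShapeSpec(kind="ellipsoid", semi_axes=(0.155, 0.155, 0.25))
        stack, truth = synthdata.render_silhouettes(spec, pixel_size=5.0)
        hull = shape3d.carve_hull(stack, voxel_size=5.0)
        assert truth.volume == pytest.approx(25.2, abs=0.05)  # (4/3)π·abc
        assert hull.volume_nl == pytest.approx(truth.volume, rel=0.03)

    def test_two_orthogonal_squares_give_exact_prism(self):
        # voxel-aligned axis-parallel case: the hull is a rectangular
        # prism whose volume is exactly width × depth × height
        m0 = np.zeros((41, 41), bool)
        m90 = np.zeros((41, 41), bool)
        m0[16:26, 11:31] = True  # 20 px wide, 10 px tall
        m90[16:26, 15:27] = True  # 12 px wide
        stack = shape3d.SilhouetteStack([m0, m90], [0.0, 90.0], 10.0, rotation_axis=20.0)
        with pytest.warns(UserWarning, match="voxels along its shortest axis"):
            hull = shape3d.carve_hull(stack, voxel_size=10.0)
        assert hull.n_occupied == 20 * 12 * 10
        assert hull.volume_nl == pytest.approx(0.200 * 0.120 * 0.100 * 1000)

    def test_inconsistent_views_fail(self):
        m0 = np.zeros((41, 41), bool)
        m1 = np.zeros((41, 41), bool)
        m0[5:15, 5:15] = True  # top-left in one view
        m1[30:40, 30:40] = True  # bottom-right in the other: no common z rows
        with pytest.raises(CarveFailureError):
            shape3d.carve_hull(
                shape3d.SilhouetteStack([m0, m1], [0.0, 90.0], 10.0, rotation_axis=20.0),
                voxel_size=10.0,
            )

    def test_hull_overapproximates_and_refines_monotonically(self, sphere_carve):
        stack, _, truth = sphere_carve
        errs = []
        for vs in (20.0, 10.0, 5.0):
            hull = shape3d.carve_hull(stack, voxel_size=vs)
            err = hull.volume_nl / truth.volume - 1
            assert err >= -1e-3, "visual hull must not undercut the solid"
            errs.append(abs(err))
        assert errs[0] >= errs[1] >= errs[2] - 1e-6


class TestOcclusionExtrapolation:
    def test_truncated_sphere_recovered_within_2pct(self):
        spec = synthdata.ShapeSpec(kind="sphere", semi_axes=(0.25,) * 3,
                                   occluded_fraction=0.10)
        stack, truth = synthdata.render_silhouettes(spec, pixel_size=5.0)
        hull = shape3d.carve_hull(stack, voxel_size=5.0)
        assert hull.volume_nl < truth.volume  # truncation loses volume
        full = shape3d.extrapolate_occluded_cap(hull, stack.row_to_z(stack.occlusion_row))
        assert full.volume_nl == pytest.approx(truth.volume, rel=0.02)

    def test_half_truncated_ellipsoid_within_10pct(self):
        spec = synthdata.ShapeSpec(kind="ellipsoid", semi_axes=(0.155, 0.155, 0.25),
                                   occluded_fraction=0.5)
        stack, truth = synthdata.render_silhouettes(spec, pixel_size=5.0)
        hull = shape3d.carve_hull(stack, voxel_size=5.0)
        full = shape3d.extrapolate_occluded_cap(hull, stack.row_to_z(stack.occlusion_row))
        assert full.volume_nl == pytest.approx(truth.volume, rel=0.10)

    def test_superset_and_cap_only_above_plane(self):
        spec = synthdata.ShapeSpec(kind="sphere", semi_axes=(0.25,) * 3,
                                   occluded_fraction=0.10)
        stack, _ = synthdata.render_silhouettes(spec, pixel_size=5.0)
        hull = shape3d.carve_hull(stack, voxel_size=5.0)
        z_occ = stack.row_to_z(stack.occlusion_row)
        full = shape3d.extrapolate_occluded_cap(hull, z_occ)
        old = hull.occupancy
        assert np.all(full.occupancy[:, :, : old.shape[2]] | ~old), "hull must grow"
        added = full.occupancy.copy()
        added[:, :, : old.shape[2]] &= ~old
        zs = full.origin[2] + np.arange(full.occupancy.shape[2]) * full.voxel_size
        assert np.all(zs[np.nonzero(added)[2]] > z_occ)

    def test_untruncated_hull_is_noop_with_warning(self, sphere_carve):
        _, hull, _ = sphere_carve
        z_above = hull.origin[2] + (hull.occupancy.shape[2] + 10) * hull.voxel_size
        with pytest.warns(UserWarning, match="no occupied voxels near"):
            out = shape3d.extrapolate_occluded_cap(hull, z_above)
        assert out.n_occupied == hull.n_occupied


class TestMorphometrics:
    def test_sphere_identity(self, sphere_carve):
        _, hull, _ = sphere_carve
        m = shape3d.measure_morphometrics(hull)
        tol = (5.0 + 5.0) / 1000.0  # one voxel + one rendering pixel
        for v in (m.length, m.width, m.height):
            assert v == pytest.approx(0.50, abs=tol)
        assert m.sphericity == pytest.approx(100.0, abs=2.0)
        assert m.sphericity <= 100.0 + 0.5

    def test_triaxial_ellipsoid_extents(self, triaxial_carve):
        _, hull, truth = triaxial_carve
        m = shape3d.measure_morphometrics(hull)
        tol = (5.0 + 5.0) / 1000.0
        assert m.length == pytest.approx(0.50, abs=tol)
        assert m.width == pytest.approx(0.31, abs=tol)
        assert m.height == pytest.approx(0.27, abs=tol)
        assert m.length >= m.width >= m.height > 0
        assert m.volume == pytest.approx(truth.volume, rel=0.03)

    def test_unit_cube_sphericity(self):
        occ = np.ones((60, 60, 60), bool)
        m = shape3d.measure_morphometrics(shape3d.VoxelHull(occ, 5.0, np.zeros(3)))
        assert m.sphericity == pytest.approx(80.6, abs=2.0)

    def test_orientation_invariance(self, triaxial_carve):
        _, hull0, _ = triaxial_carve
        m0 = shape3d.measure_morphometrics(hull0)
        spec = synthdata.ShapeSpec(kind="ellipsoid", semi_axes=(0.25, 0.155, 0.135),
                                   orientation=(30.0, 25.0, 40.0))
        stack, _ = synthdata.render_silhouettes(spec, pixel_size=5.0)
        m1 = shape3d.measure_morphometrics(shape3d.carve_hull(stack, voxel_size=5.0))
        assert m1.volume == pytest.approx(m0.volume, rel=0.03)
        for a, b in ((m0.length, m1.length), (m0.width, m1.width), (m0.height, m1.height)):
            assert b == pytest.approx(a, abs=5.0 / 1000.0)

    def test_sphere_maximizes_sphericity(self, sphere_carve, triaxial_carve):
        _, sphere_hull, _ = sphere_carve
        _, ell_hull, _ = triaxial_carve
        cube = shape3d.VoxelHull(np.ones((50, 50, 50), bool), 5.0, np.zeros(3))
        s_sphere = shape3d.measure_morphometrics(sphere_hull).sphericity
        assert s_sphere > shape3d.measure_morphometrics(ell_hull).sphericity
        assert s_sphere > shape3d.measure_morphometrics(cube).sphericity

    @pytest.mark.parametrize("r_vox", [25, 40, 55])
    def test_surface_area_calibrated_on_spheres(self, r_vox):
        n = 2 * r_vox + 8
        ax = np.arange(n) - (n - 1) / 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        occ = X**2 + Y**2 + Z**2 <= r_vox**2
        hull = shape3d.VoxelHull(occ, 5.0, np.zeros(3))
        m = shape3d.measure_morphometrics(hull)
        true_mm2 = 4 * np.pi * (r_vox * 5.0 / 1000.0) ** 2
        assert m.surface_area == pytest.approx(true_mm2, rel=0.03)

    def test_single_voxel_is_degenerate(self):
        occ = np.zeros((5, 5, 5), bool)
        occ[2, 2, 2] = True
        with pytest.raises(DegenerateShapeError):
            shape3d.measure_morphometrics(shape3d.VoxelHull(occ, 5.0, np.zeros(3)))


class TestIO:
    def test_stack_roundtrip_and_csv(self, tmp_path):
        import imageio.v3 as iio
        import json
        import pandas as pd

        spec = synthdata.ShapeSpec(kind="sphere", semi_axes=(0.1,) * 3)
        stack, _ = synthdata.render_silhouettes(spec, angles=[0.0, 90.0, 180.0],
                                                pixel_size=10.0)
        d = tmp_path / "stack"
        d.mkdir()
        for i, m in enumerate(stack.masks):
            iio.imwrite(d / f"v{i:02d}.png", (m * 255).astype(np.uint8))
        (d / "stack.json").write_text(json.dumps({
            "angles": stack.angles.tolist(), "pixel_size": stack.pixel_size,
            "rotation_axis": stack.rotation_axis,
        }))
        back = shape3d.read_stack(d)
        assert all(np.array_equal(a, b) for a, b in zip(back.masks, stack.masks))
        assert back.pixel_size == stack.pixel_size

        hull = shape3d.carve_hull(back, voxel_size=10.0)
        m = shape3d.measure_morphometrics(hull)
        csv = tmp_path / "traits.csv"
        shape3d.write_morphometrics_csv({"S-0001": m}, csv)
        df = pd.read_csv(csv)
        assert df.loc[0, "seed_id"] == "S-0001"
        assert df.loc[0, "volume_nl"] == pytest.approx(m.volume)

    def test_mesh_export(self, tmp_path, sphere_carve):
        import trimesh

        _, hull, truth = sphere_carve
        path = tmp_path / "hull.ply"
        shape3d.export_mesh(hull, path)
        mesh = trimesh.load(path)
        assert mesh.volume == pytest.approx(truth.volume / 1000.0, rel=0.05)  # mm³
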
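
import numpy as np
import pytest

import conefdk as cf
from reference_impl import backproject_view_reference, fdk_reference


@pytest.fixture(scope="module")
def oracle_geom():
    return cf.ConeBeamGeometry(
        dso=60.0, dsd=110.0, angles=cf.make_uniform_angles(5, start=0.2),
        det_rows=8, det_cols=8, det_spacing_u=4.0, det_spacing_v=4.0,
        det_offset_u=0.5, det_offset_v=-1.0,
    )


class TestBackprojectView:
    def test_zero_projection_leaves_volume_unchanged(self, oracle_geom):
        grid = cf.VolumeGrid(5, 5, 3)
        vol = cf.Volume.zeros(grid)
        before = vol.values.copy()
        cf.backproject_view(vol, np.zeros((8, 8)), oracle_geom, 0.2)
        np.testing.assert_array_equal(vol.values, before)

    def test_matches_triple_loop_reference(self, oracle_geom, rng):
        """Vectorized accumulation equals a literal scalar triple loop."""
        grid = cf.VolumeGrid(5, 5, 3, dx=6.0, dy=6.0, dz=6.0)
        q = rng.normal(size=(8, 8))
        vol = cf.Volume.zeros(grid)
        scale = 0.37
        cf.backproject_view(vol, q, oracle_geom, 0.9, scale=scale)
        ref = np.zeros(grid.shape)
        backproject_view_reference(ref, grid, oracle_geom, q, 0.9, scale)
        np.testing.assert_allclose(vol.values, ref, rtol=1e-6, atol=1e-9)

    def test_single_pixel_footprint_follows_the_ray(self, oracle_geom):
        """A lone detector pixel backprojects onto (a tube around) its ray."""
        grid = cf.VolumeGrid(16, 16, 16, dx=2.0, dy=2.0, dz=2.0)
        q = np.zeros((8, 8))
        q[5, 2] = 1.0
        angle = 0.2
        vol = cf.Volume.zeros(grid)
        cf.backproject_view(vol, q, oracle_geom, angle, scale=1.0)
        hit = np.argwhere(vol.values != 0)
        assert hit.size > 0
        centers = grid.voxel_centers()
        for i, j, k in hit:
            u, v, _ = cf.voxel_to_detector(oracle_geom, centers[i, j, k], angle)
            iu, iv = oracle_geom.detector_index(u, v)
            # every touched voxel projects within one interpolation cell
            assert abs(iu - 2) < 1.0 and abs(iv - 5) < 1.0

    def test_behind_source_voxels_are_skipped(self):
        geom = cf.ConeBeamGeometry(dso=5.0, dsd=10.0, angles=[0.0], det_rows=4,
                                   det_cols=4, det_spacing_u=4, det_spacing_v=4)
        grid = cf.VolumeGrid(9, 3, 3, dx=2.0)  # x spans -8..8, beyond the source
        vol = cf.Volume.zeros(grid)
        n_skipped = cf.backproject_view(vol, np.ones((4, 4)), geom, 0.0)
        assert n_skipped > 0
        assert np.all(np.isfinite(vol.values))


class TestFdkReconstruct:
    def test_zero_stack_gives_zero_volume(self, oracle_geom):
        stack = cf.ProjectionStack(oracle_geom, np.zeros((5, 8, 8)))
        vol = cf.fdk_reconstruct(stack, cf.VolumeGrid(6, 6, 4))
        assert np.all(vol.values == 0.0)

    def test_canonical_shape_contract(self, head_stack, canonical_grid):
        vol = cf.fdk_reconstruct(head_stack, canonical_grid)
        assert vol.values.shape == (64, 60, 50)

    def test_matches_reference_pipeline(self, rng):
        """Full pipeline equals the scalar reference on a small instance."""
        geom = cf.ConeBeamGeometry(
            dso=70.0, dsd=130.0, angles=cf.make_uniform_angles(36),
            det_rows=16, det_cols=16, det_spacing_u=3.0, det_spacing_v=3.0,
        )
        phantom = cf.EllipsoidPhantom([
            cf.Ellipsoid((4, -2, 1), (8, 6, 7), 0.3, 1.0),
            cf.Ellipsoid((-5, 3, -2), (4, 5, 4), 0.0, -0.5),
        ])
        stack = cf.project_phantom(phantom, geom)
        grid = cf.VolumeGrid(12, 12, 12, dx=2.5, dy=2.5, dz=2.5)
        spec = cf.FilterSpec(pad_length=64)
        vol = cf.fdk_reconstruct(stack, grid, cf.ReconConfig(filter=spec))
        H = cf.ramp_kernel(spec, geom.det_spacing_u)
        ref = fdk_reference(stack, grid, H)
        np.testing.assert_allclose(vol.values, ref,
                                   atol=1e-5 * np.abs(ref).max())

    def test_pipeline_linearity(self, oracle_geom, rng):
        data = rng.normal(size=(5, 8, 8))
        grid = cf.VolumeGrid(6, 6, 4)
        v1 = cf.fdk_reconstruct(cf.ProjectionStack(oracle_geom, data), grid)
        v3 = cf.fdk_reconstruct(cf.ProjectionStack(oracle_geom, 3.0 * data), grid)
        np.testing.assert_allclose(v3.values, 3.0 * v1.values,
                                   atol=1e-10 * np.abs(v1.values).max())

    def test_rotation_consistency(self):
        """Rotating the object = cyclically shifting the projection stack.

        With 8 uniform views, rotating the phantom by two angular steps (90
        degrees) must (a) cyclically shift the stack by two views and (b)
        rotate the reconstruction by a quarter turn in the xy-plane, which on
        a centered square grid is an exact array rotation.
        """
        K = 8
        geom = cf.ConeBeamGeometry(
            dso=250, dsd=500, angles=cf.make_uniform_angles(K), det_rows=33,
            det_cols=48, det_spacing_u=2.0, det_spacing_v=2.0,
        )
        grid = cf.VolumeGrid(24, 24, 8)
        phantom = cf.EllipsoidPhantom([
            cf.Ellipsoid((6, 2, 0), (4, 3, 3), 0.3, 1.0),
            cf.Ellipsoid((-3, -5, 1), (3, 5, 2), 0.0, 0.5),
        ])
        c, s = 0.0, 1.0  # rotation by +90 degrees
        rotated = cf.EllipsoidPhantom([
            cf.Ellipsoid(
                (c * e.center[0] - s * e.center[1],
                 s * e.center[0] + c * e.center[1], e.center[2]),
                e.semi_axes, e.z_rotation + np.pi / 2, e.density)
            for e in phantom.ellipsoids
        ])
        stack = cf.project_phantom(phantom, geom)
        stack_rot = cf.project_phantom(rotated, geom)
        np.testing.assert_allclose(stack_rot.data, np.roll(stack.data, 2, axis=0),
                                   atol=1e-9)
        vol = cf.fdk_reconstruct(stack, grid)
        vol_rot = cf.fdk_reconstruct(stack_rot, grid)
        np.testing.assert_allclose(
            vol_rot.values, np.rot90(vol.values, k=1, axes=(0, 1)), atol=1e-9
        )

    def test_density_recovery_uniform_sphere(self, sphere_recon, canonical_grid):
        """A unit-density sphere reconstructs to ~1 inside, ~0 outside."""
        R, vol = sphere_recon
        xs, ys, zs = canonical_grid.axis_coords()
        kz = int(np.argmin(np.abs(zs)))  # central slice
        sl = vol.values[:, :, kz]
        Rxy = np.hypot(xs[:, None], ys[None, :])
        center = sl[Rxy < 2.0].mean()
        assert center == pytest.approx(1.0, abs=0.05)
        # background: inside the fully-sampled field of view, excluding a
        # 2-voxel band at the sphere boundary
        fov_radius = min(canonical_grid.nx, canonical_grid.ny) / 2.0
        bg = sl[(Rxy > R + 2.0) & (Rxy < fov_radius - 2.0)]
        assert np.max(np.abs(bg)) < 0.05

    def test_parallel_beam_limit(self):
        """At dso, dsd -> x100 the central slice matches a 2D parallel FBP.

        The independent reference is scikit-image's iradon applied to the
        analytic parallel sinogram of the same disk.
        """
        from skimage.transform import iradon

        R = 12.0
        n = 64
        n_views = 120
        mag = 2.0
        geom = cf.ConeBeamGeometry(
            dso=25000.0, dsd=25000.0 * mag,
            angles=cf.make_uniform_angles(n_views, arc=2 * np.pi),
            det_rows=17, det_cols=n, det_spacing_u=mag, det_spacing_v=mag,
        )
        sphere = cf.EllipsoidPhantom([cf.Ellipsoid((0, 0, 0), (R, R, R))])
        grid = cf.VolumeGrid(n, n, 5)
        vol = cf.fdk_reconstruct(cf.project_phantom(sphere, geom), grid)
        central = vol.values[:, :, 2]

        # analytic parallel-beam sinogram of the disk, 1-unit bins
        s = (np.arange(n) - (n - 1) / 2.0)
        chord = 2.0 * np.sqrt(np.clip(R**2 - s**2, 0.0, None))
        theta_deg = np.degrees(cf.make_uniform_angles(n_views, arc=np.pi))
        sino = np.tile(chord[:, None], (1, n_views))
        ref = iradon(sino, theta=theta_deg, filter_name="ramp",
                     output_size=n, circle=False)
        interior = np.hypot(*np.meshgrid(s, s, indexing="ij")) < R - 2
        rmse = np.sqrt(np.mean((central[interior] - ref.T[interior]) ** 2))
        assert rmse < 0.02

    def test_short_scan_warns(self, rng):
        geom = cf.ConeBeamGeometry(
            dso=60, dsd=110, angles=cf.make_uniform_angles(10, arc=np.pi),
            det_rows=8, det_cols=8, det_spacing_u=4, det_spacing_v=4,
        )
        stack = cf.ProjectionStack(geom, rng.normal(size=(10, 8, 8)))
        with pytest.warns(UserWarning, match="short-scan"):
            cf.fdk_reconstruct(stack, cf.VolumeGrid(4, 4, 4))

    def test_nan_input_names_offending_view(self, oracle_geom):
        data = np.zeros((5, 8, 8))
        data[3, 2, 2] = np.nan
        with pytest.raises(ValueError, match="view 3"):
            cf.fdk_reconstruct(cf.ProjectionStack(oracle_geom, data),
                               cf.VolumeGrid(4, 4, 4))

    def test_single_vs_double_precision_agreement(self, head_stack, canonical_grid):
        """Single- and double-precision runs differ by <= 2.2e-3 max-abs."""
        vd = cf.fdk_reconstruct(head_stack, canonical_grid,
                                cf.ReconConfig(precision="double"))
        vs = cf.fdk_reconstruct(head_stack, canonical_grid,
                                cf.ReconConfig(precision="single"))
        assert vs.values.dtype == np.float32
        diff = cf.compare_volumes(vs.astype("double"), vd)
        assert diff["max_abs_diff"] <= 2.2e-3


class TestCompareVolumes:
    def test_identical_volumes(self, canonical_grid, rng):
        vol = cf.Volume(canonical_grid, rng.normal(size=canonical_grid.shape))
        out = cf.compare_volumes(vol, vol)
        assert out["max_abs_diff"] == 0.0
        assert out["rmse"] == 0.0

    def test_constant_offset(self, rng):
        grid = cf.VolumeGrid(4, 4, 4)
        a = cf.Volume(grid, rng.normal(size=grid.shape))
        b = cf.Volume(grid, a.values + 0.5)
        out = cf.compare_volumes(b, a)
        assert out["max_abs_diff"] == pytest.approx(0.5)
        assert out["rmse"] == pytest.approx(0.5)
        np.testing.assert_allclose(out["diff"].values, 0.5)

    def test_grid_mismatch_rejected(self, rng):
        a = cf.Volume.zeros(cf.VolumeGrid(4, 4, 4))
        b = cf.Volume.zeros(cf.VolumeGrid(4, 4, 5))
        with pytest.raises(ValueError):
            cf.compare_volumes(a, b)
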
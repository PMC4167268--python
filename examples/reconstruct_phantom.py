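"""End-to-end reconstruction of the built-in head phantom.

Simulates the canonical scan (64 x 60 detector, 72 views on a full circular
orbit), reconstructs the 64 x 60 x 50 volume with the FDK pipeline, and
compares it against the analytically voxelized ground truth.
"""


import conefdk as cf

phantom = cf.shepp_logan_3d()
geom = cf.phantom_scan_geometry()
grid = cf.phantom_volume_grid()

stack = cf.project_phantom(phantom, geom)
volume = cf.fdk_reconstruct(stack, grid)
truth = cf.voxelize_phantom(phantom, grid, supersample=2)
metrics = cf.compare_volumes(volume, truth)

kz = grid.nz // 2
print(f"projection stack shape : {stack.data.shape}   (views, det rows, det cols)")
print(f"reconstructed volume   : {volume.values.shape}")
print(f"rmse vs ground truth   : {metrics['rmse']:.4f}")
print(f"center voxel: recon {volume.values[32, 30, kz]:.4f}  truth {truth.values[32, 30, kz]:.4f}")
print(f"central-slice value range: {volume.values[:, :, kz].min():.3f}"
      f" .. {volume.values[:, :, kz].max():.3f}")
# The center voxel sits inside the 'brain' tissue of the phantom whose
# additive density is 2.0 - 0.98 = 1.02; a faithful reconstruction recovers
# that absolute value to within a few percent, and the global rmse is
# dominated by ringing at the sharp ellipsoid boundaries.
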
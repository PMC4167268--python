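"""Reconstruction from noisy projections with an apodized ramp.

Adds Gaussian noise to the simulated projections and compares plain-ramp
against Hann-windowed reconstructions — the classic resolution/noise
trade-off of filtered backprojection.
"""


import conefdk as cf

geom = cf.phantom_scan_geometry()
grid = cf.phantom_volume_grid()
phantom = cf.shepp_logan_3d()
truth = cf.voxelize_phantom(phantom, grid, supersample=2)

clean = cf.project_phantom(phantom, geom)
noisy = cf.add_noise(clean, noise_sd=2.0, seed=11)

for window in ("ramp", "hann"):
    config = cf.ReconConfig(filter=cf.FilterSpec(window=window))
    vol = cf.fdk_reconstruct(noisy, grid, config)
    err = cf.compare_volumes(vol, truth)
    print(f"window={window:5s}  rmse vs truth {err['rmse']:.4f}")
# With noisy data the Hann window lowers the error by suppressing amplified
# high-frequency noise, at the cost of softer edges; on noiseless data the
# plain ramp would win.
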
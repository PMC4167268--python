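import numpy as np
import pytest

import conefdk as cf


@pytest.fixture(scope="session")
def canonical_geom():
    """Canonical phantom scan: 64 x 60 detector, 72 views."""
    return cf.phantom_scan_geometry()


@pytest.fixture(scope="session")
def canonical_grid():
    return cf.phantom_volume_grid()


@pytest.fixture(scope="session")
def head_phantom():
    return cf.shepp_logan_3d()


@pytest.fixture(scope="session")
def head_stack(head_phantom, canonical_geom):
    """Projections of the default head phantom at the canonical geometry."""
    return cf.project_phantom(head_phantom, canonical_geom)


@pytest.fixture(scope="session")
def sphere_recon(canonical_geom, canonical_grid):
    """Reconstruction of the centered uniform sphere (radius 25% of FOV)."""
    R = 0.25 * canonical_grid.nx  # 16 units
    sphere = cf.EllipsoidPhantom([cf.Ellipsoid((0, 0, 0), (R, R, R), 0.0, 1.0)])
    stack = cf.project_phantom(sphere, canonical_geom)
    vol = cf.fdk_reconstruct(stack, canonical_grid)
    return R, vol


@pytest.fixture(scope="session")
def small_geom():
    """A small asymmetric geometry for oracle comparisons."""
    return cf.ConeBeamGeometry(
        dso=80.0,
        dsd=150.0,
        angles=cf.make_uniform_angles(5, start=0.3),
        det_rows=8,
        det_cols=8,
        det_spacing_u=3.0,
        det_spacing_v=2.5,
        det_offset_u=1.0,
        det_offset_v=-0.5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
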
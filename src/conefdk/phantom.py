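"""Analytic ellipsoid phantoms and exact cone-beam forward projection.

The synthetic-data factory for the whole package: phantoms are unions of
ellipsoids with *additive* densities, so every cone-beam line integral has a
closed form (a sum of density-weighted chord lengths) and every pipeline stage
can be validated without scanner data.

The canonical test object is a 3-D Shepp-Logan-style head phantom (ten
ellipsoids, densities in [0, 2], built from the classic table of semi-axes and
additive densities).  The phantom the original experiment used is not
published; this one is an explicit stand-in with the same role — a smooth
piecewise-constant object with fine low-contrast structure.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .containers import PRECISION_DTYPES, ProjectionStack, Volume
from .geometry import ConeBeamGeometry, VolumeGrid, make_uniform_angles

__all__ = [
    "Ellipsoid",
    "EllipsoidPhantom",
    "ray_ellipsoid_chord",
    "project_phantom",
    "voxelize_phantom",
    "add_noise",
    "shepp_logan_3d",
    "phantom_scan_geometry",
    "phantom_volume_grid",
]


@dataclass(frozen=True)
class Ellipsoid:
    """One ellipsoid: center, semi-axes (a, b, c), rotation about z, density.

    The density is *additive*: where ellipsoids overlap their densities sum,
    which is how nested structures (e.g. a skull shell with a darker interior)
    are built from positive and negative terms.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    z_rotation: float = 0.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be 3-vectors")
        if min(self.semi_axes) <= 0:
            raise ValueError(f"semi-axes must be strictly positive, got {self.semi_axes}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))

    def _to_unit_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the frame where the ellipsoid is a unit sphere."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.z_rotation), np.sin(self.z_rotation)
        # inverse (transpose) of the z-rotation, then axis scaling
        q = np.empty_like(p)
        q[..., 0] = (c * p[..., 0] + s * p[..., 1]) / self.semi_axes[0]
        q[..., 1] = (-s * p[..., 0] + c * p[..., 1]) / self.semi_axes[1]
        q[..., 2] = p[..., 2] / self.semi_axes[2]
        return q

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside or on the ellipsoid."""
        q = self._to_unit_frame(points)
        return np.einsum("...i,...i->...", q, q) <= 1.0

    def chords(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Euclidean intersection lengths for a batch of rays (0 on miss)."""
        o = self._to_unit_frame(origins)
        d = np.asarray(directions, dtype=float)
        norm = np.linalg.norm(d, axis=-1)
        if np.any(norm < 1e-12):
            raise ValueError("ray direction must be non-zero")
        c, s = np.cos(self.z_rotation), np.sin(self.z_rotation)
        dd = np.empty_like(d)
        dd[..., 0] = (c * d[..., 0] + s * d[..., 1]) / self.semi_axes[0]
        dd[..., 1] = (-s * d[..., 0] + c * d[..., 1]) / self.semi_axes[1]
        dd[..., 2] = d[..., 2] / self.semi_axes[2]
        # |o + lam * dd|^2 = 1  ->  A lam^2 + 2 B lam + C = 0
        A = np.einsum("...i,...i->...", dd, dd)
        B = np.einsum("...i,...i->...", o, dd)
        C = np.einsum("...i,...i->...", o, o) - 1.0
        disc = B * B - A * C
        lam_span = np.where(disc > 0, 2.0 * np.sqrt(np.maximum(disc, 0.0)) / A, 0.0)
        return lam_span * norm


class EllipsoidPhantom:
    """A phantom defined as a list of ellipsoids with additive densities."""

    def __init__(self, ellipsoids: Iterable[Ellipsoid] = ()) -> None:
        self.ellipsoids: list[Ellipsoid] = list(ellipsoids)

    def __len__(self) -> int:
        return len(self.ellipsoids)

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Total density at world points: sum over containing ellipsoids."""
        p = np.asarray(points, dtype=float)
        total = np.zeros(p.shape[:-1], dtype=float)
        for e in self.ellipsoids:
            total += e.density * e.contains(p)
        return total

    # -- text-table serialization ------------------------------------------
    # one ellipsoid per row: cx cy cz a b c phi_deg density

    @classmethod
    def from_table(cls, source: str | Path) -> "EllipsoidPhantom":
        """Load from a whitespace-delimited text table (``#`` comments)."""
        if isinstance(source, Path):
            text = source.read_text()
        elif "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = source
        rows = np.atleast_2d(np.loadtxt(_io.StringIO(text), comments="#"))
        if rows.size == 0:
            return cls([])
        if rows.shape[1] != 8:
            raise ValueError(
                f"phantom table needs 8 columns (cx cy cz a b c phi_deg density), got {rows.shape[1]}"
            )
        return cls(
            Ellipsoid(
                center=tuple(r[0:3]),
                semi_axes=tuple(r[3:6]),
                z_rotation=float(np.radians(r[6])),
                density=float(r[7]),
            )
            for r in rows
        )

    def to_table(self) -> str:
        lines = ["# cx cy cz a b c phi_deg density"]
        for e in self.ellipsoids:
            lines.append(
                " ".join(
                    f"{x:.9g}"
                    for x in (*e.center, *e.semi_axes, np.degrees(e.z_rotation), e.density)
                )
            )
        return "\n".join(lines) + "\n"


def ray_ellipsoid_chord(
    ellipsoid: Ellipsoid, ray_origin: Sequence[float], ray_dir: Sequence[float]
) -> float:
    """Length of the intersection of a ray (full line) with an ellipsoid.

    Solves the quadratic obtained by mapping the line into the frame where
    the ellipsoid is the unit sphere; returns 0 if the line misses.
    ``ray_dir`` must be non-zero (unit length by convention).
    """
    return float(
        ellipsoid.chords(np.asarray(ray_origin, float), np.asarray(ray_dir, float))
    )


def _detector_grid_world(geom: ConeBeamGeometry, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Source position and world coordinates of all detector pixel centers."""
    src = geom.source_position(angle)
    c_hat = np.array([np.cos(angle), np.sin(angle), 0.0])   # source -> origin
    t_hat = np.array([-np.sin(angle), np.cos(angle), 0.0])  # detector +u
    z_hat = np.array([0.0, 0.0, 1.0])                       # detector +v
    u = geom.u_coords()
    v = geom.v_coords()
    U, V = np.meshgrid(u, v)  # (det_rows, det_cols)
    pix = (
        src
        + geom.dsd * c_hat
        + U[..., None] * t_hat
        + V[..., None] * z_hat
    )
    return src, pix


def project_phantom(
    phantom: EllipsoidPhantom, geom: ConeBeamGeometry, precision: str = "double"
) -> ProjectionStack:
    """Exact cone-beam projections of a phantom: one ray per pixel center.

    For each view angle and each detector pixel, the ray from the source
    through the pixel center is intersected analytically with every
    ellipsoid; the projection value is sum(density * chord).  Deterministic,
    no discretization beyond pixel-center sampling.
    """
    data = np.zeros((geom.n_angles, geom.det_rows, geom.det_cols), dtype=float)
    for n, angle in enumerate(geom.angles):
        src, pix = _detector_grid_world(geom, angle)
        dirs = pix - src
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        origins = np.broadcast_to(src, dirs.shape)
        for e in phantom.ellipsoids:
            data[n] += e.density * e.chords(origins, dirs)
    return ProjectionStack(geom, data.astype(PRECISION_DTYPES[precision]), stage="raw")


def voxelize_phantom(
    phantom: EllipsoidPhantom, grid: VolumeGrid, supersample: int = 1
) -> Volume:
    """Ground-truth volume: mean density over supersample^3 points per voxel."""
    if int(supersample) != supersample or supersample < 1:
        raise ValueError(f"supersample must be a positive integer, got {supersample!r}")
    ss = int(supersample)
    centers = grid.voxel_centers()
    acc = np.zeros(grid.shape, dtype=float)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    spacing = np.array([grid.dx, grid.dy, grid.dz])
    for ox in offs:
        for oy in offs:
            for oz in offs:
                acc += phantom.density_at(centers + np.array([ox, oy, oz]) * spacing)
    return Volume(grid, acc / ss**3)


def add_noise(stack: ProjectionStack, noise_sd: float, seed: int) -> ProjectionStack:
    """Add i.i.d. Gaussian noise to a projection stack (reproducible by seed)."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return stack.with_data(stack.data.copy(), stack.stage)
    rng = np.random.default_rng(seed)
    noisy = stack.data + rng.normal(0.0, noise_sd, size=stack.data.shape).astype(
        stack.data.dtype, copy=False
    )
    return stack.with_data(noisy.astype(stack.data.dtype, copy=False), stack.stage)


# ---------------------------------------------------------------------------
# Canonical study configuration: Shepp-Logan-style phantom + scan geometry
# ---------------------------------------------------------------------------

# classic 3-D head-phantom table: density, semi-axes (a b c), center, phi(deg)
_SHEPP_LOGAN_3D = [
    # rho      a       b      c      x0      y0      z0     phi
    (2.00, 0.6900, 0.920, 0.900, 0.000, 0.000, 0.000, 0.0),
    (-0.98, 0.6624, 0.874, 0.880, 0.000, -0.0184, 0.000, 0.0),
    (-0.02, 0.4100, 0.160, 0.210, -0.220, 0.000, -0.250, 108.0),
    (-0.02, 0.3100, 0.110, 0.220, 0.220, 0.000, -0.250, 72.0),
    (0.02, 0.2100, 0.250, 0.500, 0.000, 0.350, -0.250, 0.0),
    (0.02, 0.0460, 0.046, 0.046, 0.000, 0.100, -0.250, 0.0),
    (0.01, 0.0460, 0.023, 0.020, -0.080, -0.605, -0.250, 0.0),
    (0.01, 0.0460, 0.023, 0.020, 0.060, -0.605, -0.250, 0.0),
    (0.02, 0.0560, 0.040, 0.100, 0.060, -0.105, 0.625, 0.0),
    (-0.02, 0.0560, 0.056, 0.100, 0.000, 0.100, 0.625, 0.0),
]


def shepp_logan_3d(scale: float = 26.0) -> EllipsoidPhantom:
    """The default ten-ellipsoid head phantom, scaled to physical units.

    ``scale`` is the half-extent (same length unit as the geometry) that the
    unit phantom is stretched to; the default 26 places the object comfortably
    inside the canonical 64 x 60 x 50 voxel field of view at 1 unit/voxel.
    """
    return EllipsoidPhantom(
        Ellipsoid(
            center=(x0 * scale, y0 * scale, z0 * scale),
            semi_axes=(a * scale, b * scale, c * scale),
            z_rotation=float(np.radians(phi)),
            density=rho,
        )
        for rho, a, b, c, x0, y0, z0, phi in _SHEPP_LOGAN_3D
    )


def phantom_scan_geometry(
    n_angles: int = 72,
    det_rows: int = 60,
    det_cols: int = 64,
    dso: float = 250.0,
    dsd: float = 500.0,
    det_spacing: float = 2.0,
) -> ConeBeamGeometry:
    """The canonical phantom-experiment scan: 64 x 60 detector, 72 views.

    Magnification 2 with 2-unit detector pixels gives 1-unit sampling on the
    central plane, matching the 1-unit voxels of :func:`phantom_volume_grid`.
    """
    return ConeBeamGeometry(
        dso=dso,
        dsd=dsd,
        angles=make_uniform_angles(n_angles),
        det_rows=det_rows,
        det_cols=det_cols,
        det_spacing_u=det_spacing,
        det_spacing_v=det_spacing,
    )


def phantom_volume_grid(nx: int = 64, ny: int = 60, nz: int = 50) -> VolumeGrid:
    """The canonical 64 x 60 x 50 reconstruction grid, 1-unit voxels, centered."""
    return VolumeGrid(nx=nx, ny=ny, nz=nz)
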
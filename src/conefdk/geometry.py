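"""Circular-orbit cone-beam scan geometry and the voxel -> detector mapping.

Coordinate convention (fixed once, used everywhere)
---------------------------------------------------
World coordinates are right-handed with the rotation axis along *z* and the
orbit center at the origin.  At view angle ``theta = 0`` the X-ray source sits
at ``(-dso, 0, 0)`` looking along ``+x``; angles increase counter-clockwise in
the xy-plane seen from ``+z``.  The flat detector is perpendicular to the
central ray at distance ``dsd`` from the source, its ``u`` axis transverse
(``+y`` at ``theta = 0``) and its ``v`` axis parallel to ``z``.

For a world point ``(x, y, z)`` at view angle ``theta`` define

    s = -(x cos(theta) + y sin(theta))     # signed distance toward the source
    t = -x sin(theta) + y cos(theta)       # transverse in-plane coordinate

and the mapping to physical detector coordinates (relative to the central ray)

    u  = dsd * t / (dso - s)
    v  = dsd * z / (dso - s)
    w2 = dso**2 / (dso - s)**2             # cone-beam distance weight

``w2`` is the per-voxel divergence weight applied during backprojection.
Points with ``dso - s <= 0`` lie at or behind the source and have no valid
projection; they are flagged with NaN and must be skipped by callers.

Physical detector coordinates convert to fractional pixel indices with
pixel-center alignment: ``index = (coord - offset) / spacing + (N - 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "ConeBeamGeometry",
    "VolumeGrid",
    "make_uniform_angles",
    "voxel_to_detector",
]


def make_uniform_angles(
    n_angles: int, arc: float = 2.0 * np.pi, start: float = 0.0
) -> np.ndarray:
    """Uniformly spaced view angles over an arc, endpoint excluded.

    Returns ``start + n * (arc / n_angles)`` for ``n = 0 .. n_angles - 1`` so
    that a full 360-degree scan does not sample 0 and 2*pi twice.

    Parameters
    ----------
    n_angles : number of source positions K (>= 1).
    arc : angular span in radians (> 0); 2*pi for a full scan.
    start : angle of the first view in radians.
    """
    if int(n_angles) != n_angles or n_angles < 1:
        raise ValueError(f"n_angles must be a positive integer, got {n_angles!r}")
    if not arc > 0:
        raise ValueError(f"arc must be positive, got {arc!r}")
    return start + np.arange(int(n_angles)) * (arc / n_angles)


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular-orbit cone-beam scan description.

    Parameters
    ----------
    dso : distance from source to orbit center / volume origin (> 0).
    dsd : distance from source to detector plane (>= dso).
    angles : view angles theta_n in radians, one per projection.
    det_rows, det_cols : detector grid size (v and u directions).
    det_spacing_u, det_spacing_v : detector pixel pitch, same length unit
        as ``dso``/``dsd``.
    det_offset_u, det_offset_v : offset of the detector center from the
        central ray, physical units.
    """

    dso: float
    dsd: float
    angles: np.ndarray
    det_rows: int
    det_cols: int
    det_spacing_u: float
    det_spacing_v: float
    det_offset_u: float = 0.0
    det_offset_v: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.atleast_1d(np.asarray(self.angles, dtype=float)))
        if not self.dso > 0:
            raise ValueError(f"dso must be positive, got {self.dso}")
        if not self.dsd >= self.dso:
            raise ValueError(f"dsd ({self.dsd}) must be >= dso ({self.dso})")
        if self.angles.ndim != 1 or self.angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError("detector dimensions must be >= 1")
        if not (self.det_spacing_u > 0 and self.det_spacing_v > 0):
            raise ValueError("detector spacings must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def orbit_radius(self) -> float:
        """Radius of the circular source orbit (equals dso)."""
        return self.dso

    @property
    def magnification(self) -> float:
        """Geometric magnification dsd / dso at the orbit center."""
        return self.dsd / self.dso

    @property
    def angle_spacing(self) -> float:
        """Uniform angular step between consecutive views (radians)."""
        if self.n_angles == 1:
            return 2.0 * np.pi
        steps = np.diff(self.angles)
        if np.ptp(steps) > 1e-12:
            raise ValueError("angles are not uniformly spaced")
        return float(steps[0])

    def source_position(self, angle: float) -> np.ndarray:
        """World position of the X-ray source at a view angle."""
        return np.array([-self.dso * np.cos(angle), -self.dso * np.sin(angle), 0.0])

    def u_coords(self) -> np.ndarray:
        """Physical u coordinate of each detector column center."""
        k = np.arange(self.det_cols)
        return (k - (self.det_cols - 1) / 2.0) * self.det_spacing_u + self.det_offset_u

    def v_coords(self) -> np.ndarray:
        """Physical v coordinate of each detector row center."""
        k = np.arange(self.det_rows)
        return (k - (self.det_rows - 1) / 2.0) * self.det_spacing_v + self.det_offset_v

    def detector_index(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (column, row) pixel indices for physical (u, v)."""
        iu = (np.asarray(u) - self.det_offset_u) / self.det_spacing_u + (self.det_cols - 1) / 2.0
        iv = (np.asarray(v) - self.det_offset_v) / self.det_spacing_v + (self.det_rows - 1) / 2.0
        return iu, iv

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Flat key-value block suitable for a YAML/JSON config file."""
        d: dict[str, Any] = {
            "dso": float(self.dso),
            "dsd": float(self.dsd),
            "det_rows": int(self.det_rows),
            "det_cols": int(self.det_cols),
            "det_spacing_u": float(self.det_spacing_u),
            "det_spacing_v": float(self.det_spacing_v),
            "det_offset_u": float(self.det_offset_u),
            "det_offset_v": float(self.det_offset_v),
            "angles_deg": [float(a) for a in np.degrees(self.angles)],
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ConeBeamGeometry":
        """Build a geometry from a flat config block.

        Angles are given either explicitly as ``angles_deg`` (a list) or
        generated from ``n_angles`` with optional ``arc_deg`` (default 360)
        and ``start_deg`` (default 0).
        """
        if "angles_deg" in d:
            angles = np.radians(np.asarray(d["angles_deg"], dtype=float))
        elif "n_angles" in d:
            angles = make_uniform_angles(
                int(d["n_angles"]),
                arc=np.radians(float(d.get("arc_deg", 360.0))),
                start=np.radians(float(d.get("start_deg", 0.0))),
            )
        else:
            raise ValueError("geometry config needs 'angles_deg' or 'n_angles'")
        return cls(
            dso=float(d["dso"]),
            dsd=float(d["dsd"]),
            angles=angles,
            det_rows=int(d["det_rows"]),
            det_cols=int(d["det_cols"]),
            det_spacing_u=float(d["det_spacing_u"]),
            det_spacing_v=float(d["det_spacing_v"]),
            det_offset_u=float(d.get("det_offset_u", 0.0)),
            det_offset_v=float(d.get("det_offset_v", 0.0)),
        )


@dataclass(frozen=True)
class VolumeGrid:
    """The reconstruction target lattice.

    Voxel ``(i, j, k)`` has world coordinate ``origin + (i*dx, j*dy, k*dz)``;
    ``origin`` is the world position of the *center* of voxel ``(0, 0, 0)``.
    """

    nx: int
    ny: int
    nz: int
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.origin is None:
            # default: grid centered on the world origin
            object.__setattr__(
                self,
                "origin",
                (
                    -(self.nx - 1) / 2.0 * self.dx,
                    -(self.ny - 1) / 2.0 * self.dy,
                    -(self.nz - 1) / 2.0 * self.dz,
                ),
            )
        else:
            object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))
            if len(self.origin) != 3:
                raise ValueError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        ox, oy, oz = self.origin
        return (
            ox + np.arange(self.nx) * self.dx,
            oy + np.arange(self.ny) * self.dy,
            oz + np.arange(self.nz) * self.dz,
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel center coordinates, shape (nx, ny, nz, 3)."""
        xs, ys, zs = self.axis_coords()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def to_dict(self) -> dict[str, Any]:
        return {
            "nx": self.nx, "ny": self.ny, "nz": self.nz,
            "dx": self.dx, "dy": self.dy, "dz": self.dz,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "VolumeGrid":
        return cls(
            nx=int(d["nx"]), ny=int(d["ny"]), nz=int(d["nz"]),
            dx=float(d.get("dx", 1.0)), dy=float(d.get("dy", 1.0)),
            dz=float(d.get("dz", 1.0)),
            origin=tuple(d["origin"]) if "origin" in d and d["origin"] is not None else None,
        )


def voxel_to_detector(
    geom: ConeBeamGeometry, point: np.ndarray, angle: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map world point(s) to physical detector coordinates and distance weight.

    Parameters
    ----------
    geom : scan geometry.
    point : array of shape (..., 3), world coordinates.
    angle : view angle theta in radians.

    Returns
    -------
    (u, v, w2) : physical detector coordinates relative to the central ray
        (detector offsets are applied downstream when converting to pixel
        indices) and the cone-beam distance weight ``dso^2 / (dso - s)^2``.
        Entries for points at or behind the source (``dso - s <= 0``) are NaN.
    """
    p = np.asarray(point, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    c, sn = np.cos(angle), np.sin(angle)
    s = -(x * c + y * sn)
    t = -x * sn + y * c
    denom = geom.dso - s
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(denom > 0, geom.dsd * t / denom, np.nan)
        v = np.where(denom > 0, geom.dsd * z / denom, np.nan)
        w2 = np.where(denom > 0, (geom.dso / denom) ** 2, np.nan)
    return u, v, w2
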
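"""Readers and writers for projection stacks and volumes.

The native on-disk format is a raw little-endian binary payload next to a
human-readable YAML sidecar header.  A stack saved to ``scan.proj`` becomes

    scan.proj        raw float payload, C order, shape (K, det_rows, det_cols)
    scan.proj.yaml   header: dtype, byte order, shape, full scan geometry

and round-trips bitwise.  Volumes additionally export to MetaImage (``.mha``,
carrying voxel spacing and origin) and to multi-page TIFF stacks.

Sizes quoted in MB use MB = 2**20 bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .containers import ProjectionStack, Volume
from .geometry import ConeBeamGeometry, VolumeGrid

__all__ = [
    "StackHeader",
    "read_projection_stack",
    "write_projection_stack",
    "read_volume",
    "write_volume",
    "expected_payload_bytes",
    "bytes_to_mb",
]

_DTYPES = {"float32": np.float32, "float64": np.float64}


def expected_payload_bytes(shape: tuple[int, ...], dtype: str) -> int:
    """Raw payload size in bytes for an array of this shape and dtype."""
    if dtype not in _DTYPES:
        raise ValueError(f"unknown dtype {dtype!r}")
    return int(np.prod(shape)) * np.dtype(_DTYPES[dtype]).itemsize


def bytes_to_mb(n_bytes: int) -> float:
    """Bytes to MB with MB = 2**20 bytes."""
    return n_bytes / 2**20


@dataclass(frozen=True)
class StackHeader:
    """Sidecar header describing a raw projection-stack payload."""

    det_rows: int
    det_cols: int
    n_angles: int
    dtype: str
    byte_order: str  # "little" | "big"
    geometry: ConeBeamGeometry

    def __post_init__(self) -> None:
        if self.dtype not in _DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r}")
        if self.byte_order not in ("little", "big"):
            raise ValueError(f"unknown byte order {self.byte_order!r}")
        if (self.geometry.n_angles, self.geometry.det_rows, self.geometry.det_cols) != (
            self.n_angles,
            self.det_rows,
            self.det_cols,
        ):
            raise ValueError("header shape fields disagree with the geometry block")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.det_rows, self.det_cols)

    @property
    def payload_bytes(self) -> int:
        return expected_payload_bytes(self.shape, self.dtype)

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "conefdk projection stack v1",
            "det_rows": self.det_rows,
            "det_cols": self.det_cols,
            "n_angles": self.n_angles,
            "dtype": self.dtype,
            "byte_order": self.byte_order,
            "payload_bytes": self.payload_bytes,
            "geometry": self.geometry.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StackHeader":
        geom = ConeBeamGeometry.from_dict(d["geometry"])
        hdr = cls(
            det_rows=int(d["det_rows"]),
            det_cols=int(d["det_cols"]),
            n_angles=int(d["n_angles"]),
            dtype=str(d["dtype"]),
            byte_order=str(d.get("byte_order", "little")),
            geometry=geom,
        )
        declared = d.get("payload_bytes")
        if declared is not None and int(declared) != hdr.payload_bytes:
            raise ValueError(
                f"header declares {declared} payload bytes but shape/dtype imply "
                f"{hdr.payload_bytes}"
            )
        return hdr


def _header_path(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def write_projection_stack(stack: ProjectionStack, path: str | Path) -> Path:
    """Write payload to ``path`` and a YAML header to ``path + '.yaml'``."""
    path = Path(path)
    dtype = "float32" if stack.data.dtype == np.float32 else "float64"
    header = StackHeader(
        det_rows=stack.geom.det_rows,
        det_cols=stack.geom.det_cols,
        n_angles=stack.geom.n_angles,
        dtype=dtype,
        byte_order="little",
        geometry=stack.geom,
    )
    payload = np.ascontiguousarray(stack.data, dtype="<" + {"float32": "f4", "float64": "f8"}[dtype])
    path.write_bytes(payload.tobytes())
    _header_path(path).write_text(yaml.safe_dump(header.to_dict(), sort_keys=False))
    return path


def read_projection_stack(path: str | Path) -> ProjectionStack:
    """Read a raw + YAML-header projection stack written by this package.

    ``path`` may point at either the payload or the header file.
    """
    path = Path(path)
    if path.suffix == ".yaml":
        header_path, payload_path = path, path.with_name(path.name[: -len(".yaml")])
    else:
        header_path, payload_path = _header_path(path), path
    if not header_path.exists():
        raise FileNotFoundError(f"missing sidecar header {header_path}")
    header = StackHeader.from_dict(yaml.safe_load(header_path.read_text()))
    raw = payload_path.read_bytes()
    if len(raw) != header.payload_bytes:
        raise ValueError(
            f"payload size mismatch for {payload_path}: header declares "
            f"{header.payload_bytes} bytes, file has {len(raw)}"
        )
    code = {"float32": "f4", "float64": "f8"}[header.dtype]
    order = "<" if header.byte_order == "little" else ">"
    data = np.frombuffer(raw, dtype=order + code).reshape(header.shape)
    data = data.astype(data.dtype.newbyteorder("="), copy=True)
    return ProjectionStack(header.geometry, data, stage="raw")


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def write_volume(volume: Volume, path: str | Path, format: str = "raw") -> Path:
    """Write a volume as raw+header, MetaImage (.mha) or a TIFF stack.

    raw: payload at ``path`` plus YAML header at ``path + '.yaml'`` (bitwise
    round-trip).  mha/tiff record voxel spacing; mha also records the origin.
    """
    path = Path(path)
    if not np.all(np.isfinite(volume.values)):
        raise ValueError("volume contains non-finite values; refusing to write")
    grid = volume.grid
    if format == "raw":
        dtype = "float32" if volume.values.dtype == np.float32 else "float64"
        payload = np.ascontiguousarray(
            volume.values, dtype="<" + {"float32": "f4", "float64": "f8"}[dtype]
        )
        path.write_bytes(payload.tobytes())
        header = {
            "format": "conefdk volume v1",
            "nx": grid.nx, "ny": grid.ny, "nz": grid.nz,
            "dtype": dtype,
            "byte_order": "little",
            "payload_bytes": expected_payload_bytes(grid.shape, dtype),
            "grid": grid.to_dict(),
        }
        _header_path(path).write_text(yaml.safe_dump(header, sort_keys=False))
        return path
    if format == "mha":
        import SimpleITK as sitk

        # SimpleITK images are indexed (z, y, x); our values are (x, y, z)
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
        img.SetSpacing((grid.dx, grid.dy, grid.dz))
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, str(path))
        return path
    if format == "tiff":
        import tifffile

        # one page per z-slice, page axes (y, x)
        pages = np.ascontiguousarray(np.transpose(volume.values, (2, 1, 0)))
        tifffile.imwrite(
            str(path),
            pages,
            photometric="minisblack",
            resolution=(1.0 / grid.dx, 1.0 / grid.dy),
            metadata={"spacing": grid.dz, "axes": "ZYX"},
        )
        return path
    raise ValueError(f"unknown volume format {format!r}; expected raw, mha or tiff")


def read_volume(path: str | Path) -> Volume:
    """Read a volume written by :func:`write_volume` (raw+header or .mha)."""
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T  # back to (x, y, z)
        sp = img.GetSpacing()
        grid = VolumeGrid(
            nx=values.shape[0], ny=values.shape[1], nz=values.shape[2],
            dx=sp[0], dy=sp[1], dz=sp[2], origin=tuple(img.GetOrigin()),
        )
        return Volume(grid, np.ascontiguousarray(values))
    if path.suffix == ".yaml":
        header_path, payload_path = path, path.with_name(path.name[: -len(".yaml")])
    else:
        header_path, payload_path = _header_path(path), path
    header = yaml.safe_load(header_path.read_text())
    grid = VolumeGrid.from_dict(header["grid"])
    raw = payload_path.read_bytes()
    expected = int(header["payload_bytes"])
    if len(raw) != expected:
        raise ValueError(
            f"payload size mismatch for {payload_path}: header declares "
            f"{expected} bytes, file has {len(raw)}"
        )
    code = {"float32": "f4", "float64": "f8"}[header["dtype"]]
    order = "<" if header.get("byte_order", "little") == "little" else ">"
    values = np.frombuffer(raw, dtype=order + code).reshape(grid.shape)
    return Volume(grid, values.astype(values.dtype.newbyteorder("="), copy=True))
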
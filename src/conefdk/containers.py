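"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ConeBeamGeometry, VolumeGrid

__all__ = ["ProjectionStack", "Volume", "PRECISION_DTYPES"]

PRECISION_DTYPES = {"single": np.float32, "double": np.float64}

_STAGES = ("raw", "weighted", "filtered")


@dataclass
class ProjectionStack:
    """A set of detector images P_1..P_K with their acquisition geometry.

    ``data`` has shape ``(n_angles, det_rows, det_cols)``.  ``stage`` records
    how far the images have moved through the pipeline; transitions only go
    forward: raw -> weighted -> filtered.
    """

    geom: ConeBeamGeometry
    data: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        expected = (self.geom.n_angles, self.geom.det_rows, self.geom.det_cols)
        if self.data.shape != expected:
            raise ValueError(
                f"projection data shape {self.data.shape} does not match geometry {expected}"
            )
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")

    @property
    def precision(self) -> str:
        return "single" if self.data.dtype == np.float32 else "double"

    def with_data(self, data: np.ndarray, stage: str) -> "ProjectionStack":
        """New stack with replaced data advancing to a later stage."""
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"stage may not go backwards: {self.stage} -> {stage}")
        return replace(self, data=data, stage=stage)

    def astype(self, precision: str) -> "ProjectionStack":
        return replace(self, data=self.data.astype(PRECISION_DTYPES[precision]))


@dataclass
class Volume:
    """A reconstruction (or ground-truth) volume on a VolumeGrid.

    ``values`` has shape ``(nx, ny, nz)`` in attenuation units.
    """

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"volume shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def precision(self) -> str:
        return "single" if self.values.dtype == np.float32 else "double"

    @classmethod
    def zeros(cls, grid: VolumeGrid, precision: str = "double") -> "Volume":
        return cls(grid, np.zeros(grid.shape, dtype=PRECISION_DTYPES[precision]))

    def astype(self, precision: str) -> "Volume":
        return Volume(self.grid, self.values.astype(PRECISION_DTYPES[precision]))
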
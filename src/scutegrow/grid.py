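"""Voxel-grid containers shared by the generator and the segmenter.

Convention: voxel indices are 0-based; the world position of voxel
(i, j, k) is ``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing``
(voxel-center convention).  All lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=np.float64).reshape(3)
    return v


@dataclass
class _Grid:
    array: np.ndarray
    voxel_spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3 or self.array.size == 0:
            raise ValueError("array must be a non-empty 3D array")
        self.voxel_spacing_mm = _as_vec3(self.voxel_spacing_mm)
        self.origin_mm = _as_vec3(self.origin_mm)
        if np.any(self.voxel_spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World positions (mm) of voxel-index rows (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return self.origin_mm + (idx + 0.5) * self.voxel_spacing_mm

    def index_of(self, world_mm) -> tuple[int, int, int]:
        """Voxel index containing a world position (clipped to bounds)."""
        p = (_as_vec3(world_mm) - self.origin_mm) / self.voxel_spacing_mm - 0.5
        idx = np.rint(p).astype(np.int64)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def same_frame(self, other: "_Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_spacing_mm, other.voxel_spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class IntensityVolume(_Grid):
    """3D grayscale volume with spatial frame metadata."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.array = self.array.astype(np.float32, copy=False)


@dataclass
class LabelField(_Grid):
    """3D integer label volume; 0 = background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.array.dtype, np.integer):
            raise ValueError("label array must be integer-typed")
        if self.array.min() < 0:
            raise ValueError("labels must be non-negative")

    def labels(self) -> np.ndarray:
        """Sorted nonzero label ids present in the field."""
        u = np.unique(self.array)
        return u[u > 0]

    def compacted(self) -> "LabelField":
        """Relabel so that ids are dense 1..N, preserving order."""
        u = self.labels()
        lut = np.zeros(int(self.array.max()) + 1, dtype=self.array.dtype)
        lut[u] = np.arange(1, len(u) + 1, dtype=self.array.dtype)
        return LabelField(lut[self.array], self.voxel_spacing_mm, self.origin_mm)

    def voxel_counts(self) -> dict[int, int]:
        u, c = np.unique(self.array, return_counts=True)
        return {int(k): int(v) for k, v in zip(u, c) if k > 0}
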
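"""Voxel-grid containers shared by every stage of the pipeline.

Conventions (fixed so masks and dose fields are bit-reproducible):

* Arrays are indexed ``[ix, iy, iz]`` with axis 0 = X (lateral, LAT),
  axis 1 = Y (anterior-posterior, AP), axis 2 = Z (superior-inferior, SI);
  the cylinder phantom axis is Z.
* Coordinates are voxel-center based: the physical position of voxel
  ``(i, j, k)`` is ``origin + index * spacing`` (mm).
* A voxel belongs to a region iff its *center* is inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "RoiMask", "DoseGrid", "AXIS_NAMES", "DIRECTION_AXES"]

#: axis index -> anatomical axis label
AXIS_NAMES = {0: "LAT", 1: "AP", 2: "SI"}

#: profile direction label -> array axis the profile runs along
DIRECTION_AXES = {"LAT": 0, "AP": 1, "SI": 2}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (X, Y, Z); every component >= 1.
    spacing : tuple of float
        Voxel pitch in mm along each axis; every component > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("GridSpec fields must be length-3 triples")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # ------------------------------------------------------------------
    @classmethod
    def for_phantom(cls, radius_cm: float, length_cm: float,
                    spacing_mm: float = 2.0, margin_mm: float = 2.0) -> "GridSpec":
        """Grid that covers a Z-axis cylinder centered on the isocenter.

        The grid is symmetric about (0, 0, 0) with an odd voxel count per
        axis so the isocenter falls exactly on a voxel center.
        """
        half = np.array([radius_cm * 10.0 + margin_mm,
                         radius_cm * 10.0 + margin_mm,
                         length_cm * 5.0 + margin_mm])
        n_half = np.ceil(half / spacing_mm).astype(int)
        shape = tuple(int(2 * n + 1) for n in n_half)
        origin = tuple(float(-n * spacing_mm) for n in n_half)
        return cls(shape=shape, spacing=(spacing_mm,) * 3, origin=origin)

    # ------------------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_of(self, position_mm, axis: int) -> int:
        """Nearest voxel index to a physical coordinate on one axis."""
        i = int(round((position_mm - self.origin[axis]) / self.spacing[axis]))
        return int(np.clip(i, 0, self.shape[axis] - 1))

    def position_of(self, index: tuple[int, int, int]) -> np.ndarray:
        """Physical position (mm) of a voxel center."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def crop_box(self, center_mm, half_extent_mm) -> tuple[slice, slice, slice]:
        """Slices covering ``center +/- half_extent`` (mm), clipped to the grid.

        Used to restrict per-structure computations (sphere kernels, corridor
        tubes, inter-vertex regions) to a tight bounding box.
        """
        center_mm = np.broadcast_to(np.asarray(center_mm, dtype=float), (3,))
        half = np.broadcast_to(np.asarray(half_extent_mm, dtype=float), (3,))
        slices = []
        for ax in range(3):
            lo = int(np.floor((center_mm[ax] - half[ax] - self.origin[ax]) / self.spacing[ax]))
            hi = int(np.ceil((center_mm[ax] + half[ax] - self.origin[ax]) / self.spacing[ax])) + 1
            slices.append(slice(max(lo, 0), min(hi, self.shape[ax])))
        return tuple(slices)

    def meshgrid(self, box: tuple[slice, slice, slice] | None = None):
        """Broadcastable physical coordinate arrays (mm), optionally cropped."""
        if box is None:
            box = (slice(None),) * 3
        coords = []
        for ax in range(3):
            c = self.axis_coords(ax)[box[ax]]
            shape = [1, 1, 1]
            shape[ax] = c.size
            coords.append(c.reshape(shape))
        return tuple(coords)

    def to_affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (for NIfTI export)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class RoiMask:
    """Named boolean region on a voxel grid."""

    name: str
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cm3

    def __and__(self, other: "RoiMask") -> "RoiMask":
        self._check_congruent(other)
        return RoiMask(f"({self.name})&({other.name})", self.mask & other.mask, self.grid)

    def __or__(self, other: "RoiMask") -> "RoiMask":
        self._check_congruent(other)
        return RoiMask(f"({self.name})|({other.name})", self.mask | other.mask, self.grid)

    def __sub__(self, other: "RoiMask") -> "RoiMask":
        self._check_congruent(other)
        return RoiMask(f"({self.name})-({other.name})", self.mask & ~other.mask, self.grid)

    def _check_congruent(self, other: "RoiMask") -> None:
        if self.grid != other.grid:
            raise ValueError("masks live on different grids")


@dataclass
class DoseGrid:
    """3D absorbed-dose distribution (Gy) on a voxel grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * float(factor), self.grid)

    def max(self) -> float:
        return float(self.values.max())
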
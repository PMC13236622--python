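"""Phantom, lattice, and planning/evaluation ROI construction.

The study geometry is a water-equivalent cylinder (30 cm diameter x 18 cm
length, axis = Z/SI) holding a 3x3x3 lattice of spherical high-dose
vertices.  Vertex diameter d (0.5-2.0 cm) and edge-to-edge separation s
(1.0-5.0 cm) define the lattice pitch d + s (center-to-center distance).

Derived ROIs:

* ``coreball`` -- concentric sphere of diameter d/2 inside each vertex,
  used by the planning objective to force the dose maximum to the center.
* ``Avoid_axial`` / ``Avoid_SI`` -- rectangular prism extending 1.0 cm
  beyond the outermost vertex surfaces, minus the vertex union.  The two
  avoid ROIs differ only in which optimizer objectives they carry in a
  planning system; geometrically they follow the same prism rule, so both
  are generated identically and kept as separate named masks.
* ``Eval_Normal`` -- phantom minus the avoid prisms; the normal-tissue
  surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, RoiMask

__all__ = [
    "PhantomSpec",
    "LatticeSpec",
    "lattice_centers",
    "build_phantom_mask",
    "build_vertex_masks",
    "build_coreball_masks",
    "build_avoid_masks",
    "build_eval_normal_mask",
    "AVOID_MARGIN_MM",
]

#: avoid-prism expansion beyond the outermost vertex surface (1.0 cm)
AVOID_MARGIN_MM = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical water-equivalent phantom (default 30 cm dia x 18 cm)."""

    radius_cm: float = 15.0
    length_cm: float = 18.0
    axis: int = 2  # cylinder axis: 0=X, 1=Y, 2=Z (SI)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_cm < 0 or self.length_cm < 0:
            raise ValueError("phantom radius and length must be >= 0")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1, or 2")

    @property
    def volume_cm3(self) -> float:
        return float(np.pi * self.radius_cm ** 2 * self.length_cm)


@dataclass(frozen=True)
class LatticeSpec:
    """Regular lattice of spherical vertices.

    ``diameter_cm`` is the vertex sphere diameter d, ``separation_cm`` the
    edge-to-edge distance s between adjacent spheres; the center-to-center
    pitch is d + s.  ``counts`` defaults to the 3x3x3 / 27-vertex layout.
    """

    diameter_cm: float
    separation_cm: float
    counts: tuple[int, int, int] = (3, 3, 3)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError("vertex diameter must be > 0")
        if self.diameter_cm + self.separation_cm <= 0:
            raise ValueError("pitch (diameter + separation) must be > 0")
        if any(int(n) < 1 for n in self.counts):
            raise ValueError("lattice counts must be >= 1")
        object.__setattr__(self, "counts", tuple(int(n) for n in self.counts))

    @property
    def pitch_mm(self) -> float:
        """Center-to-center distance (mm) between adjacent vertices."""
        return (self.diameter_cm + self.separation_cm) * 10.0

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 5.0

    @property
    def gap_mm(self) -> float:
        """Edge-to-edge distance (mm) between adjacent spheres."""
        return self.separation_cm * 10.0

    @property
    def n_vertices(self) -> int:
        return int(np.prod(self.counts))


def lattice_centers(spec: LatticeSpec) -> np.ndarray:
    """Vertex center positions (mm), shape (n_vertices, 3).

    The grid of ``counts`` points is centered on ``spec.center_mm`` with
    per-axis pitch d + s, and returned in deterministic lexicographic order
    with Z slowest, then Y, then X: index = (iz * ny + iy) * nx + ix.
    """
    pitch = spec.pitch_mm
    offsets = [
        (np.arange(spec.counts[ax]) - (spec.counts[ax] - 1) / 2.0) * pitch
        for ax in range(3)
    ]
    centers = np.empty((spec.n_vertices, 3))
    idx = 0
    for iz in range(spec.counts[2]):
        for iy in range(spec.counts[1]):
            for ix in range(spec.counts[0]):
                centers[idx] = (offsets[0][ix], offsets[1][iy], offsets[2][iz])
                idx += 1
    return centers + np.asarray(spec.center_mm)


def vertex_index(spec: LatticeSpec, ix: int, iy: int, iz: int) -> int:
    """Linear vertex index for lattice coordinates (ix, iy, iz)."""
    nx, ny, _ = spec.counts
    return (iz * ny + iy) * nx + ix


def _sphere_mask(center: np.ndarray, radius_mm: float, grid: GridSpec) -> np.ndarray:
    """Boolean volume: voxel centers within ``radius_mm`` of ``center``."""
    out = np.zeros(grid.shape, dtype=bool)
    if radius_mm <= 0:
        return out
    box = grid.crop_box(center, radius_mm + max(grid.spacing))
    gx, gy, gz = grid.meshgrid(box)
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    out[box] = d2 <= radius_mm ** 2
    return out


def build_phantom_mask(phantom: PhantomSpec, grid: GridSpec) -> RoiMask:
    """Voxel-center-inside mask of the cylinder phantom.

    Inclusion is strict radially and half-open axially, so boundary-
    aligned voxel centers never double-count a face.  Emits a warning if
    the grid does not fully contain the cylinder (the mask is then
    clipped to the grid).
    """
    axes = [ax for ax in range(3) if ax != phantom.axis]
    gx, gy, gz = grid.meshgrid()
    coords = (gx, gy, gz)
    center = np.asarray(phantom.center_mm)
    r_mm = phantom.radius_cm * 10.0
    half_len = phantom.length_cm * 5.0

    # strict radial / half-open axial inclusion: voxel centers landing
    # exactly on a face are counted once, not twice, so the voxel volume
    # stays an unbiased estimate of pi r^2 L at any aligned spacing
    radial2 = sum((coords[ax] - center[ax]) ** 2 for ax in axes)
    axial = coords[phantom.axis] - center[phantom.axis]
    mask = (radial2 < r_mm ** 2) & (axial >= -half_len) & (axial < half_len)

    lo = grid.position_of((0, 0, 0))
    hi = grid.position_of(tuple(n - 1 for n in grid.shape))
    for ax in axes:
        if center[ax] - r_mm < lo[ax] or center[ax] + r_mm > hi[ax]:
            warnings.warn("grid does not contain the phantom radially; mask clipped")
            break
    if (center[phantom.axis] - half_len < lo[phantom.axis]
            or center[phantom.axis] + half_len > hi[phantom.axis]):
        warnings.warn("grid does not contain the phantom axially; mask clipped")
    return RoiMask("phantom", mask, grid)


def build_vertex_masks(spec: LatticeSpec, grid: GridSpec) -> list[RoiMask]:
    """One sphere mask (diameter d) per lattice vertex.

    Masks are pairwise disjoint whenever separation > 0; overlapping
    spheres (separation <= 0) raise.
    """
    if spec.separation_cm <= 0:
        raise ValueError(
            "vertex spheres overlap or touch: separation must be > 0")
    centers = lattice_centers(spec)
    return [
        RoiMask(f"vertex_{k:02d}", _sphere_mask(c, spec.radius_mm, grid), grid)
        for k, c in enumerate(centers)
    ]


def build_coreball_masks(spec: LatticeSpec, grid: GridSpec) -> list[RoiMask]:
    """Concentric core spheres of diameter d/2 (planning objective ROIs).

    Each coreball is a subset of its vertex mask by construction.  At
    coarse spacing a coreball of sub-voxel radius may contain no voxel
    centers and come back empty.
    """
    centers = lattice_centers(spec)
    return [
        RoiMask(f"coreball_{k:02d}", _sphere_mask(c, spec.radius_mm / 2.0, grid), grid)
        for k, c in enumerate(centers)
    ]


def build_avoid_masks(
    spec: LatticeSpec,
    vertex_masks: list[RoiMask],
    grid: GridSpec,
    phantom_mask: RoiMask | None = None,
) -> tuple[RoiMask, RoiMask]:
    """The two avoidance prisms (valley-dose shaping ROIs).

    Each prism is the axis-aligned bounding box of the vertex-sphere union
    expanded by 1.0 cm on every face, minus the vertex union.  Both masks
    follow the same prism rule and are returned as separate named ROIs
    (``Avoid_axial``, ``Avoid_SI``) for reporting parity.  If a phantom
    mask is supplied and the prism extends beyond it, the prism is clipped
    to the phantom with a warning.
    """
    if not vertex_masks:
        raise ValueError("vertex_masks must be non-empty")
    grid_ = vertex_masks[0].grid
    centers = lattice_centers(spec)
    lo = centers.min(axis=0) - spec.radius_mm - AVOID_MARGIN_MM
    hi = centers.max(axis=0) + spec.radius_mm + AVOID_MARGIN_MM

    # half-open box so grid-aligned faces are not double-counted
    gx, gy, gz = grid.meshgrid()
    box = ((gx >= lo[0]) & (gx < hi[0])
           & (gy >= lo[1]) & (gy < hi[1])
           & (gz >= lo[2]) & (gz < hi[2]))

    union = np.zeros(grid.shape, dtype=bool)
    for vm in vertex_masks:
        union |= vm.mask

    avoid = box & ~union
    if phantom_mask is not None:
        outside = avoid & ~phantom_mask.mask
        if outside.any():
            warnings.warn("avoid prism extends beyond the phantom; clipped")
            avoid = avoid & phantom_mask.mask
    return (RoiMask("Avoid_axial", avoid.copy(), grid_),
            RoiMask("Avoid_SI", avoid.copy(), grid_))


def build_eval_normal_mask(phantom_mask: RoiMask,
                           avoid_masks: tuple[RoiMask, RoiMask] | list[RoiMask],
                           vertex_masks: list[RoiMask] = (),
                           ) -> RoiMask:
    """Normal-tissue surrogate: phantom minus the union of avoid prisms.

    The avoid prisms exclude the vertex interiors by construction, so when
    normal-tissue metrics are the goal the vertex masks should be passed
    as well: the tumor-surrogate spheres are then also removed and
    Eval_Normal is the phantom minus the entire prism region.  With
    ``vertex_masks`` omitted the result is the plain set difference
    phantom minus avoid-union (which still contains the vertices).
    """
    avoid_union = np.zeros(phantom_mask.grid.shape, dtype=bool)
    for am in list(avoid_masks) + list(vertex_masks):
        phantom_mask._check_congruent(am)
        avoid_union |= am.mask
    return RoiMask("Eval_Normal", phantom_mask.mask & ~avoid_union,
                   phantom_mask.grid)
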
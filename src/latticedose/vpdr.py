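"""Valley-to-peak dose ratio (VPDR) extraction.

For each of the three orthogonal directions (AP, LAT, SI) the 3x3x3
lattice yields nine profile lines, one per transverse lattice
(row, column).  Along each line the dose maximum inside each of the three
vertex volumes (peak) and the dose minimum in each of the two inter-vertex
regions (valley) are located independently, giving an alternating
peak-valley-peak-valley-peak sequence; the extracted points need not be
collinear.  The per-profile statistic is

    VPDR = 100 * min(valley doses) / max(peak doses)   [%]

yielding nine VPDR values per direction per configuration.

The inter-vertex search region is the spatial domain between the facing
sphere boundaries: voxels whose projection onto the center-connecting
segment lies strictly between the boundaries and whose perpendicular
distance to the segment is at most the vertex radius (a finite cylinder).
A ``lateral_radius_mm`` override allows narrowing the search toward a pure
line-segment search.

Argmax/argmin ties are broken by lowest linear (C-order) voxel index so
results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import LatticeSpec, lattice_centers
from .grids import DIRECTION_AXES, DoseGrid, GridSpec, RoiMask

__all__ = [
    "PeakPoint",
    "ValleyPoint",
    "DoseProfile",
    "VpdrResult",
    "find_peaks",
    "intervertex_region",
    "find_valley",
    "assemble_profile",
    "profile_vpdr",
    "directional_vpdr",
]


@dataclass(frozen=True)
class PeakPoint:
    """Location and value of the dose maximum inside one vertex volume."""

    vertex_index: int
    position_mm: tuple[float, float, float]
    dose_gy: float


@dataclass(frozen=True)
class ValleyPoint:
    """Location and value of the dose minimum between two adjacent vertices."""

    pair: tuple[int, int]
    position_mm: tuple[float, float, float]
    dose_gy: float


@dataclass(frozen=True)
class DoseProfile:
    """Ordered peak/valley anchors along one direction plus a uniformly
    respaced curve through them.

    ``points`` alternates peak, valley, peak, valley, peak (doses in Gy);
    ``stations_mm`` are arc-length positions of the resampled curve and
    ``resampled_gy`` the dose at each station.  Anchor doses are preserved
    exactly at their nearest stations, so the VPDR is independent of the
    resampling density.
    """

    direction: str
    points: tuple
    stations_mm: np.ndarray
    resampled_gy: np.ndarray

    @property
    def peak_doses(self) -> np.ndarray:
        return np.array([p.dose_gy for p in self.points[0::2]])

    @property
    def valley_doses(self) -> np.ndarray:
        return np.array([p.dose_gy for p in self.points[1::2]])


@dataclass(frozen=True)
class VpdrResult:
    """Per-direction VPDR summary: the nine per-profile values (%), their
    mean, and sample SD (n-1)."""

    direction: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _argext(dose: DoseGrid, mask: np.ndarray, mode: str):
    """Deterministic argmax/argmin over a boolean mask.

    Ties resolve to the lowest linear C-order voxel index.  Returns
    (index triple, dose value).
    """
    flat_idx = np.flatnonzero(mask.ravel(order="C"))
    if flat_idx.size == 0:
        raise ValueError("search region contains no voxels")
    vals = dose.values.ravel(order="C")[flat_idx]
    pos = np.argmax(vals) if mode == "max" else np.argmin(vals)
    # np.argmax/argmin already return the first (lowest linear index) hit
    ijk = np.unravel_index(flat_idx[pos], dose.values.shape, order="C")
    return tuple(int(i) for i in ijk), float(vals[pos])


def find_peaks(dose: DoseGrid, vertex_masks: list[RoiMask]) -> list[PeakPoint]:
    """Per-vertex dose maxima (one PeakPoint per mask, in mask order)."""
    peaks = []
    for k, vm in enumerate(vertex_masks):
        if dose.grid != vm.grid:
            raise ValueError("vertex mask grid differs from dose grid")
        ijk, val = _argext(dose, vm.mask, "max")
        peaks.append(PeakPoint(k, tuple(dose.grid.position_of(ijk)), val))
    return peaks


def intervertex_region(c1, c2, vertex_radius_mm: float, grid: GridSpec,
                       lateral_radius_mm: float | None = None) -> RoiMask:
    """Finite cylinder between the facing boundaries of two vertex spheres.

    Voxel centers whose projection onto the c1->c2 segment lies strictly
    between the sphere boundaries and whose perpendicular distance to the
    segment is at most ``lateral_radius_mm`` (default: the vertex radius).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    length = float(np.linalg.norm(c2 - c1))
    if length <= 2.0 * vertex_radius_mm:
        raise ValueError("vertex spheres overlap or touch; the inter-vertex "
                         "region is empty")
    lateral = vertex_radius_mm if lateral_radius_mm is None else lateral_radius_mm
    lateral = max(lateral, 0.51 * max(grid.spacing))  # keep >= ~1 voxel wide
    u = (c2 - c1) / length

    mask = np.zeros(grid.shape, dtype=bool)
    mid = (c1 + c2) / 2.0
    half = np.abs(c2 - c1) / 2.0 + lateral + max(grid.spacing)
    box = grid.crop_box(mid, half)
    gx, gy, gz = grid.meshgrid(box)
    dx, dy, dz = gx - c1[0], gy - c1[1], gz - c1[2]
    t = dx * u[0] + dy * u[1] + dz * u[2]
    perp2 = (dx ** 2 + dy ** 2 + dz ** 2) - t ** 2
    mask[box] = ((t > vertex_radius_mm)
                 & (t < length - vertex_radius_mm)
                 & (perp2 <= lateral ** 2))
    if not mask.any():
        raise ValueError("inter-vertex region contains no voxels at this "
                         "grid spacing")
    return RoiMask("intervertex", mask, grid)


def find_valley(dose: DoseGrid, region: RoiMask,
                pair: tuple[int, int] = (-1, -1)) -> ValleyPoint:
    """Dose minimum over an inter-vertex region."""
    if dose.grid != region.grid:
        raise ValueError("region grid differs from dose grid")
    ijk, val = _argext(dose, region.mask, "min")
    return ValleyPoint(tuple(pair), tuple(dose.grid.position_of(ijk)), val)


def assemble_profile(peaks: list[PeakPoint], valleys: list[ValleyPoint],
                     direction: str, dose: DoseGrid,
                     n_stations: int = 101) -> DoseProfile:
    """Polyline profile through alternating peak/valley anchors.

    The anchors (possibly non-collinear) are connected in order along the
    profile direction; dose is sampled by trilinear interpolation at
    ``n_stations`` uniformly spaced arc-length stations, then each
    anchor's exact dose overwrites its nearest station so the alternating
    extrema survive resampling.
    """
    if direction not in DIRECTION_AXES:
        raise ValueError(f"unknown direction {direction!r}")
    if len(peaks) != len(valleys) + 1:
        raise ValueError("need k peaks and k-1 valleys")
    axis = DIRECTION_AXES[direction]

    anchors: list = []
    for i, p in enumerate(peaks):
        anchors.append(p)
        if i < len(valleys):
            anchors.append(valleys[i])
    coords = np.array([a.position_mm for a in anchors])
    along = coords[:, axis]
    if np.any(np.diff(along) <= 0):
        raise ValueError(
            f"anchors are not monotonically ordered along {direction}")

    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    stations = np.linspace(0.0, arc[-1], n_stations)
    # interpolate each spatial coordinate along arc length, then sample dose
    pts = np.stack([np.interp(stations, arc, coords[:, ax]) for ax in range(3)])
    vox = (pts - np.asarray(dose.grid.origin)[:, None]) / \
        np.asarray(dose.grid.spacing)[:, None]
    sampled = map_coordinates(dose.values, vox, order=1, mode="nearest")
    for a, s in zip(anchors, arc):
        sampled[int(np.argmin(np.abs(stations - s)))] = a.dose_gy
    return DoseProfile(direction, tuple(anchors), stations, sampled)


def profile_vpdr(profile: DoseProfile) -> float:
    """VPDR (%) of one profile: 100 * min(valleys) / max(peaks)."""
    peaks = profile.peak_doses
    valleys = profile.valley_doses
    if peaks.size == 0 or valleys.size == 0:
        raise ValueError("profile needs at least one peak and one valley")
    d_peak = float(peaks.max())
    if d_peak <= 0:
        raise ValueError("maximum peak dose is zero; VPDR undefined")
    return 100.0 * float(valleys.min()) / d_peak


def directional_vpdr(dose: DoseGrid, lattice: LatticeSpec,
                     vertex_masks: list[RoiMask], direction: str,
                     peaks: list[PeakPoint] | None = None,
                     lateral_radius_mm: float | None = None,
                     n_stations: int = 101) -> VpdrResult:
    """All per-profile VPDR values for one direction.

    For a k-wide lattice each profile line (one per transverse lattice
    position) carries k peaks and k-1 valleys; the 3x3x3 default yields
    nine values.  ``peaks`` may be supplied to reuse a prior
    :func:`find_peaks` result.
    """
    axis = DIRECTION_AXES[direction]
    if lattice.counts[axis] < 2:
        raise ValueError("need >= 2 vertices along the profile direction")
    centers = lattice_centers(lattice)
    if peaks is None:
        peaks = find_peaks(dose, vertex_masks)

    nx, ny, nz = lattice.counts
    t_axes = [ax for ax in range(3) if ax != axis]  # transverse lattice axes

    def lin(i, j, k):
        return (k * ny + j) * nx + i

    values = []
    for ta in range(lattice.counts[t_axes[0]]):
        for tb in range(lattice.counts[t_axes[1]]):
            line_idx = []
            for m in range(lattice.counts[axis]):
                pos = [0, 0, 0]
                pos[axis] = m
                pos[t_axes[0]] = ta
                pos[t_axes[1]] = tb
                line_idx.append(lin(*pos))
            line_peaks = [peaks[k] for k in line_idx]
            line_valleys = []
            for k1, k2 in zip(line_idx[:-1], line_idx[1:]):
                region = intervertex_region(centers[k1], centers[k2],
                                            lattice.radius_mm, dose.grid,
                                            lateral_radius_mm)
                line_valleys.append(find_valley(dose, region, (k1, k2)))
            profile = assemble_profile(line_peaks, line_valleys, direction,
                                       dose, n_stations)
            values.append(profile_vpdr(profile))
    return VpdrResult(direction, np.asarray(values))
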
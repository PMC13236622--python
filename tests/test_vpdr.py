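"""Peak/valley extraction, profile assembly, and VPDR computation."""

import numpy as np
import pytest

from latticedose.geometry import LatticeSpec, build_vertex_masks, lattice_centers
from latticedose.grids import DoseGrid, GridSpec
from latticedose.simulate import DeliveryMode, SimParams, simulate_dose
from latticedose.vpdr import (DoseProfile, PeakPoint, ValleyPoint,
                              assemble_profile, directional_vpdr, find_peaks,
                              find_valley, intervertex_region, profile_vpdr)

from conftest import SUITE_SEED, compact_grid, simulated_config


def brute_force_extremum(dose, mask, mode):
    """Independent oracle: explicit python scan in linear-index order."""
    best_idx, best_val = None, None
    for idx in map(tuple, np.argwhere(mask)):
        v = dose.values[idx]
        if best_val is None or (mode == "max" and v > best_val) \
                or (mode == "min" and v < best_val):
            best_idx, best_val = idx, v
    return best_idx, best_val


@pytest.fixture(scope="module")
def coarse_field():
    """8 mm noisy field: coarse enough for exhaustive-oracle comparisons."""
    lattice = LatticeSpec(2.0, 3.0)
    grid = compact_grid(lattice, spacing_mm=8.0)
    params = DeliveryMode.params("coplanar", seed=SUITE_SEED, noise_sigma=0.05)
    dose = simulate_dose(lattice, params, grid)
    masks = build_vertex_masks(lattice, grid)
    return lattice, grid, dose, masks


class TestFindPeaks:
    def test_matches_exhaustive_scan(self, coarse_field):
        lattice, grid, dose, masks = coarse_field
        peaks = find_peaks(dose, masks)
        for pk, m in zip(peaks, masks):
            idx, val = brute_force_extremum(dose, m.mask, "max")
            assert pk.dose_gy == val
            np.testing.assert_allclose(pk.position_mm, grid.position_of(idx))

    def test_peak_at_least_center_dose(self, coarse_field):
        lattice, grid, dose, masks = coarse_field
        peaks = find_peaks(dose, masks)
        for pk, c in zip(peaks, lattice_centers(lattice)):
            cidx = tuple(grid.index_of(c[ax], ax) for ax in range(3))
            assert pk.dose_gy >= dose.values[cidx]

    def test_empty_mask_rejected(self, coarse_field):
        _, grid, dose, _ = coarse_field
        from latticedose.grids import RoiMask
        empty = RoiMask("empty", np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            find_peaks(dose, [empty])


class TestIntervertexRegion:
    def test_geometry_of_region(self):
        # d=1, s=2: region length 2 cm, radius 0.5 cm between X-neighbors
        lattice = LatticeSpec(1.0, 2.0)
        grid = compact_grid(lattice, spacing_mm=1.0)
        centers = lattice_centers(lattice)
        region = intervertex_region(centers[0], centers[1], lattice.radius_mm,
                                    grid)
        pos = np.array([grid.position_of(tuple(i))
                        for i in np.argwhere(region.mask)])
        length = pos[:, 0].max() - pos[:, 0].min()
        assert length <= 20.0  # within the 2 cm gap
        assert length >= 20.0 - 2 * grid.spacing[0]
        # analytic cylinder volume pi r^2 s = 1.571 cm^3
        assert region.volume_cm3 == pytest.approx(np.pi * 0.5 ** 2 * 2.0,
                                                  rel=0.15)

    def test_region_disjoint_from_vertices(self):
        lattice = LatticeSpec(1.0, 2.0)
        grid = compact_grid(lattice, spacing_mm=2.0)
        centers = lattice_centers(lattice)
        masks = build_vertex_masks(lattice, grid)
        region = intervertex_region(centers[0], centers[1], lattice.radius_mm,
                                    grid)
        for m in masks:
            assert not (region.mask & m.mask).any()

    def test_overlapping_spheres_rejected(self):
        grid = compact_grid(LatticeSpec(1.0, 2.0), spacing_mm=4.0)
        with pytest.raises(ValueError, match="overlap"):
            intervertex_region((0, 0, 0), (9.0, 0, 0), 5.0, grid)


class TestFindValley:
    def test_matches_exhaustive_scan(self, coarse_field):
        lattice, grid, dose, _ = coarse_field
        centers = lattice_centers(lattice)
        for k1, k2 in [(0, 1), (0, 3), (0, 9), (13, 14)]:
            region = intervertex_region(centers[k1], centers[k2],
                                        lattice.radius_mm, grid)
            valley = find_valley(dose, region, (k1, k2))
            idx, val = brute_force_extremum(dose, region.mask, "min")
            assert valley.dose_gy == val
            np.testing.assert_allclose(valley.position_mm,
                                       grid.position_of(idx))

    def test_corridor_free_valley_near_background(self):
        lattice = LatticeSpec(1.0, 5.0)
        grid = compact_grid(lattice, spacing_mm=2.0)
        params = SimParams(corridor_amplitude=(0, 0, 0), noise_sigma=0.0,
                           scatter_fraction=0.0)
        dose = simulate_dose(lattice, params, grid)
        centers = lattice_centers(lattice)
        region = intervertex_region(centers[0], centers[1], lattice.radius_mm,
                                    grid)
        valley = find_valley(dose, region)
        assert valley.dose_gy == pytest.approx(params.background, rel=0.01)

    def test_valley_below_flanking_peaks(self, coarse_field):
        lattice, grid, dose, masks = coarse_field
        centers = lattice_centers(lattice)
        peaks = find_peaks(dose, masks)
        for k1, k2 in [(0, 1), (4, 13), (13, 22)]:
            region = intervertex_region(centers[k1], centers[k2],
                                        lattice.radius_mm, grid)
            valley = find_valley(dose, region, (k1, k2))
            assert valley.dose_gy <= peaks[k1].dose_gy
            assert valley.dose_gy <= peaks[k2].dose_gy


def make_points(direction_axis, positions, doses, kind):
    pts = []
    for i, (x, d) in enumerate(zip(positions, doses)):
        pos = [0.0, 0.0, 0.0]
        pos[direction_axis] = x
        if kind[i] == "p":
            pts.append(PeakPoint(i, tuple(pos), d))
        else:
            pts.append(ValleyPoint((i - 1, i), tuple(pos), d))
    return pts


class TestAssembleProfile:
    def analytic_dose(self, grid):
        gx, gy, gz = grid.meshgrid()
        values = 10.0 * np.exp(-(gx ** 2 + gy ** 2 + gz ** 2) / (2 * 30.0 ** 2))
        return DoseGrid(values + 1.0, grid)

    def test_anchor_doses_preserved(self, coarse_field):
        lattice, grid, dose, masks = coarse_field
        centers = lattice_centers(lattice)
        peaks = find_peaks(dose, masks)
        line = [0, 1, 2]
        valleys = []
        for k1, k2 in zip(line[:-1], line[1:]):
            region = intervertex_region(centers[k1], centers[k2],
                                        lattice.radius_mm, grid)
            valleys.append(find_valley(dose, region, (k1, k2)))
        prof = assemble_profile([peaks[k] for k in line], valleys, "LAT", dose)
        assert len(prof.resampled_gy) == 101
        anchor_doses = [p.dose_gy for p in prof.points]
        for d in anchor_doses:
            assert d in prof.resampled_gy

    def test_alternation_and_ordering_enforced(self, coarse_field):
        lattice, grid, dose, masks = coarse_field
        peaks = find_peaks(dose, masks)
        with pytest.raises(ValueError, match="k peaks"):
            assemble_profile(peaks[:3], [], "LAT", dose)
        # non-monotone anchors rejected
        pk = make_points(0, [0, 30], [20, 21], "pp")
        vl = make_points(0, [50], [5], "v")  # valley beyond second peak
        with pytest.raises(ValueError, match="ordered"):
            assemble_profile(pk, vl, "LAT", dose)

    def test_resampling_converges_on_smooth_field(self):
        grid = GridSpec(shape=(81, 81, 81), spacing=(1.0,) * 3,
                        origin=(-40.0,) * 3)
        dose = self.analytic_dose(grid)
        # slightly non-collinear anchors on the smooth field
        xs = [-30.0, -15.0, 0.0, 15.0, 30.0]
        ys = [0.0, 1.0, 0.0, -1.0, 0.0]
        anchors = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            d = float(10.0 * np.exp(-(x ** 2 + y ** 2) / (2 * 30.0 ** 2)) + 1.0)
            anchors.append((x, y, d))
        peaks = [PeakPoint(i, (x, y, 0.0), d)
                 for i, (x, y, d) in enumerate(anchors[0::2])]
        valleys = [ValleyPoint((i, i + 1), (x, y, 0.0), d)
                   for i, (x, y, d) in enumerate(anchors[1::2])]

        def analytic_on_polyline(n):
            prof = assemble_profile(peaks, valleys, "LAT", dose, n_stations=n)
            coords = np.array([p.position_mm for p in prof.points])
            seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            s = prof.stations_mm
            x = np.interp(s, arc, coords[:, 0])
            y = np.interp(s, arc, coords[:, 1])
            exact = 10.0 * np.exp(-(x ** 2 + y ** 2) / (2 * 30.0 ** 2)) + 1.0
            return np.max(np.abs(prof.resampled_gy - exact))

        # max error is dominated by the anchor-to-nearest-station snap and
        # shrinks as the station count doubles
        # down to the trilinear interpolation floor of the 1 mm grid
        errs = [analytic_on_polyline(n) for n in (26, 101, 401)]
        assert errs[0] > errs[1]
        assert max(errs[1], errs[2]) < 0.01


class TestProfileVpdr:
    def test_direct_arithmetic(self):
        pk = make_points(2, [0, 30, 60], [20.0, 20.0, 20.0], "ppp")
        vl = make_points(2, [15, 45], [10.0, 12.0], "vv")
        prof = DoseProfile("SI", (pk[0], vl[0], pk[1], vl[1], pk[2]),
                           np.linspace(0, 60, 5), np.zeros(5))
        assert profile_vpdr(prof) == pytest.approx(50.0)

    def test_valleys_equal_peaks_give_100(self):
        pk = make_points(2, [0, 30, 60], [7.0, 7.0, 7.0], "ppp")
        vl = make_points(2, [15, 45], [7.0, 7.0], "vv")
        prof = DoseProfile("SI", (pk[0], vl[0], pk[1], vl[1], pk[2]),
                           np.linspace(0, 60, 5), np.zeros(5))
        assert profile_vpdr(prof) == pytest.approx(100.0)

    def test_matches_bruteforce_on_random_anchors(self):
        rng = np.random.default_rng(SUITE_SEED)
        for _ in range(50):
            peaks = rng.uniform(10, 25, size=3)
            valleys = rng.uniform(1, 9, size=2)
            pk = make_points(2, [0, 30, 60], peaks, "ppp")
            vl = make_points(2, [15, 45], valleys, "vv")
            prof = DoseProfile("SI", (pk[0], vl[0], pk[1], vl[1], pk[2]),
                               np.linspace(0, 60, 5), np.zeros(5))
            assert profile_vpdr(prof) == pytest.approx(
                100.0 * min(valleys) / max(peaks))

    def test_zero_peak_rejected(self):
        pk = make_points(2, [0, 30, 60], [0.0, 0.0, 0.0], "ppp")
        vl = make_points(2, [15, 45], [0.0, 0.0], "vv")
        prof = DoseProfile("SI", (pk[0], vl[0], pk[1], vl[1], pk[2]),
                           np.linspace(0, 60, 5), np.zeros(5))
        with pytest.raises(ValueError):
            profile_vpdr(prof)


class TestDirectionalVpdr:
    def test_nine_values_per_direction(self, rep_field):
        lattice, grid, params, masks, dose = rep_field
        for direction in ("AP", "LAT", "SI"):
            res = directional_vpdr(dose, lattice, masks, direction)
            assert res.values.shape == (9,)
            assert np.all((res.values > 0) & (res.values <= 100))

    def test_transverse_symmetry_in_noiseless_field(self):
        lattice, grid, params, masks, dose = simulated_config(
            1.0, 2.0, "noncoplanar", noise_sigma=0.0)
        ap = directional_vpdr(dose, lattice, masks, "AP")
        lat = directional_vpdr(dose, lattice, masks, "LAT")
        assert ap.mean == pytest.approx(lat.mean, rel=1e-6)

    def test_coplanar_si_below_transverse(self, rep_field):
        lattice, grid, params, masks, dose = rep_field
        res = {d: directional_vpdr(dose, lattice, masks, d)
               for d in ("AP", "LAT", "SI")}
        assert res["SI"].mean < res["AP"].mean
        assert res["SI"].mean < res["LAT"].mean

    def test_scale_invariance(self, rep_field):
        lattice, grid, params, masks, dose = rep_field
        base = directional_vpdr(dose, lattice, masks, "SI").values
        scaled = directional_vpdr(dose.scaled(3.7), lattice, masks,
                                  "SI").values
        np.testing.assert_allclose(base, scaled, rtol=1e-12)

    def test_single_row_lattice_rejected_along_direction(self):
        lattice = LatticeSpec(1.0, 2.0, counts=(3, 3, 1))
        grid = compact_grid(LatticeSpec(1.0, 2.0), spacing_mm=4.0)
        masks = build_vertex_masks(lattice, grid)
        dose = simulate_dose(lattice, SimParams(noise_sigma=0.0), grid)
        with pytest.raises(ValueError, match=">= 2"):
            directional_vpdr(dose, lattice, masks, "SI")
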
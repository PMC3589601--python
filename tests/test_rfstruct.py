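"""RF structure statistics: enumerated cases and construction oracles."""

import numpy as np
import pytest

from rfmotion.config import GridSpec
from rfmotion.nullstats import PolarObservations
from rfmotion.rfstruct import (count_peaks, detect_multiple_directions,
                               fit_rf_geometry, monotonicity_test,
                               percent_missing, split_subregions,
                               subregion_summary, supercover_line,
                               valley_over_peak)


def grid_of(nx, ny):
    return GridSpec(patch_size_deg=1.0, origin_x_deg=0.0, origin_y_deg=0.0,
                    nx=nx, ny=ny, n_dir_bins=8)


class TestSupercover:
    def test_axis_aligned(self):
        assert supercover_line((0, 0), (3, 0)) == [(0, 0), (1, 0), (2, 0), (3, 0)]

    def test_diagonal_touches_corner_neighbors(self):
        cells = set(supercover_line((0, 0), (2, 2)))
        assert {(0, 0), (1, 1), (2, 2)} <= cells
        assert {(0, 1), (1, 0)} <= cells or {(1, 2), (2, 1)} <= cells

    def test_endpoints_always_included(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = tuple(rng.integers(-5, 6, 2))
            b = tuple(rng.integers(-5, 6, 2))
            cells = supercover_line(a, b)
            assert cells[0] == a and cells[-1] == b
            # contiguity: consecutive cells share an edge or corner
            for (x0, y0), (x1, y1) in zip(cells, cells[1:]):
                assert max(abs(x1 - x0), abs(y1 - y0)) <= 1


class TestCountPeaks:
    def test_blob_counts(self):
        p = np.ones((9, 12))
        p[1:4, 1:4] = 0.001          # one blob
        assert count_peaks(p) == 1
        p[5:8, 8:11] = 0.001         # second blob, far away
        assert count_peaks(p) == 2

    def test_empty_map(self):
        assert count_peaks(np.ones((5, 5))) == 0


class TestPercentMissing:
    def test_solid_rectangle(self):
        mask = np.zeros((6, 6), bool)
        mask[1:4, 2:5] = True
        assert percent_missing(mask) == 0.0

    def test_two_endpoint_line(self):
        """Patches at (0,0) and (4,0): the hull is a segment through five
        patch centers, three of which are missing -> 60%."""
        mask = np.zeros((3, 6), bool)
        mask[0, 0] = mask[0, 4] = True
        assert percent_missing(mask) == pytest.approx(60.0)

    def test_single_patch(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 2] = True
        assert percent_missing(mask) == 0.0

    def test_ring_has_missing_interior(self):
        mask = np.zeros((7, 7), bool)
        mask[1:6, 1:6] = True
        mask[2:5, 2:5] = False
        pm = percent_missing(mask)
        assert pm == pytest.approx(100.0 * 9 / 25)


class TestValleyOverPeak:
    def test_line_profile_ratio(self):
        """Strengths [10, 2, 8] along a line: primary 10, secondary 8,
        valley 2 -> ratio 0.25."""
        grid = grid_of(5, 3)
        strength = np.zeros(grid.n_patches)
        mask = np.zeros((3, 5), bool)
        for x, v in [(1, 10.0), (2, 2.0), (3, 8.0)]:
            strength[1 * 5 + x] = v
            mask[1, x] = True
        assert valley_over_peak(strength, mask, grid) == pytest.approx(0.25)

    def test_monotone_hill_returns_none(self):
        grid = grid_of(5, 3)
        strength = np.zeros(grid.n_patches)
        mask = np.zeros((3, 5), bool)
        for x, v in [(0, 10.0), (1, 7.0), (2, 5.0), (3, 2.0)]:
            strength[1 * 5 + x] = v
            mask[1, x] = True
        assert valley_over_peak(strength, mask, grid) is None

    def test_zero_valley_gives_zero_ratio(self):
        grid = grid_of(5, 3)
        strength = np.zeros(grid.n_patches)
        mask = np.zeros((3, 5), bool)
        for x, v in [(1, 10.0), (2, 0.0), (3, 8.0)]:
            strength[1 * 5 + x] = v
            mask[1, x] = True
        assert valley_over_peak(strength, mask, grid) == pytest.approx(0.0)


class TestSubregions:
    def test_block_diagonal_recovery(self):
        """A block-diagonal similarity matrix (two mutually similar groups)
        is split exactly."""
        n1, n2 = 4, 3
        S = np.full((7, 7), 0.001)
        S[:n1, :n1] = 0.9
        S[n1:, n1:] = 0.9
        np.fill_diagonal(S, 1.0)
        labels = split_subregions(S, seed=0)
        assert len(set(labels[:n1])) == 1
        assert len(set(labels[n1:])) == 1
        assert labels[0] != labels[-1]

    def test_two_patches_one_each(self):
        S = np.array([[1.0, 0.001], [0.001, 1.0]])
        labels = split_subregions(S, seed=1)
        assert sorted(labels) == [0, 1]

    def test_summary_ratios(self):
        """Region B = region A with all PD lengths halved: relative strength
        50%, relative size 100% (linearity of the vector sum)."""
        angles = np.array([10.0, 20.0, 30.0, 10.0, 20.0, 30.0])
        lengths = np.array([2.0, 3.0, 4.0, 1.0, 1.5, 2.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        s = subregion_summary(labels, angles, lengths)
        assert s.relative_strength_pct == pytest.approx(50.0)
        assert s.relative_size_pct == pytest.approx(100.0)
        assert s.size_normalized_strength_pct == pytest.approx(50.0)
        assert s.directional_range_deg == pytest.approx(0.0, abs=1e-9)

    def test_directional_range(self):
        angles = np.array([0.0, 0.0, 90.0, 90.0])
        lengths = np.ones(4)
        s = subregion_summary(np.array([0, 0, 1, 1]), angles, lengths)
        assert s.directional_range_deg == pytest.approx(90.0)

    def test_mirror_regions_symmetric(self):
        angles = np.array([0.0, 10.0, 180.0, 190.0])
        lengths = np.array([1.0, 2.0, 1.0, 2.0])
        s = subregion_summary(np.array([0, 0, 1, 1]), angles, lengths)
        assert s.relative_strength_pct == pytest.approx(100.0)
        assert s.relative_size_pct == pytest.approx(100.0)


class TestGeometry:
    @staticmethod
    def sampled_gaussian(grid, x0, y0, s_long, s_short, theta_deg, amp=5.0):
        cx, cy = np.meshgrid(grid.patch_centers_x, grid.patch_centers_y)
        th = np.deg2rad(theta_deg)
        u = (cx - x0) * np.cos(th) + (cy - y0) * np.sin(th)
        v = -(cx - x0) * np.sin(th) + (cy - y0) * np.cos(th)
        return (amp * np.exp(-0.5 * ((u / s_long) ** 2 + (v / s_short) ** 2))).ravel()

    def test_noiseless_recovery(self):
        grid = GridSpec.centered(20, 16, n_dir_bins=8)
        strength = self.sampled_gaussian(grid, 1.0, -2.0, 2.0, 1.0, 30.0)
        mask = grid.as_map(strength) > 0.5
        pd = np.full(grid.n_patches, 120.0)   # perpendicular to the long axis
        geo = fit_rf_geometry(strength, pd, strength, mask, grid)
        assert geo is not None and geo.converged
        assert geo.sigma_long_deg == pytest.approx(2.0, rel=0.01)
        assert geo.sigma_short_deg == pytest.approx(1.0, rel=0.01)
        assert geo.size_deg == pytest.approx(3.0, rel=0.01)
        assert geo.elongation == pytest.approx(2.0, rel=0.02)
        assert geo.orientation_deg == pytest.approx(30.0, abs=1.0)
        assert geo.pd_axis_angle_deg == pytest.approx(90.0, abs=1.0)

    def test_isotropic_elongation_one(self):
        grid = GridSpec.centered(16, 16, n_dir_bins=8)
        strength = self.sampled_gaussian(grid, 0.0, 0.0, 1.5, 1.5, 0.0)
        mask = grid.as_map(strength) > 0.5
        pd = np.full(grid.n_patches, 45.0)
        geo = fit_rf_geometry(strength, pd, strength, mask, grid)
        assert geo.elongation == pytest.approx(1.0, abs=0.02)

    def test_too_few_patches(self):
        grid = grid_of(5, 5)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert fit_rf_geometry(np.ones(25), np.ones(25), np.ones(25), mask,
                               grid) is None


def synthetic_obs(grid, pds, strengths, n_blocks=80, noise=0.5, seed=0):
    """Block observations for given per-patch PDs and strengths."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(pds))
    vecs = np.empty((len(ids), n_blocks, 2))
    for i, pid in enumerate(ids):
        th = np.deg2rad(pds[pid])
        base = strengths[pid] * np.array([np.cos(th), np.sin(th)])
        vecs[i] = base[None, :] + rng.normal(0, noise, (n_blocks, 2))
    return PolarObservations(patch_ids=ids, vectors=vecs)


class TestDetectMultipleDirections:
    def test_two_groups_positive(self):
        grid = grid_of(6, 3)
        ids = [7, 8, 9, 10]
        pds = {7: 0.0, 8: 0.0, 9: 90.0, 10: 90.0}
        strengths = {i: 2.0 for i in ids}
        obs = synthetic_obs(grid, pds, strengths, seed=1)
        res = detect_multiple_directions(np.array(ids), obs, seed=2)
        assert res.positive
        assert res.n_pairs == 6

    def test_homogeneous_negative(self):
        grid = grid_of(6, 3)
        ids = [7, 8, 9]
        pds = {i: 45.0 for i in ids}
        strengths = {i: 1.0 for i in ids}
        obs = synthetic_obs(grid, pds, strengths, noise=1.0, seed=3)
        res = detect_multiple_directions(np.array(ids), obs, seed=4)
        assert not res.positive

    def test_single_patch_negative(self):
        res = detect_multiple_directions(np.array([5]), None, seed=0)
        assert not res.positive and res.n_pairs == 0


class TestMonotonicity:
    def make_ridge(self, values):
        """A 1 x n ridge RF on a 3-row grid with given strengths."""
        grid = grid_of(len(values) + 2, 3)
        mask = np.zeros((3, grid.nx), bool)
        strength = np.zeros(grid.n_patches)
        pds, strengths = {}, {}
        for i, v in enumerate(values):
            x = i + 1
            mask[1, x] = True
            fid = 1 * grid.nx + x
            strength[fid] = v
            pds[fid] = 0.0
            strengths[fid] = v
        return grid, mask, strength, pds, strengths

    def test_decreasing_ridge_monotonic(self):
        grid, mask, strength, pds, strengths = self.make_ridge([5.0, 3.0, 1.5])
        obs = synthetic_obs(grid, pds, strengths, noise=0.4, seed=5)
        res = monotonicity_test(strength, mask, obs, grid, seed=6)
        assert not res.multi_peaked

    def test_strength_rebound_flagged(self):
        """A strong rebound beyond a weak patch violates monotone decrease."""
        grid, mask, strength, pds, strengths = self.make_ridge([5.0, 0.5, 4.5])
        obs = synthetic_obs(grid, pds, strengths, noise=0.3, n_blocks=150, seed=7)
        res = monotonicity_test(strength, mask, obs, grid, seed=8)
        assert res.multi_peaked

    def test_single_patch_monotonic(self):
        grid = grid_of(4, 3)
        mask = np.zeros((3, 4), bool)
        mask[1, 1] = True
        res = monotonicity_test(np.ones(grid.n_patches), mask, None, grid, seed=0)
        assert not res.multi_peaked and res.n_pairs == 0
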
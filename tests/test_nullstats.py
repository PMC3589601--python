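"""Null calibration, cluster correction, and the percentile bootstraps."""

import numpy as np
import pytest

from rfmotion.config import GridSpec
from rfmotion.encode import sdh_from_dense
from rfmotion.nullstats import (bootstrap_direction_test,
                                bootstrap_strength_test, cluster_correct,
                                fit_null, null_sta, patch_significance,
                                polar_block_observations)
from rfmotion.sta import compute_sta


def toy_sdh(seed=0, n_trials=2, n_frames=100, nx=3, ny=2, nbins=8):
    grid = GridSpec(patch_size_deg=1, origin_x_deg=0, origin_y_deg=0,
                    nx=nx, ny=ny, n_dir_bins=nbins)
    rng = np.random.default_rng(seed)
    dense = rng.poisson(0.4, (n_trials * n_frames, nx * ny, nbins))
    return sdh_from_dense(dense, grid, n_trials, n_frames), dense


class TestNullSTA:
    def test_single_nonzero_bin_mirrors_stimulus(self):
        """With one nonzero response bin, the null STA picks out the
        time-mirrored stimulus frame."""
        sdh, dense = toy_sdh(seed=1, n_trials=1)
        resp = np.zeros((1, 100))
        resp[0, 30] = 1.0
        lag = 3
        nsta, _, _ = null_sta(resp, sdh, lag)
        # reversed response has its nonzero at index 99 - 30 = 69, which
        # correlates with the stimulus frame 69 - lag = 66
        expected = dense[66] / (100 - lag)
        assert np.allclose(nsta, expected, atol=1e-12)

    def test_total_mass_preserved(self, small_config, small_grid):
        """Response reversal preserves marginals: with the full-field dot
        stimulus (constant per-frame dot count) the summed STA mass of the
        forward and null STA agree exactly at lag 0."""
        from rfmotion.stimulus import generate_bmdots
        from rfmotion.encode import build_sdh

        traj = generate_bmdots(small_config.with_(n_trials=2), seed=21)
        sdh = build_sdh(traj, small_grid)
        rng = np.random.default_rng(3)
        resp = rng.normal(size=(2, sdh.n_frames))
        fwd = compute_sta(resp, sdh, 0)
        rev, _, _ = null_sta(resp, sdh, 0)
        assert fwd.sum() == pytest.approx(rev.sum(), abs=1e-9 * np.abs(fwd).sum())


class TestFitNull:
    def test_degenerate_pool_closed_form(self):
        """Pool all equal to L0: sigma^2 = L0^2/2 and p(L0) = 1/e."""
        model = fit_null(np.full(100, 2.5))
        assert model.sigma2 == pytest.approx(2.5 ** 2 / 2)
        assert model.pvalue(2.5) == pytest.approx(np.exp(-1.0))

    def test_p_of_zero_is_one_and_monotone(self):
        model = fit_null(np.array([1.0, 2.0, 3.0]))
        assert model.pvalue(0.0) == pytest.approx(1.0)
        L = np.linspace(0, 5, 50)
        p = model.pvalue(L)
        assert np.all(np.diff(p) < 0)

    def test_all_zero_pool_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_null(np.zeros(10))

    def test_boundary_exclusion(self):
        """L^2 = 2 sigma^2 ln(100) sits exactly at p = 0.01 and is excluded
        under the strict inequality."""
        model = fit_null(np.full(50, 1.0))   # sigma2 = 0.5
        L = np.sqrt(2 * model.sigma2 * np.log(100.0))
        p, sig = patch_significance(np.array([L]), model, alpha=0.01)
        assert p[0] == pytest.approx(0.01)
        assert not sig[0]


class TestClusterCorrect:
    def test_isolated_patch_removed(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert not cluster_correct(mask).any()

    def test_2x2_block_kept(self):
        mask = np.zeros((5, 5), bool)
        mask[1:3, 1:3] = True
        assert np.array_equal(cluster_correct(mask), mask)

    def test_1x3_row_removed(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 1:4] = True
        assert not cluster_correct(mask).any()

    def test_monotone_in_input(self):
        rng = np.random.default_rng(4)
        mask = rng.random((10, 10)) < 0.3
        kept = cluster_correct(mask)
        grown = mask.copy()
        grown[0, 0] = grown[5, 5] = True
        kept_grown = cluster_correct(grown)
        assert np.all(kept_grown[kept])


def tuned_blocks(rng, n_blocks, pd_deg, strength=1.0, noise=0.3):
    """Synthetic per-block resultants of a tuned patch."""
    base = strength * np.array([np.cos(np.deg2rad(pd_deg)),
                                np.sin(np.deg2rad(pd_deg))])
    return base[None, :] + rng.normal(0, noise, (n_blocks, 2))


class TestBootstrapDirection:
    def test_identical_data_p_one(self):
        rng = np.random.default_rng(5)
        obs = tuned_blocks(rng, 50, 45.0)
        assert bootstrap_direction_test(obs, obs, seed=1) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("delta,bound", [(90.0, 1e-3), (135.0, 1e-3),
                                             (180.0, 0.05)])
    def test_separated_pds_significant(self, delta, bound):
        """Strongly tuned patches with well-separated PDs reject decisively.

        At exactly 180 deg the pooled null is balanced-bimodal (the pooled
        resultant cancels, so null replicates also concentrate near 180) and
        the attainable p-value plateaus at the percent level; at any smaller
        separation the null collapses toward 0 and p reaches the resolution
        floor.
        """
        rng = np.random.default_rng(6)
        a = tuned_blocks(rng, 100, 0.0)
        b = tuned_blocks(rng, 100, delta)
        p = bootstrap_direction_test(a, b, seed=2, n_boot=5000,
                                     n_boot_max=50_000, p_stop=1e-4)
        assert p < bound

    def test_rotation_invariance(self):
        """Globally rotating all directions in both patches leaves p
        unchanged (identical RNG stream)."""
        rng = np.random.default_rng(7)
        a = tuned_blocks(rng, 60, 20.0)
        b = tuned_blocks(rng, 60, 80.0)
        phi = np.deg2rad(123.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        p1 = bootstrap_direction_test(a, b, seed=3)
        p2 = bootstrap_direction_test(a @ rot.T, b @ rot.T, seed=3)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_type_one_error_controlled(self):
        """Patches drawn from one common tuned distribution reject at about
        the nominal rate."""
        rng = np.random.default_rng(8)
        alpha = 0.1
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            a = tuned_blocks(rng, 40, 30.0, noise=1.0)
            b = tuned_blocks(rng, 40, 30.0, noise=1.0)
            if bootstrap_direction_test(a, b, seed=rng) < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep < alpha + 3 * se

    def test_zero_resultant_rejected(self):
        a = np.array([[1.0, 0.0], [-1.0, 0.0]])
        b = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero resultant"):
            bootstrap_direction_test(a, b, seed=0)


class TestBootstrapStrength:
    def test_identical_data_p_half(self):
        rng = np.random.default_rng(9)
        obs = tuned_blocks(rng, 80, 10.0)
        p = bootstrap_strength_test(obs, obs, seed=1)
        assert 0.3 < p < 0.7

    def test_five_to_one_ratio_significant(self):
        rng = np.random.default_rng(10)
        strong = tuned_blocks(rng, 100, 0.0, strength=5.0)
        weak = tuned_blocks(rng, 100, 0.0, strength=1.0)
        p = bootstrap_strength_test(strong, weak, seed=2, p_stop=5e-4)
        assert p < 0.05 / 100   # Bonferroni-corrected for 100 comparisons

    def test_rotation_isolates_strength(self):
        """Equal-strength patches with different PDs are not flagged: the
        alignment step removes the direction difference."""
        rng = np.random.default_rng(11)
        a = tuned_blocks(rng, 80, 0.0, strength=2.0)
        b = tuned_blocks(rng, 80, 90.0, strength=2.0)
        p = bootstrap_strength_test(a, b, seed=3)
        assert p > 0.05


class TestPolarObservations:
    def test_block_vectors_reconstruct_sta_resultant(self):
        """Summing a patch's block vectors equals the (unnormalised) STA
        resultant of that patch over whole blocks."""
        sdh, dense = toy_sdh(seed=12, n_trials=2, n_frames=100)
        rng = np.random.default_rng(13)
        resp = rng.normal(size=(2, 100))
        lag = 2
        block_frames = 10
        ids = np.arange(sdh.grid.n_patches)
        obs = polar_block_observations(resp, sdh, lag, ids, block_frames)
        theta = np.deg2rad(sdh.grid.dir_bin_centers_deg)
        for p in ids:
            total = np.zeros(2)
            for trial in range(2):
                for f in range(100 - lag):
                    if f >= (100 // block_frames) * block_frames:
                        continue
                    w = resp[trial, f + lag] * dense[trial * 100 + f, p]
                    total[0] += np.sum(w * np.cos(theta))
                    total[1] += np.sum(w * np.sin(theta))
            assert np.allclose(obs.for_patch(p).sum(axis=0), total, atol=1e-9)
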
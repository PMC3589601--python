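"""Null calibration and resampling tests for the reverse-correlation maps.

Null model
    Reversing the response in time destroys the causal stimulus-response
    correlation while preserving the marginal statistics of both stimulus and
    spike counts.  The PD vectors of the resulting "null STA", pooled over
    patches, calibrate significance: a null PD is the resultant of many weak
    independent contributions, so its two components are approximately
    Gaussian and the squared length follows sigma^2 * chi^2 with 2 degrees of
    freedom.  Hence p(L) = exp(-L^2 / (2 sigma^2)) with sigma^2 estimated as
    mean(L^2)/2 over the pool.

Receptive field
    Patches significant at p < alpha (default 0.01) form the RF, after a
    cluster correction that keeps only patches with >= 3 significant
    8-connected neighbours.

Bootstrap tests
    Percentile-bootstrap comparisons of direction preference and of tuning
    strength between two patches.  The resampling unit is a 200 ms block of
    data (the timescale at which the stimulus is independent); the null pools
    the blocks of both patches and redraws sets of the original sizes with
    replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .encode import SparseSDH

__all__ = [
    "NullModel",
    "PolarObservations",
    "null_sta",
    "fit_null",
    "patch_significance",
    "cluster_correct",
    "polar_block_observations",
    "bootstrap_direction_test",
    "bootstrap_strength_test",
]


# ---------------------------------------------------------------------------
# Null model


@dataclass
class NullModel:
    """Chi-square (df=2) model of null PD lengths."""

    sigma2: float
    pool: np.ndarray

    def pvalue(self, length) -> np.ndarray:
        """Probability of a null PD at least this long."""
        L = np.asarray(length, dtype=float)
        return np.exp(-(L ** 2) / (2.0 * self.sigma2))


def null_sta(resp: np.ndarray, sdh: SparseSDH, latency_frames: int):
    """STA of the time-reversed response: the empirical null.

    The session-concatenated response sequence is reversed (which reverses
    both the trial order and time within each trial), then the standard STA
    and per-patch PD vectors are computed.

    Returns ``(null_sta, null_pd_angle_deg, null_pd_length)``.
    """
    from .sta import compute_sta, pd_vector

    resp = np.asarray(resp, dtype=float)
    resp_rev = resp.ravel()[::-1].reshape(resp.shape)
    sta = compute_sta(resp_rev, sdh, latency_frames)
    angle, length = pd_vector(sta)
    return sta, angle, length


def fit_null(pool: np.ndarray) -> NullModel:
    """Fit the null PD length distribution: L^2 ~ sigma^2 * chi^2_2.

    The per-axis variance is estimated as mean(L^2)/2, the maximum-likelihood
    estimate under the isotropic bivariate-Gaussian resultant model.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0 or not np.any(pool > 0):
        raise ValueError("cannot fit a null model to an all-zero pool")
    sigma2 = float(np.mean(pool ** 2) / 2.0)
    return NullModel(sigma2=sigma2, pool=pool)


def patch_significance(
    pd_length: np.ndarray, null_model: NullModel, alpha: float = 0.01
):
    """Per-patch tuning-strength p-values and the strict-alpha mask."""
    p = null_model.pvalue(pd_length)
    return p, p < alpha


def cluster_correct(mask: np.ndarray, min_neighbors: int = 3) -> np.ndarray:
    """Keep significant patches with >= min_neighbors significant
    8-connected neighbours (single pass on the input mask)."""
    mask = np.asarray(mask, dtype=bool)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    n_neighbors = ndimage.convolve(mask.astype(int), kernel, mode="constant", cval=0)
    return mask & (n_neighbors >= min_neighbors)


# ---------------------------------------------------------------------------
# Polar block observations


@dataclass
class PolarObservations:
    """Per-patch direction/response data grouped into 200 ms blocks.

    ``vectors[i, b]`` is the 2-D resultant contributed by block b at patch
    ``patch_ids[i]``: the sum over dot-direction occurrences in that block of
    count * response(t + lag) * (cos theta, sin theta).  Only whole blocks
    are included.  The block resultants are sufficient for every resampling
    statistic used here (PD angle and resultant length are linear in them).
    """

    patch_ids: np.ndarray      # (n_req,)
    vectors: np.ndarray        # (n_req, n_blocks, 2)

    @property
    def n_blocks(self) -> int:
        return self.vectors.shape[1]

    def for_patch(self, patch_id: int) -> np.ndarray:
        i = int(np.flatnonzero(self.patch_ids == patch_id)[0])
        return self.vectors[i]


def polar_block_observations(
    resp: np.ndarray,
    sdh: SparseSDH,
    latency_frames: int,
    patch_ids: np.ndarray,
    block_frames: int,
) -> PolarObservations:
    """Collect the raw per-patch polar data behind the STA, in blocks.

    ``block_frames`` is the direction-epoch length in frames (200 ms at the
    stimulus frame rate); trailing frames that do not fill a whole block are
    excluded, as are frames whose lagged response falls outside the trial.
    """
    patch_ids = np.asarray(patch_ids)
    resp = np.asarray(resp, dtype=float)
    grid = sdh.grid
    blocks_per_trial = sdh.n_frames // block_frames
    n_blocks = sdh.n_trials * blocks_per_trial

    local = np.full(grid.n_patches, -1, dtype=np.int64)
    local[patch_ids] = np.arange(len(patch_ids))
    sel = (
        (local[sdh.patch] >= 0)
        & (sdh.frame + latency_frames < sdh.n_frames)
        & (sdh.frame < blocks_per_trial * block_frames)
    )
    w = resp[sdh.trial[sel], sdh.frame[sel] + latency_frames] * sdh.count[sel]
    theta = np.deg2rad(grid.dir_bin_centers_deg[sdh.dir_bin[sel]])
    block = sdh.trial[sel].astype(np.int64) * blocks_per_trial + sdh.frame[sel] // block_frames
    key = local[sdh.patch[sel]] * n_blocks + block
    size = len(patch_ids) * n_blocks
    vx = np.bincount(key, weights=w * np.cos(theta), minlength=size)
    vy = np.bincount(key, weights=w * np.sin(theta), minlength=size)
    vectors = np.stack([vx, vy], axis=-1).reshape(len(patch_ids), n_blocks, 2)
    return PolarObservations(patch_ids=patch_ids, vectors=vectors)


# ---------------------------------------------------------------------------
# Percentile bootstrap


def _resultant(vecs: np.ndarray) -> np.ndarray:
    return vecs.sum(axis=-2)


def _angle_deg(v: np.ndarray) -> np.ndarray:
    return np.rad2deg(np.arctan2(v[..., 1], v[..., 0])) % 360.0


def _circdiff_deg(a, b):
    d = np.mod(a - b, 360.0)
    return np.minimum(d, 360.0 - d)


def _check_blocks(vecs: np.ndarray, name: str) -> float:
    if vecs.shape[0] < 2:
        raise ValueError(f"{name}: at least 2 blocks are required")
    r = float(np.hypot(*vecs.sum(axis=0)))
    if r <= 0.0:
        raise ValueError(f"{name}: zero resultant, preferred direction undefined")
    return r


def _percentile_boot(
    pool: np.ndarray,
    n1: int,
    n2: int,
    observed: float,
    stat,
    rng: np.random.Generator,
    n_boot: int,
    n_boot_max: int,
    min_exceedances: int,
    p_stop: float,
) -> float:
    """Adaptive pooled-block resampling.

    Draws replicates in chunks until (a) the observed statistic has been met
    or exceeded ``min_exceedances`` times (enough relative precision anywhere
    near a rejection threshold), (b) the running p-value estimate has dropped
    below ``p_stop`` (the caller's decision threshold — further replicates
    cannot change the decision), or (c) ``n_boot_max`` replicates have been
    used.  The returned p-value uses the (1 + exceedances) / (1 + n)
    permutation estimator, which can never be exactly zero.
    """
    # float32 halves the memory traffic of the gather-and-sum, which
    # dominates the cost; the statistics are far above float32 resolution
    pool = np.ascontiguousarray(pool, dtype=np.float32)
    n_pool = pool.shape[0]
    n_done = 0
    n_exc = 0
    chunk = int(n_boot)
    # keep each chunk's index array below ~8M entries
    max_chunk = max(256, int(8_000_000 / max(n1, n2)))
    while True:
        m = min(chunk, n_boot_max - n_done, max_chunk)
        if m <= 0:
            break
        s1 = pool[rng.integers(0, n_pool, (m, n1))].sum(axis=1)
        s2 = pool[rng.integers(0, n_pool, (m, n2))].sum(axis=1)
        n_exc += int((stat(s1, s2) >= observed - 1e-12).sum())
        n_done += m
        p_hat = (1.0 + n_exc) / (1.0 + n_done)
        if n_exc >= min_exceedances or n_done >= n_boot_max or p_hat < p_stop:
            break
        chunk *= 2
    return (1.0 + n_exc) / (1.0 + n_done)


def bootstrap_direction_test(
    obs_a: np.ndarray,
    obs_b: np.ndarray,
    seed,
    n_boot: int = 1000,
    n_boot_max: int = 100_000,
    min_exceedances: int = 100,
    p_stop: float = 0.0,
) -> float:
    """Percentile-bootstrap test for a difference in preferred direction.

    ``obs_a``/``obs_b`` are (n_blocks, 2) block-resultant arrays of the two
    patches.  Each patch's data are first normalised to unit resultant length
    so that only angles matter; the observed statistic is the absolute
    circular difference between the two PD angles.  The null pools the
    normalised blocks of both patches and resamples sets of the original
    sizes; p is the fraction of null differences at least as large.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ra = _check_blocks(obs_a, "patch A")
    rb = _check_blocks(obs_b, "patch B")
    a = np.asarray(obs_a, dtype=float) / ra
    b = np.asarray(obs_b, dtype=float) / rb
    observed = float(_circdiff_deg(_angle_deg(a.sum(axis=0)), _angle_deg(b.sum(axis=0))))
    pool = np.concatenate([a, b], axis=0)

    def stat(s1, s2):
        return _circdiff_deg(_angle_deg(s1), _angle_deg(s2))

    return _percentile_boot(pool, len(a), len(b), observed, stat, rng,
                            n_boot, n_boot_max, min_exceedances, p_stop)


def bootstrap_strength_test(
    obs_a: np.ndarray,
    obs_b: np.ndarray,
    seed,
    n_boot: int = 1000,
    n_boot_max: int = 100_000,
    min_exceedances: int = 100,
    p_stop: float = 0.0,
) -> float:
    """Percentile-bootstrap test for a difference in tuning strength.

    Patch B's directions are first rotated so both patches share the same
    preferred direction, isolating strength from direction preference.  The
    observed statistic is R_A - R_B (difference of resultant lengths); the
    one-sided p-value is the fraction of pooled-resample differences at least
    as large, so a small p is evidence that patch A is the stronger one.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ra = _check_blocks(obs_a, "patch A")
    rb = _check_blocks(obs_b, "patch B")
    a = np.asarray(obs_a, dtype=float)
    b = np.asarray(obs_b, dtype=float)
    phi = np.deg2rad(_angle_deg(a.sum(axis=0)) - _angle_deg(b.sum(axis=0)))
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    b = b @ rot.T
    observed = ra - rb
    pool = np.concatenate([a, b], axis=0)

    def stat(s1, s2):
        return np.hypot(s1[:, 0], s1[:, 1]) - np.hypot(s2[:, 0], s2[:, 1])

    return _percentile_boot(pool, len(a), len(b), observed, stat, rng,
                            n_boot, n_boot_max, min_exceedances, p_stop)
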
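"""Spike-triggered averaging of the space-direction histogram.

The STA at latency D is the cross-correlation between the selective response
and the stimulus histogram,

    STA(p, d) = sum_t r(t + D) * S_t(p, d) / N_frames,

accumulated sparsely over the nonzero histogram cells.  Under the usual
reverse-correlation assumptions it is a complete direction tuning curve
(64 bins) for every 1-degree patch.  Each patch's curve is reduced to a
preferred-direction (PD) vector — the vector sum of the per-bin values at the
bin-center angles — whose angle is the locally preferred direction and whose
length is the local tuning strength.  The analysis latency is the one that
maximises the summed PD length over patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import GridSpec
from .encode import SparseSDH

__all__ = [
    "STAResult",
    "PolarityLabels",
    "compute_sta",
    "pd_vector",
    "select_latency",
    "label_polarity",
    "similarity_index",
    "split_half_similarity",
]


@dataclass
class STAResult:
    """STA at the selected latency plus the latency-selection profile."""

    sta: np.ndarray                 # (n_patches, n_dir_bins)
    latency_frames: int
    latency_ms: float
    lags_frames: np.ndarray         # candidate lags
    latency_profile: np.ndarray     # summed PD length per candidate lag
    baseline: np.ndarray            # per-direction mean across patches
    pd_angle_deg: np.ndarray        # (n_patches,)
    pd_length: np.ndarray           # (n_patches,)
    grid: GridSpec


@dataclass
class PolarityLabels:
    """Excitatory/suppressive labels relative to the null-STA mean."""

    excitatory: np.ndarray          # (n_patches, n_dir_bins) bool
    patch_suppressive: np.ndarray   # (n_patches,) bool


def compute_sta(
    resp: np.ndarray,
    sdh: SparseSDH,
    latency_frames: int,
    trials: np.ndarray | None = None,
) -> np.ndarray:
    """Sparse cross-correlation of the response with the stimulus histogram.

    ``resp`` is the (n_trials, n_frames) selective response.  Frames whose
    lagged response falls beyond the trial end are skipped.  ``trials``
    optionally restricts the accumulation to a subset of trials (used by the
    split-half validation).  Normalisation is by the number of contributing
    (trial, frame) bins; any positive scaling cancels downstream.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.shape != (sdh.n_trials, sdh.n_frames):
        raise ValueError("response shape does not match the SDH session structure")
    if latency_frames < 0:
        raise ValueError("latency must be non-negative")
    if not np.any(resp):
        warnings.warn("compute_sta: response is identically zero")

    grid = sdh.grid
    valid = sdh.frame + latency_frames < sdh.n_frames
    n_trials_used = sdh.n_trials
    if trials is not None:
        member = np.zeros(sdh.n_trials, dtype=bool)
        member[np.asarray(trials)] = True
        valid &= member[sdh.trial]
        n_trials_used = int(member.sum())
    w = resp[sdh.trial[valid], sdh.frame[valid] + latency_frames] * sdh.count[valid]
    cell = sdh.patch[valid].astype(np.int64) * grid.n_dir_bins + sdh.dir_bin[valid]
    flat = np.bincount(cell, weights=w, minlength=grid.n_patches * grid.n_dir_bins)
    n_norm = max(1, n_trials_used * (sdh.n_frames - latency_frames))
    return flat.reshape(grid.n_patches, grid.n_dir_bins) / n_norm


def pd_vector(tuning: np.ndarray, n_dir_bins: int | None = None):
    """Preferred-direction vector of one or many direction tuning curves.

    ``tuning`` has direction bins on the last axis; angles are the bin
    centers.  Returns (angle_deg in [0, 360), length >= 0); any
    direction-independent (constant) component cancels exactly.
    """
    tuning = np.asarray(tuning, dtype=float)
    n = tuning.shape[-1] if n_dir_bins is None else n_dir_bins
    theta = np.deg2rad((np.arange(n) + 0.5) * 360.0 / n)
    vx = tuning @ np.cos(theta)
    vy = tuning @ np.sin(theta)
    angle = np.rad2deg(np.arctan2(vy, vx)) % 360.0
    return angle, np.hypot(vx, vy)


def select_latency(
    resp: np.ndarray, sdh: SparseSDH, max_latency_ms: float = 100.0
) -> STAResult:
    """Pick the analysis latency maximising summed PD length over patches.

    The lag grid is every frame from 0 to ``max_latency_ms``; ties break
    toward the smaller lag.
    """
    fr = sdh.frame_rate_hz
    max_lag = int(np.floor(max_latency_ms / 1000.0 * fr))
    lags = np.arange(0, max_lag + 1)
    scores = np.empty(len(lags))
    best = None
    for i, lag in enumerate(lags):
        sta = compute_sta(resp, sdh, int(lag))
        _, length = pd_vector(sta)
        scores[i] = length.sum()
        if best is None or scores[i] > best[1]:
            best = (int(lag), scores[i], sta)
    lag_sel, _, sta_sel = best
    angle, length = pd_vector(sta_sel)
    return STAResult(
        sta=sta_sel,
        latency_frames=lag_sel,
        latency_ms=lag_sel * 1000.0 / fr,
        lags_frames=lags,
        latency_profile=scores,
        baseline=sta_sel.mean(axis=0),
        pd_angle_deg=angle,
        pd_length=length,
        grid=sdh.grid,
    )


def label_polarity(sta: np.ndarray, null_mean) -> PolarityLabels:
    """Label STA cells excitatory/suppressive against the null-STA mean.

    A cell is excitatory if its STA value exceeds the null mean; a patch is
    suppressive if, summed over directions, suppression exceeds excitation
    (ties count as excitatory).
    """
    sta = np.asarray(sta, dtype=float)
    null_mean = np.broadcast_to(np.asarray(null_mean, dtype=float), sta.shape)
    diff = sta - null_mean
    excitatory = diff > 0
    suppression = np.clip(-diff, 0, None).sum(axis=1)
    excitation = np.clip(diff, 0, None).sum(axis=1)
    return PolarityLabels(excitatory=excitatory,
                          patch_suppressive=suppression > excitation)


def similarity_index(u: np.ndarray, v: np.ndarray) -> float:
    """Inner product of two normalised vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("similarity index undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def split_half_similarity(
    resp: np.ndarray, sdh: SparseSDH, latency_frames: int, seed: int
) -> float:
    """Reliability check: similarity of STAs from two random halves.

    Trials are split 50/50 at random (whole trials, preserving trial-locked
    structure); the similarity index of the two flattened STAs estimates the
    reproducibility of the map.
    """
    n = sdh.n_trials
    if n < 2:
        raise ValueError("split-half validation requires at least 2 trials")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]
    sta_a = compute_sta(resp, sdh, latency_frames, trials=half_a)
    sta_b = compute_sta(resp, sdh, latency_frames, trials=half_b)
    return similarity_index(sta_a, sta_b)
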
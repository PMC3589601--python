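"""Classical single-dot analyses and their comparison with the
reverse-correlation maps.

The single-dot paradigms (grid mapping and per-patch direction mapping) are
analysed the traditional way: mean firing rate in a 200 ms window after
stimulus onset, shifted by the neuron's onset latency.  The resulting rate
maps and tuning curves validate the reverse-correlation estimates — on the
same neuron the two approaches should agree (high similarity index, circular
correlation of preferred directions near 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._circular import circmean_deg
from .preprocess import SpikeData
from .sta import similarity_index
from .stimulus import PatchSchedule

__all__ = [
    "RateMap",
    "TuningCurve",
    "onset_latency",
    "gridrf_rate_map",
    "prefdir_tuning",
    "circular_correlation",
    "compare_maps",
]


@dataclass
class RateMap:
    """Mean firing rate per probed patch (single-dot grid mapping)."""

    patch_x_deg: np.ndarray
    patch_y_deg: np.ndarray
    rate_hz: np.ndarray
    n_epochs: np.ndarray


@dataclass
class TuningCurve:
    """Smoothed direction tuning of one probed patch.

    ``rate_hz[k]`` is the smoothed mean rate for direction ``directions_deg[k]``
    (circular, wraps at 360).  ``pd_deg`` is the circular mean of the rate
    distribution; None (flagged) when the resultant is zero.
    """

    patch_x_deg: float
    patch_y_deg: float
    directions_deg: np.ndarray
    rate_hz: np.ndarray
    raw_rate_hz: np.ndarray
    pd_deg: float | None
    interpolated: np.ndarray      # directions never shown, filled by smoothing


def onset_latency(
    rates: np.ndarray,
    times_s: np.ndarray,
    baseline_window_s: tuple[float, float],
    n_sd: float = 5.0,
) -> float:
    """Response onset latency from a PSTH, in ms.

    The first time at/after 0 at which the rate deviates from the baseline
    mean by more than ``n_sd`` baseline standard deviations, in either
    direction (suppressive onsets count).  Returns 0 with a warning if the
    response never crosses.
    """
    rates = np.asarray(rates, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    sel = (times_s >= baseline_window_s[0]) & (times_s < baseline_window_s[1])
    if sel.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 bins")
    mu, sd = rates[sel].mean(), rates[sel].std()
    if sd == 0:
        sd = np.finfo(float).tiny
    after = times_s >= 0
    crossed = after & (np.abs(rates - mu) > n_sd * sd)
    if not crossed.any():
        warnings.warn("onset_latency: response never crossed the threshold; returning 0")
        return 0.0
    return float(times_s[crossed][0] * 1000.0)


def _epoch_spike_counts(
    spikes: SpikeData, schedule: PatchSchedule, latency_ms: float,
    window_s: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike count per schedule epoch in the latency-adjusted response
    window; epochs whose window does not fit in the trial are masked out."""
    lat = latency_ms / 1000.0
    onset = schedule.onset_s + lat
    offset = onset + window_s
    ok = schedule.complete & (offset <= spikes.trial_duration_s + 1e-9)
    counts = np.zeros(len(schedule), dtype=float)
    for e in np.flatnonzero(ok):
        train = spikes.trains[schedule.trial[e]]
        counts[e] = np.searchsorted(train, offset[e]) - np.searchsorted(train, onset[e])
    return counts, ok


def gridrf_rate_map(
    spikes: SpikeData, schedule: PatchSchedule, latency_ms: float
) -> RateMap:
    """Average firing rate per probed patch in the 200 ms response window."""
    counts, ok = _epoch_spike_counts(spikes, schedule, latency_ms)
    keys = np.column_stack([schedule.patch_x_deg, schedule.patch_y_deg])
    uniq, inv = np.unique(keys.round(6), axis=0, return_inverse=True)
    n = np.bincount(inv[ok], minlength=len(uniq))
    tot = np.bincount(inv[ok], weights=counts[ok], minlength=len(uniq))
    with np.errstate(invalid="ignore"):
        rate = np.where(n > 0, tot / np.maximum(n, 1) / 0.2, np.nan)
    return RateMap(patch_x_deg=uniq[:, 0], patch_y_deg=uniq[:, 1],
                   rate_hz=rate, n_epochs=n)


def _wrapped_gaussian_smooth(values: np.ndarray, step_deg: float,
                             sigma_deg: float) -> np.ndarray:
    """Circular Gaussian smoothing on a uniformly sampled direction circle,
    with renormalisation over observed entries (NaNs are interpolated)."""
    n = len(values)
    offs = np.arange(n)
    d = np.minimum(offs, n - offs) * step_deg
    kernel = np.exp(-0.5 * (d / sigma_deg) ** 2)
    obs = np.isfinite(values)
    v = np.where(obs, values, 0.0)
    num = np.real(np.fft.ifft(np.fft.fft(v) * np.fft.fft(kernel)))
    den = np.real(np.fft.ifft(np.fft.fft(obs.astype(float)) * np.fft.fft(kernel)))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 1e-12, num / den, np.nan)


def prefdir_tuning(
    spikes: SpikeData,
    schedule: PatchSchedule,
    latency_ms: float,
    smooth_sigma_deg: float = 5.0,
) -> list[TuningCurve]:
    """Per-patch direction tuning curves from the single-dot paradigm.

    Mean rate per (patch, shown direction), smoothed with a wrapped Gaussian
    kernel (sigma = 5 deg); directions never shown in a patch are
    interpolated by the smoothing and flagged.  The preferred direction is
    the circular mean of the rate distribution.
    """
    counts, ok = _epoch_spike_counts(spikes, schedule, latency_ms)
    dirs = np.unique(schedule.direction_deg)
    step = 360.0 / len(dirs) if len(dirs) > 1 else 360.0
    keys = np.column_stack([schedule.patch_x_deg, schedule.patch_y_deg])
    patches, pinv = np.unique(keys.round(6), axis=0, return_inverse=True)
    dinv = np.searchsorted(dirs, schedule.direction_deg)
    curves = []
    for ip, (px, py) in enumerate(patches):
        raw = np.full(len(dirs), np.nan)
        for idd in range(len(dirs)):
            sel = ok & (pinv == ip) & (dinv == idd)
            if sel.any():
                raw[idd] = counts[sel].mean() / 0.2
        smooth = _wrapped_gaussian_smooth(raw, step, smooth_sigma_deg)
        w = np.where(np.isfinite(smooth), smooth, 0.0)
        try:
            pd = circmean_deg(dirs, w)
        except ValueError:
            warnings.warn("prefdir_tuning: flat tuning curve, PD undefined")
            pd = None
        curves.append(TuningCurve(
            patch_x_deg=float(px), patch_y_deg=float(py),
            directions_deg=dirs, rate_hz=smooth, raw_rate_hz=raw,
            pd_deg=pd, interpolated=~np.isfinite(raw),
        ))
    return curves


def circular_correlation(
    a_deg, b_deg, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Fisher-Lee circular correlation of paired angles, with permutation p.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) /
        sqrt(sum sin^2(a_i - a_j) * sum sin^2(b_i - b_j)),

    invariant to a rotation of either variable.  The p-value is two-sided,
    from random permutations of b.
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D angle arrays are required")
    if len(a) < 5:
        raise ValueError("at least 5 paired angles are required")

    def fl(a, b):
        sa = np.sin(a[:, None] - a[None, :])
        sb = np.sin(b[:, None] - b[None, :])
        num = np.sum(np.triu(sa * sb, 1))
        den = np.sqrt(np.sum(np.triu(sa ** 2, 1)) * np.sum(np.triu(sb ** 2, 1)))
        if den == 0:
            raise ValueError("circular correlation undefined for a constant vector")
        return num / den

    r = float(fl(a, b))
    rng = np.random.default_rng(seed)
    n_exc = 0
    for _ in range(n_perm):
        if abs(fl(a, rng.permutation(b))) >= abs(r) - 1e-12:
            n_exc += 1
    return r, (1.0 + n_exc) / (1.0 + n_perm)


def compare_maps(
    values_a: np.ndarray, values_b: np.ndarray,
    valid_a: np.ndarray | None = None, valid_b: np.ndarray | None = None,
) -> float:
    """Similarity index of two spatial maps over their common mapped patches."""
    values_a = np.asarray(values_a, dtype=float).ravel()
    values_b = np.asarray(values_b, dtype=float).ravel()
    valid_a = np.isfinite(values_a) if valid_a is None else np.asarray(valid_a, bool).ravel()
    valid_b = np.isfinite(values_b) if valid_b is None else np.asarray(valid_b, bool).ravel()
    both = valid_a & valid_b
    if not both.any():
        raise ValueError("maps share no mapped patches")
    return similarity_index(values_a[both], values_b[both])
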
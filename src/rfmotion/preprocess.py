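"""From raw spike trains to the binned selective response.

Spikes are binned at the monitor frame rate, then two non-selective
components are removed: (1) the trial-locked response — the cross-trial mean
per bin, Gaussian-smoothed (sigma = 10 ms) — which captures onset transients
and within-trial adaptation; (2) the per-trial mean rate, which captures
adaptation on a slower-than-trial timescale.  What remains ("the selective
response") is the stimulus-selective modulation that enters the
reverse-correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpikeData", "bin_spikes", "selective_response"]


@dataclass
class SpikeData:
    """Trial-structured spike times.

    ``trains[t]`` holds the sorted spike times (s, relative to trial start)
    of trial t; all trials share ``trial_duration_s`` and ``frame_rate_hz``.
    """

    trains: list
    trial_duration_s: float
    frame_rate_hz: float

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def mean_rate_hz(self) -> float:
        return self.n_spikes / (self.n_trials * self.trial_duration_s)

    def to_dataframe(self) -> pd.DataFrame:
        trial = np.repeat(np.arange(self.n_trials), [len(t) for t in self.trains])
        t_s = np.concatenate(self.trains) if self.n_spikes else np.empty(0)
        return pd.DataFrame({"trial": trial, "t_s": t_s})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_trials: int, trial_duration_s: float,
        frame_rate_hz: float,
    ) -> "SpikeData":
        trains = [
            np.sort(df.loc[df["trial"] == t, "t_s"].to_numpy(float))
            for t in range(n_trials)
        ]
        return cls(trains=trains, trial_duration_s=trial_duration_s,
                   frame_rate_hz=frame_rate_hz)

    @classmethod
    def from_csv(cls, path, n_trials: int, trial_duration_s: float,
                 frame_rate_hz: float) -> "SpikeData":
        return cls.from_dataframe(pd.read_csv(path), n_trials,
                                  trial_duration_s, frame_rate_hz)


def bin_spikes(spikes: SpikeData) -> np.ndarray:
    """Spike counts per (trial, frame bin); bin b covers [b/f, (b+1)/f).

    Spikes at or beyond the trial duration are rejected with a warning.
    """
    f = spikes.frame_rate_hz
    n_frames = int(round(spikes.trial_duration_s * f))
    out = np.zeros((spikes.n_trials, n_frames), dtype=np.int64)
    n_rejected = 0
    for t, train in enumerate(spikes.trains):
        train = np.asarray(train, dtype=float)
        ok = (train >= 0) & (train < spikes.trial_duration_s)
        n_rejected += int((~ok).sum())
        b = np.minimum((train[ok] * f).astype(np.int64), n_frames - 1)
        np.add.at(out[t], b, 1)
    if n_rejected:
        warnings.warn(f"bin_spikes: rejected {n_rejected} spikes outside [0, trial duration)")
    return out


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    half = max(1, int(np.ceil(4.0 * sigma_bins)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def _smooth_renormalized(signal: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing, kernel truncated at 4 sigma and renormalised at
    the edges so that flat signals stay exactly flat."""
    k = _gaussian_kernel(sigma_bins)
    num = np.convolve(signal, k, mode="same")
    den = np.convolve(np.ones_like(signal), k, mode="same")
    return num / den


def selective_response(
    binned: np.ndarray, frame_rate_hz: float, smooth_ms: float = 10.0
) -> np.ndarray:
    """Remove trial-locked and slow non-selective response components.

    Step 1 subtracts the smoothed cross-trial mean per bin from every trial;
    step 2 subtracts the remaining per-trial mean.  The output has exactly
    zero mean in every trial.
    """
    binned = np.asarray(binned, dtype=float)
    if binned.ndim != 2:
        raise ValueError("binned must be (n_trials, n_frames)")
    if binned.shape[0] < 2:
        warnings.warn(
            "selective_response: a single trial yields a degenerate (near-zero) "
            "output; at least 2 trials are recommended"
        )
    sigma_bins = smooth_ms / 1000.0 * frame_rate_hz
    trial_locked = _smooth_renormalized(binned.mean(axis=0), sigma_bins)
    resid = binned - trial_locked[None, :]
    resid -= resid.mean(axis=1, keepdims=True)
    return resid
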
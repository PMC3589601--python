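"""Dot-trajectory generators for the three mapping paradigms.

* ``generate_bmdots`` — the full-field reverse-correlation stimulus: many
  independently moving dots, each holding a uniformly drawn direction for one
  200 ms epoch before a new direction is assigned.  Per-dot epoch phases are
  staggered so that only a fraction of the dots changes direction on any one
  frame.  Dots wrap toroidally at the field edges, keeping density constant.
* ``generate_gridrf`` — a single dot probing one patch of an 11 x 11 grid per
  epoch, moving in a fixed direction and wrapping at the patch edges.
* ``generate_prefdir`` — a single dot probing up to five pre-selected patches,
  with an independently sampled direction (one of 64) per epoch.

All generators are bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StimulusConfig

__all__ = [
    "DotTrajectories",
    "PatchSchedule",
    "generate_bmdots",
    "generate_gridrf",
    "generate_prefdir",
]


@dataclass
class DotTrajectories:
    """Per-frame dot positions and motion directions for one session.

    Arrays are shaped ``(n_trials, n_frames, n_dots)``; positions are degrees
    relative to fixation, directions degrees in [0, 360).  The *direction*
    stored for frame f is the direction of the displacement applied between
    frames f and f+1.
    """

    x: np.ndarray
    y: np.ndarray
    direction: np.ndarray
    frame_rate_hz: float
    config: StimulusConfig | None = None

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    @property
    def n_dots(self) -> int:
        return self.x.shape[2]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per live dot per frame."""
        t, f, d = np.meshgrid(
            np.arange(self.n_trials),
            np.arange(self.n_frames),
            np.arange(self.n_dots),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "trial": t.ravel(),
                "frame": f.ravel(),
                "dot_id": d.ravel(),
                "x_deg": self.x.ravel(),
                "y_deg": self.y.ravel(),
                "direction_deg": self.direction.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate_hz: float) -> "DotTrajectories":
        n_trials = int(df["trial"].max()) + 1
        n_frames = int(df["frame"].max()) + 1
        n_dots = int(df["dot_id"].max()) + 1
        shape = (n_trials, n_frames, n_dots)
        x = np.full(shape, np.nan)
        y = np.full(shape, np.nan)
        direction = np.full(shape, np.nan)
        idx = (df["trial"].to_numpy(), df["frame"].to_numpy(), df["dot_id"].to_numpy())
        x[idx] = df["x_deg"].to_numpy()
        y[idx] = df["y_deg"].to_numpy()
        direction[idx] = df["direction_deg"].to_numpy()
        return cls(x=x, y=y, direction=direction, frame_rate_hz=frame_rate_hz)

    @classmethod
    def from_csv(cls, path, frame_rate_hz: float) -> "DotTrajectories":
        return cls.from_dataframe(pd.read_csv(path), frame_rate_hz)


@dataclass
class PatchSchedule:
    """Epoch schedule of the single-dot paradigms.

    One entry per direction epoch: trial, first frame, scheduled patch center
    (deg), motion direction, epoch length in frames and a completeness flag
    (epochs truncated by the trial end are generated but flagged, and excluded
    from epoch-based analyses).
    """

    trial: np.ndarray
    frame_start: np.ndarray
    patch_x_deg: np.ndarray
    patch_y_deg: np.ndarray
    direction_deg: np.ndarray
    n_frames: np.ndarray
    complete: np.ndarray
    frame_rate_hz: float = 75.0

    def __len__(self) -> int:
        return len(self.trial)

    @property
    def onset_s(self) -> np.ndarray:
        return self.frame_start / self.frame_rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "frame_start": self.frame_start,
                "patch_x": self.patch_x_deg,
                "patch_y": self.patch_y_deg,
                "direction_deg": self.direction_deg,
                "n_frames": self.n_frames,
                "complete": self.complete.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate_hz: float) -> "PatchSchedule":
        return cls(
            trial=df["trial"].to_numpy(int),
            frame_start=df["frame_start"].to_numpy(int),
            patch_x_deg=df["patch_x"].to_numpy(float),
            patch_y_deg=df["patch_y"].to_numpy(float),
            direction_deg=df["direction_deg"].to_numpy(float),
            n_frames=df["n_frames"].to_numpy(int),
            complete=df["complete"].to_numpy(bool),
            frame_rate_hz=frame_rate_hz,
        )


def _wrap_interval(v: np.ndarray, lo: float, width: float) -> np.ndarray:
    """Toroidal wrap of v into [lo, lo + width)."""
    return (v - lo) % width + lo


def generate_bmdots(config: StimulusConfig, seed: int) -> DotTrajectories:
    """Generate the full-field Brownian-motion-dots stimulus.

    Each dot starts at a uniform position, holds a uniformly drawn direction
    for one epoch (200 ms by default) and then redraws it.  A per-dot random
    epoch phase, fixed within each trial, interleaves the direction changes
    across dots.  Dots wrap toroidally at the field edges.
    """
    if config.paradigm != "bmdots":
        raise ValueError("config.paradigm must be 'bmdots'")
    rng = np.random.default_rng(seed)
    n_frames, n_dots = config.frames_per_trial, config.n_dots
    epoch = config.frames_per_epoch
    w, h = config.field_width_deg, config.field_height_deg
    step = config.dot_speed_deg_per_s / config.frame_rate_hz

    x = np.empty((config.n_trials, n_frames, n_dots))
    y = np.empty_like(x)
    direction = np.empty_like(x)
    frame_ix = np.arange(n_frames)[:, None]

    for trial in range(config.n_trials):
        phase = rng.integers(0, epoch, n_dots)
        # Epoch index per (frame, dot); phase staggers the change frames.
        ep = (frame_ix + phase[None, :]) // epoch
        n_ep = int(ep.max()) + 1
        dirs = rng.uniform(0.0, 360.0, (n_ep, n_dots))
        direction[trial] = np.take_along_axis(dirs, ep, axis=0)

        theta = np.deg2rad(direction[trial])
        dx = step * np.cos(theta)
        dy = step * np.sin(theta)
        x0 = rng.uniform(-w / 2, w / 2, n_dots)
        y0 = rng.uniform(-h / 2, h / 2, n_dots)
        x[trial, 0] = x0
        y[trial, 0] = y0
        x[trial, 1:] = x0[None, :] + np.cumsum(dx[:-1], axis=0)
        y[trial, 1:] = y0[None, :] + np.cumsum(dy[:-1], axis=0)
        x[trial] = _wrap_interval(x[trial], -w / 2, w)
        y[trial] = _wrap_interval(y[trial], -h / 2, h)

    return DotTrajectories(x=x, y=y, direction=direction,
                           frame_rate_hz=config.frame_rate_hz, config=config)


def _epoch_table(config: StimulusConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch (trial, frame_start, n_frames, complete) tiling every trial."""
    epoch, n_frames = config.frames_per_epoch, config.frames_per_trial
    starts_one = np.arange(0, n_frames, epoch)
    lens_one = np.minimum(epoch, n_frames - starts_one)
    trial = np.repeat(np.arange(config.n_trials), len(starts_one))
    starts = np.tile(starts_one, config.n_trials)
    lens = np.tile(lens_one, config.n_trials)
    return trial, starts, lens, lens == epoch


def _single_dot_walk(
    rng: np.random.Generator,
    config: StimulusConfig,
    px: np.ndarray,
    py: np.ndarray,
    direction: np.ndarray,
    starts: np.ndarray,
    lens: np.ndarray,
    trial: np.ndarray,
) -> DotTrajectories:
    """Trajectory of the single probe dot for an epoch schedule.

    The dot appears at a uniform position inside the scheduled patch and wraps
    at the patch edges (patch side = one analysis-grid patch, 1 deg).
    """
    size = 1.0  # probe patch side, degrees
    step = config.dot_speed_deg_per_s / config.frame_rate_hz
    n_frames = config.frames_per_trial
    x = np.empty((config.n_trials, n_frames, 1))
    y = np.empty_like(x)
    d = np.empty_like(x)
    for e in range(len(starts)):
        t0, f0, ln = trial[e], starts[e], lens[e]
        theta = np.deg2rad(direction[e])
        rel = np.arange(ln)
        sx = px[e] - size / 2 + rng.uniform(0, size)
        sy = py[e] - size / 2 + rng.uniform(0, size)
        xs = sx + rel * step * np.cos(theta)
        ys = sy + rel * step * np.sin(theta)
        x[t0, f0 : f0 + ln, 0] = _wrap_interval(xs, px[e] - size / 2, size)
        y[t0, f0 : f0 + ln, 0] = _wrap_interval(ys, py[e] - size / 2, size)
        d[t0, f0 : f0 + ln, 0] = direction[e]
    return DotTrajectories(x=x, y=y, direction=d,
                           frame_rate_hz=config.frame_rate_hz, config=config)


def _probe_grid_centers(config: StimulusConfig, rf_center: tuple[float, float]) -> np.ndarray:
    """Patch centers of the n x n probe grid centered on the classical RF."""
    n = int(round(config.gridrf_extent_deg))  # 1-deg patches
    offs = np.arange(n) - (n - 1) / 2.0
    cx, cy = np.meshgrid(rf_center[0] + offs, rf_center[1] + offs, indexing="xy")
    return np.column_stack([cx.ravel(), cy.ravel()])


def generate_gridrf(
    config: StimulusConfig, rf_center: tuple[float, float], seed: int
) -> tuple[DotTrajectories, PatchSchedule]:
    """Single-dot grid mapping: one dot probes one grid patch per epoch.

    Patches are visited in block-randomised order (shuffled full passes over
    the grid) for balanced coverage; within an epoch the dot moves in the
    configured constant direction and wraps at the patch edges.
    """
    if config.paradigm != "gridrf":
        raise ValueError("config.paradigm must be 'gridrf'")
    half = config.gridrf_extent_deg / 2.0
    if (abs(rf_center[0]) + half > config.field_width_deg / 2.0 + 1e-9) or (
        abs(rf_center[1]) + half > config.field_height_deg / 2.0 + 1e-9
    ):
        raise ValueError("probe grid extends beyond the stimulus field")
    rng = np.random.default_rng(seed)
    centers = _probe_grid_centers(config, rf_center)
    trial, starts, lens, complete = _epoch_table(config)
    n_epochs = len(starts)
    # Balanced coverage: concatenate shuffled passes over all patches.
    n_pass = -(-n_epochs // len(centers))
    order = np.concatenate([rng.permutation(len(centers)) for _ in range(n_pass)])[:n_epochs]
    px, py = centers[order, 0], centers[order, 1]
    direction = np.full(n_epochs, config.gridrf_direction_deg % 360.0)
    traj = _single_dot_walk(rng, config, px, py, direction, starts, lens, trial)
    sched = PatchSchedule(trial=trial, frame_start=starts, patch_x_deg=px,
                          patch_y_deg=py, direction_deg=direction, n_frames=lens,
                          complete=complete, frame_rate_hz=config.frame_rate_hz)
    return traj, sched


def generate_prefdir(
    config: StimulusConfig, patches, seed: int
) -> tuple[DotTrajectories, PatchSchedule]:
    """Single-dot direction mapping in up to five pre-selected patches.

    Each epoch independently samples a (patch, direction) pair: the patch
    uniformly from the given list, the direction uniformly from the
    ``prefdir_n_directions`` equally spaced directions.
    """
    if config.paradigm != "prefdir":
        raise ValueError("config.paradigm must be 'prefdir'")
    patches = np.atleast_2d(np.asarray(patches, dtype=float))
    if not (1 <= len(patches) <= 5):
        raise ValueError("between 1 and 5 probe patches are required")
    rng = np.random.default_rng(seed)
    trial, starts, lens, complete = _epoch_table(config)
    n_epochs = len(starts)
    which = rng.integers(0, len(patches), n_epochs)
    k = rng.integers(0, config.prefdir_n_directions, n_epochs)
    direction = k * (360.0 / config.prefdir_n_directions)
    px, py = patches[which, 0], patches[which, 1]
    traj = _single_dot_walk(rng, config, px, py, direction, starts, lens, trial)
    sched = PatchSchedule(trial=trial, frame_start=starts, patch_x_deg=px,
                          patch_y_deg=py, direction_deg=direction, n_frames=lens,
                          complete=complete, frame_rate_hz=config.frame_rate_hz)
    return traj, sched
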
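"""Sparse space-direction histogram (SDH) of a dot stimulus.

For every display frame, the dots inside the analysis grid are counted
jointly by 1-degree spatial patch and 64-bin motion direction.  The result is
the reverse-correlation regressor: a (time x patch x direction-bin) histogram
stored sparsely (at most ``n_dots`` nonzeros per frame, versus ~70k cells
dense at the default grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GridSpec
from .stimulus import DotTrajectories

__all__ = ["SparseSDH", "build_sdh", "densify", "sdh_from_dense"]

log = logging.getLogger(__name__)

# Guard for densify(): refuse blocks beyond this many cells.
_MAX_DENSE_CELLS = 200_000_000


@dataclass
class SparseSDH:
    """Nonzero cells of the space-direction histogram.

    Parallel arrays sorted by (trial, frame): ``count[i]`` dots were inside
    patch ``patch[i]`` (flat row-major index) moving in direction bin
    ``dir_bin[i]`` on frame ``frame[i]`` of trial ``trial[i]``.
    """

    trial: np.ndarray
    frame: np.ndarray
    patch: np.ndarray
    dir_bin: np.ndarray
    count: np.ndarray
    grid: GridSpec
    n_trials: int
    n_frames: int  # frames per trial
    frame_rate_hz: float

    @property
    def nnz(self) -> int:
        return len(self.count)

    @property
    def t_flat(self) -> np.ndarray:
        """Session-concatenated time index: trial * n_frames + frame."""
        return self.trial.astype(np.int64) * self.n_frames + self.frame

    @property
    def total_frames(self) -> int:
        return self.n_trials * self.n_frames

    def to_dataframe(self) -> pd.DataFrame:
        ix, iy = self.grid.unflatten(self.patch)
        return pd.DataFrame(
            {
                "trial": self.trial,
                "frame": self.frame,
                "patch_ix": ix,
                "patch_iy": iy,
                "dir_bin": self.dir_bin,
                "count": self.count,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, grid: GridSpec, n_trials: int, n_frames: int,
        frame_rate_hz: float,
    ) -> "SparseSDH":
        patch = grid.flat_index(df["patch_ix"].to_numpy(), df["patch_iy"].to_numpy())
        return cls(
            trial=df["trial"].to_numpy(np.int32),
            frame=df["frame"].to_numpy(np.int32),
            patch=patch.astype(np.int32),
            dir_bin=df["dir_bin"].to_numpy(np.int16),
            count=df["count"].to_numpy(np.int32),
            grid=grid, n_trials=n_trials, n_frames=n_frames,
            frame_rate_hz=frame_rate_hz,
        )


def build_sdh(traj: DotTrajectories, grid: GridSpec) -> SparseSDH:
    """Bin dot trajectories into the sparse space-direction histogram.

    Patch membership uses half-open intervals, direction bin k covers
    [k*360/n_bins, (k+1)*360/n_bins).  Dots outside the grid extent are
    dropped (counted in a log line).
    """
    n_trials, n_frames, _ = traj.x.shape
    ix, iy, inside = grid.locate(traj.x.ravel(), traj.y.ravel())
    db = grid.direction_bin(traj.direction.ravel())
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("build_sdh: dropped %d dot-frames outside the grid extent", n_dropped)

    tf = np.repeat(np.arange(n_trials * n_frames, dtype=np.int64), traj.n_dots)
    patch = (iy * grid.nx + ix)[inside]
    tf = tf[inside]
    db = db[inside]

    key = (tf * grid.n_patches + patch) * grid.n_dir_bins + db
    uniq, counts = np.unique(key, return_counts=True)
    db_u = uniq % grid.n_dir_bins
    rest = uniq // grid.n_dir_bins
    patch_u = rest % grid.n_patches
    tf_u = rest // grid.n_patches
    return SparseSDH(
        trial=(tf_u // n_frames).astype(np.int32),
        frame=(tf_u % n_frames).astype(np.int32),
        patch=patch_u.astype(np.int32),
        dir_bin=db_u.astype(np.int16),
        count=counts.astype(np.int32),
        grid=grid,
        n_trials=n_trials,
        n_frames=n_frames,
        frame_rate_hz=traj.frame_rate_hz,
    )


def densify(sdh: SparseSDH, frames: range | None = None) -> np.ndarray:
    """Dense (n_block_frames, n_patches, n_dir_bins) histogram block.

    ``frames`` indexes session-concatenated time (trial-major); the default
    is the whole session.  Inverse of sparsification.
    """
    if frames is None:
        frames = range(sdh.total_frames)
    n = len(frames)
    cells = n * sdh.grid.n_patches * sdh.grid.n_dir_bins
    if cells > _MAX_DENSE_CELLS:
        raise MemoryError(
            f"dense block of {cells:,} cells exceeds the {_MAX_DENSE_CELLS:,}-cell guard"
        )
    out = np.zeros((n, sdh.grid.n_patches, sdh.grid.n_dir_bins), dtype=np.int64)
    t = sdh.t_flat
    sel = (t >= frames.start) & (t < frames.stop)
    if frames.step not in (None, 1):
        raise ValueError("only unit-stride frame ranges are supported")
    out[t[sel] - frames.start, sdh.patch[sel], sdh.dir_bin[sel]] = sdh.count[sel]
    return out


def sdh_from_dense(
    dense: np.ndarray, grid: GridSpec, n_trials: int, n_frames: int,
    frame_rate_hz: float = 75.0,
) -> SparseSDH:
    """Sparsify a dense (total_frames, n_patches, n_dir_bins) histogram."""
    if dense.shape != (n_trials * n_frames, grid.n_patches, grid.n_dir_bins):
        raise ValueError("dense block shape does not match grid/session structure")
    tf, patch, db = np.nonzero(dense)
    return SparseSDH(
        trial=(tf // n_frames).astype(np.int32),
        frame=(tf % n_frames).astype(np.int32),
        patch=patch.astype(np.int32),
        dir_bin=db.astype(np.int16),
        count=dense[tf, patch, db].astype(np.int32),
        grid=grid, n_trials=n_trials, n_frames=n_frames,
        frame_rate_hz=frame_rate_hz,
    )
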
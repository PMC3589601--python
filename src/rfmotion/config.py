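"""Stimulus and analysis configuration.

Two small frozen dataclasses carry every geometric convention used across the
package:

``StimulusConfig``
    The display and dot-kinematics parameters of the three mapping paradigms
    (full-field Brownian-motion dots, single-dot grid mapping, single-dot
    direction mapping).

``GridSpec``
    The analysis grid of 1 deg x 1 deg patches imposed on the screen and the
    64-bin direction discretisation.

Angle convention everywhere: degrees in [0, 360), 0 = rightward motion,
counter-clockwise positive.  Spatial coordinates are degrees of visual angle
relative to the fixation point at (0, 0).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["StimulusConfig", "GridSpec", "load_config"]

PARADIGMS = ("bmdots", "gridrf", "prefdir")


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of a dot-stimulus session.

    Defaults reproduce the standard configuration: a 40 x 30 deg field at
    75 Hz, 300 dots (0.25 dots per square degree) moving at 8 deg/s, with a
    new motion direction assigned to each dot every 200 ms, in trials of 3 s.
    """

    field_width_deg: float = 40.0
    field_height_deg: float = 30.0
    frame_rate_hz: float = 75.0
    n_dots: int = 300
    dot_speed_deg_per_s: float = 8.0
    direction_epoch_ms: float = 200.0
    trial_duration_s: float = 3.0
    n_trials: int = 1
    paradigm: str = "bmdots"
    gridrf_extent_deg: float = 11.0
    gridrf_direction_deg: float = 0.0
    prefdir_patches: tuple = ()
    prefdir_n_directions: int = 64
    # Luminance metadata of the rendered dots.  Recorded for provenance only:
    # every analysis in this package operates on motion vectors, not pixels.
    dot_sigma_deg: float = 0.2
    dot_contrast: float = 0.25

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"paradigm must be one of {PARADIGMS}, got {self.paradigm!r}")
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if len(self.prefdir_patches) > 5:
            raise ValueError("prefdir_patches is limited to 5 patch locations")
        # The direction epoch must be an integer number of display frames.
        frames = self.direction_epoch_ms * self.frame_rate_hz / 1000.0
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError(
                f"direction_epoch_ms={self.direction_epoch_ms} is not an integer "
                f"number of frames at {self.frame_rate_hz} Hz"
            )

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.direction_epoch_ms * self.frame_rate_hz / 1000.0))

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.frame_rate_hz))

    @property
    def frame_dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def dot_density_per_deg2(self) -> float:
        return self.n_dots / (self.field_width_deg * self.field_height_deg)

    def with_(self, **kwargs) -> "StimulusConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GridSpec:
    """The analysis grid: spatial patches x direction bins.

    The default covers a 39 x 29 deg region of the 40 x 30 deg monitor with
    1 deg patches whose boundaries fall on integer degrees, and 64 direction
    bins of 5.625 deg each.  Patch (ix, iy) covers the half-open box
    [origin_x + ix, origin_x + ix + 1) x [origin_y + iy, origin_y + iy + 1).
    Flat patch indices are row-major: ``flat = iy * nx + ix``.
    """

    patch_size_deg: float = 1.0
    origin_x_deg: float = -19.0
    origin_y_deg: float = -14.0
    nx: int = 39
    ny: int = 29
    n_dir_bins: int = 64

    @property
    def n_patches(self) -> int:
        return self.nx * self.ny

    @property
    def dir_bin_width_deg(self) -> float:
        return 360.0 / self.n_dir_bins

    @property
    def dir_bin_centers_deg(self) -> np.ndarray:
        w = self.dir_bin_width_deg
        return (np.arange(self.n_dir_bins) + 0.5) * w

    @property
    def patch_centers_x(self) -> np.ndarray:
        """Patch-center x (deg) indexed by ix."""
        s = self.patch_size_deg
        return self.origin_x_deg + (np.arange(self.nx) + 0.5) * s

    @property
    def patch_centers_y(self) -> np.ndarray:
        s = self.patch_size_deg
        return self.origin_y_deg + (np.arange(self.ny) + 0.5) * s

    def flat_index(self, ix, iy):
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def unflatten(self, flat):
        flat = np.asarray(flat)
        return flat % self.nx, flat // self.nx

    def patch_center(self, flat):
        """Center (x_deg, y_deg) of the patch with the given flat index."""
        ix, iy = self.unflatten(flat)
        s = self.patch_size_deg
        return (self.origin_x_deg + (ix + 0.5) * s, self.origin_y_deg + (iy + 0.5) * s)

    def locate(self, x_deg, y_deg):
        """Map positions to (ix, iy, inside) with half-open patch membership."""
        s = self.patch_size_deg
        ix = np.floor((np.asarray(x_deg) - self.origin_x_deg) / s).astype(np.int64)
        iy = np.floor((np.asarray(y_deg) - self.origin_y_deg) / s).astype(np.int64)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        return ix, iy, inside

    def direction_bin(self, direction_deg):
        """Direction bin k covering [k*w, (k+1)*w), w = 360/n_dir_bins."""
        d = np.mod(np.asarray(direction_deg, dtype=float), 360.0)
        return np.minimum(
            (d / self.dir_bin_width_deg).astype(np.int64), self.n_dir_bins - 1
        )

    def as_map(self, flat_values: np.ndarray) -> np.ndarray:
        """Reshape a flat per-patch array to an (ny, nx) map."""
        flat_values = np.asarray(flat_values)
        return flat_values.reshape(flat_values.shape[:-1] + (self.ny, self.nx))

    @classmethod
    def centered(
        cls,
        width_deg: float,
        height_deg: float,
        patch_size_deg: float = 1.0,
        n_dir_bins: int = 64,
    ) -> "GridSpec":
        """A grid of whole patches centered on fixation (for small fields)."""
        nx = int(round(width_deg / patch_size_deg))
        ny = int(round(height_deg / patch_size_deg))
        return cls(
            patch_size_deg=patch_size_deg,
            origin_x_deg=-nx * patch_size_deg / 2.0,
            origin_y_deg=-ny * patch_size_deg / 2.0,
            nx=nx,
            ny=ny,
            n_dir_bins=n_dir_bins,
        )


def load_config(path) -> tuple[StimulusConfig, GridSpec]:
    """Read a TOML configuration file with [stimulus] and [grid] tables."""
    with open(Path(path), "rb") as fh:
        raw = tomllib.load(fh)
    stim_kw = dict(raw.get("stimulus", {}))
    if "prefdir_patches" in stim_kw:
        stim_kw["prefdir_patches"] = tuple(tuple(p) for p in stim_kw["prefdir_patches"])
    stim = StimulusConfig(**stim_kw)
    grid_kw = raw.get("grid", {})
    grid = GridSpec(**grid_kw) if grid_kw else GridSpec()
    return stim, grid
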
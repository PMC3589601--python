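"""Map rendering: the hue/saturation preferred-direction image.

The standard visual summary of a spatio-directional RF map encodes the
preferred direction of each patch as hue (the full color circle spans 360
degrees of motion direction) and the tuning strength as saturation, so that
strongly tuned patches are vivid and untuned ones fade to gray.
"""

from __future__ import annotations

import numpy as np

from .config import GridSpec

__all__ = ["pd_map_rgb", "save_pd_map"]


def _hsv_to_rgb(h, s, v):
    """Vectorised HSV -> RGB, channels in [0, 1]."""
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def pd_map_rgb(
    pd_angle_deg: np.ndarray,
    pd_length: np.ndarray,
    grid: GridSpec,
    length_scale: float | None = None,
) -> np.ndarray:
    """(ny, nx, 3) float RGB image of a PD map.

    Hue encodes the preferred direction, saturation the tuning strength
    relative to ``length_scale`` (default: the maximum length in the map).
    Rows are ordered top-to-bottom (image convention: row 0 = highest y).
    """
    angle = grid.as_map(np.asarray(pd_angle_deg, dtype=float))
    length = grid.as_map(np.asarray(pd_length, dtype=float))
    scale = float(length.max()) if length_scale is None else float(length_scale)
    sat = np.clip(length / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(length)
    rgb = _hsv_to_rgb((angle % 360.0) / 360.0, sat, np.ones_like(sat))
    return rgb[::-1]   # y increases upward on the screen


def save_pd_map(path, pd_angle_deg, pd_length, grid, upscale: int = 12) -> None:
    """Write the PD map as a PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = pd_map_rgb(pd_angle_deg, pd_length, grid)
    rgb = np.repeat(np.repeat(rgb, upscale, axis=0), upscale, axis=1)
    plt.imsave(path, rgb)
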
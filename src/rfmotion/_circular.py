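"""Small circular-statistics helpers shared across modules (degrees)."""

from __future__ import annotations

import numpy as np


def wrap_deg(a):
    """Wrap angles into [0, 360)."""
    return np.mod(a, 360.0)


def circdiff_deg(a, b):
    """Absolute circular difference in [0, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b), 360.0)
    return np.minimum(d, 360.0 - d)


def circmean_deg(a, weights=None):
    """Weighted circular mean; raises on a zero resultant."""
    a = np.deg2rad(np.asarray(a, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    c = float(np.sum(w * np.cos(a)))
    s = float(np.sum(w * np.sin(a)))
    if np.hypot(c, s) < 1e-12 * max(1.0, float(np.abs(w).sum())):
        raise ValueError("circular mean undefined: zero resultant")
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def circmedian_abs_deg(errors):
    """Median of absolute circular errors (errors already in [0, 180])."""
    return float(np.median(np.asarray(errors, dtype=float)))
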
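"""Receptive-field structure statistics.

Given the per-patch PD map, the RF mask and the raw polar observations, this
module decides whether a cell's RF is inhomogeneous:

* multiple preferred directions — Bonferroni-corrected pairwise bootstrap
  comparisons of direction preference between all RF patches;
* multiple peaks — a monotonicity test: along every line from the most
  responsive patch to any other RF patch, tuning strength should decrease;
  a significant increase with distance (strength bootstrap, Bonferroni)
  rejects the single-hill null;
* descriptive geometry — peak counting on the thresholded significance map,
  the fraction of the RF's convex hull that is unresponsive ("percent
  missing"), the valley-over-peak depth between the two strongest peaks,
  K-means (K=2) sub-region segmentation with strength/size summaries, and an
  elliptical 2D-Gaussian fit of the strength profile.

All spatial operations use 8-connectivity and patch-index coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import shapely
from scipy import ndimage, optimize
from shapely.geometry import MultiPoint
from sklearn.cluster import KMeans

from ._circular import circdiff_deg, circmean_deg
from .config import GridSpec
from .nullstats import (PolarObservations, bootstrap_direction_test,
                        bootstrap_strength_test, cluster_correct)

__all__ = [
    "MultipleDirectionsResult",
    "MonotonicityResult",
    "SubregionSummary",
    "RFGeometry",
    "supercover_line",
    "pairwise_direction_pvalues",
    "detect_multiple_directions",
    "monotonicity_test",
    "count_peaks",
    "percent_missing",
    "valley_over_peak",
    "split_subregions",
    "subregion_summary",
    "fit_rf_geometry",
]

_EIGHT = np.ones((3, 3), dtype=int)


# ---------------------------------------------------------------------------
# Line rasterisation


def supercover_line(a, b):
    """All grid cells touched by the segment between the centers of cells
    ``a`` and ``b`` (supercover traversal: diagonal corner crossings include
    both adjacent cells)."""
    x0, y0 = int(a[0]), int(a[1])
    x1, y1 = int(b[0]), int(b[1])
    dx, dy = x1 - x0, y1 - y0
    nx, ny = abs(dx), abs(dy)
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    px, py = x0, y0
    cells = [(px, py)]
    ix = iy = 0
    while ix < nx or iy < ny:
        d = (1 + 2 * ix) * ny - (1 + 2 * iy) * nx
        if d == 0:
            # exact corner crossing: both side cells are touched
            cells.append((px + sx, py))
            cells.append((px, py + sy))
            px += sx
            py += sy
            ix += 1
            iy += 1
        elif d < 0:
            px += sx
            ix += 1
        else:
            py += sy
            iy += 1
        cells.append((px, py))
    return cells


# ---------------------------------------------------------------------------
# Multiple preferred directions


@dataclass
class MultipleDirectionsResult:
    positive: bool
    n_pairs: int
    alpha_corrected: float
    pvalues: np.ndarray          # (n_pairs,) aligned with ``pairs``
    pairs: np.ndarray            # (n_pairs, 2) flat patch ids
    significant_pairs: np.ndarray


def pairwise_direction_pvalues(
    patch_ids: np.ndarray,
    obs: PolarObservations,
    seed,
    **boot_kw,
) -> np.ndarray:
    """Symmetric matrix of direction-bootstrap p-values (diagonal 1).

    This is the preferred-direction similarity matrix used for sub-region
    segmentation: entry (i, j) is the p-value of the test comparing the
    preferred direction of patch i with patch j.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patch_ids = np.asarray(patch_ids)
    n = len(patch_ids)
    S = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        p = bootstrap_direction_test(
            obs.for_patch(patch_ids[i]), obs.for_patch(patch_ids[j]), rng, **boot_kw
        )
        S[i, j] = S[j, i] = p
    return S


def detect_multiple_directions(
    rf_patch_ids: np.ndarray,
    obs: PolarObservations,
    seed,
    alpha: float = 0.05,
    similarity: np.ndarray | None = None,
    early_stop: bool = False,
    **boot_kw,
) -> MultipleDirectionsResult:
    """Does preferred direction change across the RF?

    All unordered pairs of RF patches are compared with the direction
    bootstrap at Bonferroni-corrected alpha; the cell is positive if at least
    one pair differs significantly.  A precomputed similarity matrix can be
    passed to avoid re-running the bootstraps.  With ``early_stop`` the pairs
    are visited in order of decreasing observed angular difference and
    testing stops at the first significant pair (the decision is unchanged;
    p-values of unvisited pairs are reported as NaN).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rf_patch_ids = np.asarray(rf_patch_ids)
    if len(rf_patch_ids) < 2:
        return MultipleDirectionsResult(False, 0, alpha, np.empty(0),
                                        np.empty((0, 2), int), np.empty((0, 2), int))
    pairs = np.array(list(combinations(range(len(rf_patch_ids)), 2)), dtype=int)
    alpha_c = alpha / len(pairs)
    if similarity is not None:
        pvals = similarity[pairs[:, 0], pairs[:, 1]]
    else:
        boot_kw.setdefault("p_stop", alpha_c)
        # observed angular differences, cheap: order the expensive bootstraps
        # so the most extreme pair is tested first
        res = obs.vectors.sum(axis=1)
        ang = np.rad2deg(np.arctan2(res[:, 1], res[:, 0])) % 360.0
        lookup = {pid: k for k, pid in enumerate(obs.patch_ids)}
        ia = np.array([lookup[p] for p in rf_patch_ids[pairs[:, 0]]])
        ib = np.array([lookup[p] for p in rf_patch_ids[pairs[:, 1]]])
        order = np.argsort(-circdiff_deg(ang[ia], ang[ib]))
        pvals = np.full(len(pairs), np.nan)
        for k in order:
            i, j = pairs[k]
            pvals[k] = bootstrap_direction_test(
                obs.for_patch(rf_patch_ids[i]), obs.for_patch(rf_patch_ids[j]),
                rng, **boot_kw)
            if early_stop and pvals[k] < alpha_c:
                break
    with np.errstate(invalid="ignore"):
        sig = pvals < alpha_c
    id_pairs = rf_patch_ids[pairs]
    return MultipleDirectionsResult(
        positive=bool(sig.any()),
        n_pairs=len(pairs),
        alpha_corrected=alpha_c,
        pvalues=pvals,
        pairs=id_pairs,
        significant_pairs=id_pairs[sig],
    )


# ---------------------------------------------------------------------------
# Multiple peaks (monotonicity)


@dataclass
class MonotonicityResult:
    multi_peaked: bool
    n_pairs: int
    alpha_corrected: float
    pairs: np.ndarray            # (n_pairs, 2) (closer, farther) flat ids
    pvalues: np.ndarray          # p small <=> farther significantly stronger
    peak_patch: int


def monotonicity_test(
    strength: np.ndarray,
    rf_mask: np.ndarray,
    obs: PolarObservations,
    grid: GridSpec,
    seed,
    alpha: float = 0.05,
    early_stop: bool = False,
    **boot_kw,
) -> MonotonicityResult:
    """Test the single-hill null: strength decreases away from the peak.

    Supercover lines run from the most responsive RF patch to every other RF
    patch; for every ordered (closer, farther) pair of RF patches on a line,
    the strength bootstrap asks whether the farther patch is significantly
    STRONGER (Bonferroni over all compared pairs) — a significant increase
    with distance violates monotonic decrease.  ``rf_mask`` should be the
    strictly defined RF (p < 0.005, suppressive patches removed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rf_mask = np.asarray(rf_mask, dtype=bool)
    strength = np.asarray(strength, dtype=float)
    iy, ix = np.nonzero(rf_mask)
    flat = iy * grid.nx + ix
    if len(flat) < 2:
        return MonotonicityResult(False, 0, alpha, np.empty((0, 2), int),
                                  np.empty(0), int(flat[0]) if len(flat) else -1)
    peak = int(flat[np.argmax(strength[flat])])
    pix, piy = peak % grid.nx, peak // grid.nx

    def dist2(f):
        return (f % grid.nx - pix) ** 2 + (f // grid.nx - piy) ** 2

    pair_set = set()
    for f in flat:
        if f == peak:
            continue
        cells = supercover_line((pix, piy), (f % grid.nx, f // grid.nx))
        on_line = []
        for cx, cy in cells:
            if 0 <= cx < grid.nx and 0 <= cy < grid.ny and rf_mask[cy, cx]:
                on_line.append(cy * grid.nx + cx)
        on_line = sorted(set(on_line), key=dist2)
        for i, j in combinations(range(len(on_line)), 2):
            ci, cj = on_line[i], on_line[j]
            if dist2(cj) > dist2(ci):
                pair_set.add((ci, cj))
    pairs = np.array(sorted(pair_set), dtype=int)
    if len(pairs) == 0:
        return MonotonicityResult(False, 0, alpha, pairs, np.empty(0), peak)
    alpha_c = alpha / len(pairs)
    boot_kw.setdefault("p_stop", alpha_c)
    pvals = np.full(len(pairs), np.nan)
    # visit the largest observed strength increases first so early stopping
    # finds a violation (if any) quickly
    order = np.argsort(strength[pairs[:, 0]] - strength[pairs[:, 1]])
    for k in order:
        closer, farther = pairs[k]
        # first argument = farther: small p means farther is stronger
        pvals[k] = bootstrap_strength_test(
            obs.for_patch(farther), obs.for_patch(closer), rng, **boot_kw
        )
        if early_stop and pvals[k] < alpha_c:
            break
    with np.errstate(invalid="ignore"):
        any_violation = bool((pvals < alpha_c).any())
    return MonotonicityResult(
        multi_peaked=any_violation,
        n_pairs=len(pairs),
        alpha_corrected=alpha_c,
        pairs=pairs,
        pvalues=pvals,
        peak_patch=peak,
    )


# ---------------------------------------------------------------------------
# Descriptive map statistics


def count_peaks(
    p_map: np.ndarray, threshold: float = 0.01, min_neighbors: int = 3
) -> int:
    """Number of isolated RF sub-regions: 8-connected components of the
    cluster-corrected {p < threshold} map.  ``p_map`` is the (ny, nx) map."""
    p_map = np.asarray(p_map)
    if p_map.ndim != 2:
        raise ValueError("count_peaks expects the (ny, nx) p-value map")
    mask = cluster_correct(p_map < threshold, min_neighbors)
    _, n = ndimage.label(mask, structure=_EIGHT)
    return int(n)


def _hull_candidates(rf_mask: np.ndarray):
    """Patches whose centers lie in (or on) the convex hull of the RF
    patch centers; returned as a boolean map."""
    iy, ix = np.nonzero(rf_mask)
    pts = np.column_stack([ix, iy]).astype(float)
    hull = MultiPoint(pts).convex_hull.buffer(1e-9)
    ny, nx = rf_mask.shape
    x0, x1 = int(ix.min()), int(ix.max())
    y0, y1 = int(iy.min()), int(iy.max())
    gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    cand_pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]).astype(float))
    inside = shapely.covers(hull, cand_pts)
    out = np.zeros_like(rf_mask, dtype=bool)
    out[gy.ravel()[inside], gx.ravel()[inside]] = True
    return out


def percent_missing(rf_mask: np.ndarray) -> float:
    """Percentage of patches inside the RF's convex hull (boundary
    inclusive, by patch center) that are not part of the RF."""
    rf_mask = np.asarray(rf_mask, dtype=bool)
    if not rf_mask.any():
        raise ValueError("percent_missing requires a non-empty RF")
    cand = _hull_candidates(rf_mask)
    n_cand = int(cand.sum())
    n_missing = int((cand & ~rf_mask).sum())
    return 100.0 * n_missing / n_cand


def valley_over_peak(strength: np.ndarray, rf_mask: np.ndarray, grid: GridSpec):
    """Depth of the valley between the two strongest RF peaks.

    A response threshold descends through the sorted distinct strength
    values inside the RF's convex hull until a second isolated component
    appears; the secondary peak is that component's maximum.  The valley is
    the minimum strength on the supercover line between the two peak
    patches, and the ratio valley/secondary quantifies the drop.  Returns
    None for single-hill RFs (no second component at any threshold).
    """
    rf_mask = np.asarray(rf_mask, dtype=bool)
    strength = np.asarray(strength, dtype=float)
    if not rf_mask.any():
        raise ValueError("valley_over_peak requires a non-empty RF")
    smap = grid.as_map(strength)
    domain = _hull_candidates(rf_mask)
    primary_flat = int(np.argmax(np.where(rf_mask.ravel(), strength, -np.inf)))
    ppos = (primary_flat % grid.nx, primary_flat // grid.nx)
    values = np.unique(smap[domain])[::-1]
    for thr in values:
        mask = domain & (smap >= thr)
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n < 2:
            continue
        primary_lab = labels[ppos[1], ppos[0]]
        other = mask & (labels != primary_lab)
        sec_flat = int(np.argmax(np.where(other.ravel(), smap.ravel(), -np.inf)))
        spos = (sec_flat % grid.nx, sec_flat // grid.nx)
        line = supercover_line(ppos, spos)
        vals = [smap[cy, cx] for cx, cy in line
                if 0 <= cx < grid.nx and 0 <= cy < grid.ny]
        valley = float(min(vals))
        sec = float(smap[spos[1], spos[0]])
        return valley / sec if sec > 0 else 0.0
    return None


# ---------------------------------------------------------------------------
# Sub-region segmentation and summaries


@dataclass
class SubregionSummary:
    labels: np.ndarray            # per RF patch, 0 = primary, 1 = secondary
    r_primary: float
    r_secondary: float
    n_primary: int
    n_secondary: int
    directional_range_deg: float
    relative_strength_pct: float
    relative_size_pct: float
    size_normalized_strength_pct: float


@dataclass
class RFGeometry:
    center_x_deg: float
    center_y_deg: float
    sigma_long_deg: float
    sigma_short_deg: float
    orientation_deg: float        # long axis, mod 180
    size_deg: float               # sigma_long + sigma_short
    elongation: float             # sigma_long / sigma_short
    pd_axis_angle_deg: float      # folded PD-vs-long-axis angle in [0, 90]
    converged: bool


def split_subregions(similarity: np.ndarray, seed: int) -> np.ndarray:
    """K-means (K=2) segmentation of the RF from the preferred-direction
    similarity matrix: rows of S are the feature vectors; patches whose
    direction p-value profiles agree end up in the same cluster."""
    S = np.asarray(similarity, dtype=float)
    if S.shape[0] < 2:
        raise ValueError("at least 2 patches are required to split sub-regions")
    if np.allclose(S, S[0][None, :]):
        warnings.warn("split_subregions: degenerate similarity matrix, arbitrary split")
    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    return km.fit_predict(S)


def subregion_summary(
    labels: np.ndarray, pd_angle_deg: np.ndarray, pd_length: np.ndarray
) -> SubregionSummary:
    """Tuning strength and size of the two RF sub-regions.

    Each region's strength R is the length of the vector sum of its patch PD
    vectors; the primary region is the one with the larger R.  Reported
    ratios follow the convention secondary/primary x 100%.
    """
    labels = np.asarray(labels)
    out = {}
    for lab in (0, 1):
        sel = labels == lab
        if not sel.any():
            raise ValueError("both sub-regions must be non-empty")
        th = np.deg2rad(pd_angle_deg[sel])
        vx = float(np.sum(pd_length[sel] * np.cos(th)))
        vy = float(np.sum(pd_length[sel] * np.sin(th)))
        out[lab] = (np.hypot(vx, vy), int(sel.sum()),
                    np.rad2deg(np.arctan2(vy, vx)) % 360.0)
    prim = 0 if out[0][0] >= out[1][0] else 1
    sec = 1 - prim
    rp, n_p, ang_p = out[prim]
    rs, n_s, ang_s = out[sec]
    # relabel so 0 = primary
    labels01 = np.where(labels == prim, 0, 1)
    return SubregionSummary(
        labels=labels01,
        r_primary=rp,
        r_secondary=rs,
        n_primary=n_p,
        n_secondary=n_s,
        directional_range_deg=float(circdiff_deg(ang_p, ang_s)),
        relative_strength_pct=100.0 * rs / rp if rp > 0 else np.nan,
        relative_size_pct=100.0 * n_s / n_p,
        size_normalized_strength_pct=(
            100.0 * (rs / n_s) / (rp / n_p) if rp > 0 else np.nan
        ),
    )


def _gauss2d(params, x, y):
    amp, x0, y0, s1, s2, th = params
    ct, st = np.cos(th), np.sin(th)
    u = (x - x0) * ct + (y - y0) * st
    v = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))


def fit_rf_geometry(
    strength: np.ndarray,
    pd_angle_deg: np.ndarray,
    pd_length: np.ndarray,
    rf_mask: np.ndarray,
    grid: GridSpec,
    margin: int = 2,
):
    """Elliptical 2D-Gaussian fit of the tuning-strength profile.

    Fits amplitude, center, the two axis sigmas and the orientation by least
    squares over the RF bounding box (plus a margin).  Reports RF size as
    the sum of the sigmas, elongation as their ratio, and the folded angle
    between the RF-mean preferred direction and the long axis.  Returns None
    if fewer than 6 RF patches are available or the fit fails.
    """
    rf_mask = np.asarray(rf_mask, dtype=bool)
    if rf_mask.sum() < 6:
        return None
    smap = grid.as_map(np.asarray(strength, dtype=float))
    iy, ix = np.nonzero(rf_mask)
    y0b, y1b = max(0, iy.min() - margin), min(grid.ny, iy.max() + margin + 1)
    x0b, x1b = max(0, ix.min() - margin), min(grid.nx, ix.max() + margin + 1)
    sub = smap[y0b:y1b, x0b:x1b]
    gy, gx = np.mgrid[y0b:y1b, x0b:x1b]
    xs = grid.origin_x_deg + (gx.ravel() + 0.5) * grid.patch_size_deg
    ys = grid.origin_y_deg + (gy.ravel() + 0.5) * grid.patch_size_deg
    z = sub.ravel()

    w = np.clip(z, 0, None)
    if w.sum() <= 0:
        return None
    mx = float(np.sum(w * xs) / w.sum())
    my = float(np.sum(w * ys) / w.sum())
    cxx = float(np.sum(w * (xs - mx) ** 2) / w.sum())
    cyy = float(np.sum(w * (ys - my) ** 2) / w.sum())
    cxy = float(np.sum(w * (xs - mx) * (ys - my)) / w.sum())
    evals, evecs = np.linalg.eigh(np.array([[cxx, cxy], [cxy, cyy]]))
    s_init = np.sqrt(np.clip(evals, 1e-4, None))
    th_init = float(np.arctan2(evecs[1, 1], evecs[0, 1]))  # major axis
    p0 = [float(z.max()), mx, my, float(s_init[1]), float(s_init[0]), th_init]

    try:
        res = optimize.least_squares(
            lambda p: _gauss2d(p, xs, ys) - z,
            p0,
            bounds=([0, xs.min(), ys.min(), 0.05, 0.05, -np.pi],
                    [np.inf, xs.max(), ys.max(), 50, 50, np.pi]),
            max_nfev=2000,
        )
    except Exception:
        return None
    if not res.success:
        return None
    amp, x0, y0, s1, s2, th = res.x
    if s1 >= s2:
        s_long, s_short, axis = s1, s2, np.rad2deg(th) % 180.0
    else:
        s_long, s_short, axis = s2, s1, (np.rad2deg(th) + 90.0) % 180.0
    try:
        pd_mean = circmean_deg(pd_angle_deg[rf_mask.ravel()],
                               pd_length[rf_mask.ravel()])
    except ValueError:
        pd_mean = np.nan
    if np.isnan(pd_mean):
        folded = np.nan
    else:
        folded = abs(((pd_mean - axis + 90.0) % 180.0) - 90.0)
    return RFGeometry(
        center_x_deg=float(x0),
        center_y_deg=float(y0),
        sigma_long_deg=float(s_long),
        sigma_short_deg=float(s_short),
        orientation_deg=float(axis),
        size_deg=float(s_long + s_short),
        elongation=float(s_long / s_short),
        pd_axis_angle_deg=float(folded),
        converged=True,
    )
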
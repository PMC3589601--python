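"""End-to-end per-cell analysis: the full reverse-correlation flow.

``analyze_cell`` chains the stages on a stimulus histogram plus a spike
train: selective response -> latency-selected STA and PD map -> time-reversed
null and chi-square patch significance -> cluster-corrected RF (suppressive
patches removed) -> inhomogeneity tests (multiple directions, monotonicity)
-> descriptive structure (peak count, percent missing, valley-over-peak,
sub-regions, 2D-Gaussian geometry) -> split-half reliability.

``simulate_session`` builds a complete synthetic recording (stimulus +
model neuron) from a preset; together they power the parameter-recovery and
calibration studies.  Every stochastic stage consumes an independent child
of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GridSpec, StimulusConfig
from .encode import SparseSDH, build_sdh
from .nullstats import (NullModel, cluster_correct,
                        fit_null, null_sta, patch_significance,
                        polar_block_observations)
from .preprocess import SpikeData, bin_spikes, selective_response
from .rfstruct import (MonotonicityResult, MultipleDirectionsResult,
                       RFGeometry, SubregionSummary, count_peaks,
                       detect_multiple_directions, fit_rf_geometry,
                       monotonicity_test, pairwise_direction_pvalues,
                       percent_missing, split_subregions, subregion_summary,
                       valley_over_peak)
from .sta import STAResult, label_polarity, select_latency, split_half_similarity
from .stimulus import generate_bmdots
from .synthetic import GroundTruthRF, make_ground_truth, simulate_responses

__all__ = ["CellReport", "analyze_cell", "simulate_session", "report_to_dict"]


@dataclass
class CellReport:
    """Everything the per-cell analysis produces."""

    sta: STAResult
    null_model: NullModel
    null_mean: np.ndarray            # per-(patch, bin) null STA
    p_map: np.ndarray                # (n_patches,)
    rf_mask: np.ndarray              # (ny, nx) cluster-corrected, excitatory
    rf_mask_strict: np.ndarray       # same at the strict threshold
    suppressive: np.ndarray          # (n_patches,) bool
    multiple_directions: MultipleDirectionsResult | None
    monotonicity: MonotonicityResult | None
    n_peaks: int
    percent_missing: float | None
    valley_over_peak: float | None
    subregions: SubregionSummary | None
    geometry: RFGeometry | None
    split_half: float | None
    n_spikes: int
    mean_rate_hz: float


def analyze_cell(
    sdh: SparseSDH,
    spikes: SpikeData,
    epoch_frames: int,
    seed: int,
    alpha_rf: float = 0.01,
    alpha_rf_strict: float = 0.005,
    alpha_pairs: float = 0.05,
    alpha_mono: float = 0.05,
    min_neighbors: int = 3,
    max_latency_ms: float = 100.0,
    boot_kw: dict | None = None,
    run_pair_tests: bool = True,
    do_subregions: bool = True,
    fit_geometry: bool = True,
) -> CellReport:
    """Run the complete reverse-correlation analysis for one cell.

    ``boot_kw`` tunes the resampling budget of the pairwise bootstraps; the
    defaults (first chunk 1000, cap 20000, stop at 30 exceedances) resolve
    p-values comfortably below the Bonferroni thresholds at the pair counts
    this pipeline produces while keeping multi-seed calibration studies
    affordable.  Raise ``n_boot_max`` for very large RFs.
    """
    boot_kw = {"n_boot": 500, "n_boot_max": 20_000, "min_exceedances": 30,
               **(boot_kw or {})}
    ss = np.random.SeedSequence(seed)
    seed_pairs, seed_mono, seed_km, seed_split = ss.spawn(4)
    grid = sdh.grid

    binned = bin_spikes(spikes)
    resp = selective_response(binned, sdh.frame_rate_hz)
    sta = select_latency(resp, sdh, max_latency_ms=max_latency_ms)

    nsta, _, null_len = null_sta(resp, sdh, sta.latency_frames)
    null_model = fit_null(null_len)
    p_map, sig = patch_significance(sta.pd_length, null_model, alpha_rf)
    polarity = label_polarity(sta.sta, nsta.mean())
    excitatory_ok = ~polarity.patch_suppressive

    def make_rf(alpha):
        mask = (p_map < alpha) & excitatory_ok
        return cluster_correct(grid.as_map(mask), min_neighbors)

    rf_mask = make_rf(alpha_rf)
    rf_strict = make_rf(alpha_rf_strict)

    multi_dir = None
    mono = None
    subregions = None
    obs = None
    if run_pair_tests:
        rf_ids = np.flatnonzero(rf_mask.ravel())
        strict_ids = np.flatnonzero(rf_strict.ravel())
        all_ids = np.union1d(rf_ids, strict_ids)
        if len(all_ids):
            obs = polar_block_observations(resp, sdh, sta.latency_frames,
                                           all_ids, epoch_frames)
        multi_dir = detect_multiple_directions(
            rf_ids, obs, seed_pairs, alpha=alpha_pairs, early_stop=True,
            **boot_kw)
        if multi_dir.positive and do_subregions:
            # The sub-region segmentation needs the full similarity matrix.
            # K-means only needs the contrast between similar and different
            # pairs, not deep tail precision, so the replicate cap is lowered.
            S = pairwise_direction_pvalues(
                rf_ids, obs, seed_pairs,
                **{**boot_kw, "n_boot_max": min(4000, boot_kw["n_boot_max"]),
                   "p_stop": multi_dir.alpha_corrected})
            labels = split_subregions(S, seed=int(seed_km.generate_state(1)[0] % (2**31)))
            subregions = subregion_summary(
                labels, sta.pd_angle_deg[rf_ids], sta.pd_length[rf_ids])
        if len(strict_ids) >= 1:
            mono = monotonicity_test(sta.pd_length, rf_strict, obs, grid,
                                     seed_mono, alpha=alpha_mono,
                                     early_stop=True, **boot_kw)

    n_peaks = count_peaks(grid.as_map(np.where(excitatory_ok, p_map, 1.0)),
                          threshold=alpha_rf, min_neighbors=min_neighbors)
    pmiss = percent_missing(rf_mask) if rf_mask.any() else None
    vop = valley_over_peak(sta.pd_length, rf_mask, grid) if rf_mask.any() else None
    geometry = None
    if fit_geometry and rf_mask.any():
        geometry = fit_rf_geometry(sta.pd_length, sta.pd_angle_deg,
                                   sta.pd_length, rf_mask, grid)
    split = None
    if sdh.n_trials >= 2:
        split = split_half_similarity(resp, sdh, sta.latency_frames,
                                      int(seed_split.generate_state(1)[0] % (2**31)))
    return CellReport(
        sta=sta, null_model=null_model, null_mean=nsta, p_map=p_map,
        rf_mask=rf_mask, rf_mask_strict=rf_strict,
        suppressive=polarity.patch_suppressive,
        multiple_directions=multi_dir, monotonicity=mono,
        n_peaks=n_peaks, percent_missing=pmiss, valley_over_peak=vop,
        subregions=subregions, geometry=geometry, split_half=split,
        n_spikes=spikes.n_spikes, mean_rate_hz=spikes.mean_rate_hz(),
    )


def simulate_session(
    preset: str,
    config: StimulusConfig,
    grid: GridSpec,
    seed: int,
    **preset_kw,
) -> tuple[SparseSDH, SpikeData, GroundTruthRF]:
    """Full-field stimulus + model neuron: a complete synthetic recording."""
    ss = np.random.SeedSequence(seed)
    s_stim, s_gt, s_spk = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    traj = generate_bmdots(config, s_stim)
    sdh = build_sdh(traj, grid)
    gt = make_ground_truth(preset, grid, s_gt, **preset_kw)
    spikes = simulate_responses(gt, sdh, s_spk)
    return sdh, spikes, gt


def report_to_dict(report: CellReport) -> dict:
    """JSON-serialisable summary of a CellReport."""
    d = {
        "latency_ms": report.sta.latency_ms,
        "latency_frames": report.sta.latency_frames,
        "n_spikes": report.n_spikes,
        "mean_rate_hz": report.mean_rate_hz,
        "null_sigma2": report.null_model.sigma2,
        "n_rf_patches": int(report.rf_mask.sum()),
        "n_rf_patches_strict": int(report.rf_mask_strict.sum()),
        "n_suppressive_patches": int(report.suppressive.sum()),
        "n_peaks": report.n_peaks,
        "percent_missing": report.percent_missing,
        "valley_over_peak": report.valley_over_peak,
        "split_half_similarity": report.split_half,
        "multiple_directions": (
            None if report.multiple_directions is None
            else report.multiple_directions.positive
        ),
        "multi_peaked": (
            None if report.monotonicity is None else report.monotonicity.multi_peaked
        ),
    }
    if report.subregions is not None:
        s = report.subregions
        d["subregions"] = {
            "relative_strength_pct": s.relative_strength_pct,
            "relative_size_pct": s.relative_size_pct,
            "size_normalized_strength_pct": s.size_normalized_strength_pct,
            "directional_range_deg": s.directional_range_deg,
        }
    if report.geometry is not None:
        g = report.geometry
        d["geometry"] = {
            "size_deg": g.size_deg,
            "elongation": g.elongation,
            "orientation_deg": g.orientation_deg,
            "pd_axis_angle_deg": g.pd_axis_angle_deg,
        }
    return d
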
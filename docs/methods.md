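# Methods

This note documents the models, estimators and numerical choices behind
`rfmotion`. The package maps the joint spatial and directional receptive
field (RF) of a motion-selective neuron — the kind recorded in primate
cortical area MT — from its responses to a full-field random-dot stimulus,
using reverse correlation, and then asks two questions about the resulting
map: does the preferred direction change across the RF, and is the spatial
sensitivity profile a single hill or several?

## Stimulus model

The mapping stimulus ("BMDots") is a field of `n_dots` independently moving
dots at fixed speed (defaults: 300 dots on a 40° x 30° field, i.e. 0.25
dots/deg², 8°/s, 75 Hz refresh). Each dot keeps its motion direction for one
200 ms epoch and then redraws it uniformly on the circle. Per-dot epoch
phases are drawn uniformly per trial, so direction changes are interleaved
across frames rather than synchronized; the original interleaving schedule
is not specified anywhere, and an independent uniform phase is the simplest
rule with the right marginal statistics. Dots wrap toroidally at the field
edges — also an open choice; wrapping keeps the dot density exactly constant,
which the analysis implicitly assumes. The dot luminance profile (Gaussian,
sigma 0.2°, contrast 0.25) is carried as configuration metadata only: every
analysis operates on motion vectors, and none of the estimators below ever
touches pixel luminance.

Two single-dot control paradigms probe the map the classical way: `gridrf`
moves one dot in a constant direction inside one patch of an 11 x 11 probe
grid per epoch (block-randomized patch order, so coverage is balanced), and
`prefdir` probes up to five chosen patches with one of 64 directions per
epoch, both with patch-edge wrapping.

Angle convention: degrees in [0, 360), 0° = rightward, counter-clockwise
positive. Epochs truncated by a trial boundary are generated but flagged,
and all epoch-based analyses use complete epochs only.

## Stimulus encoding

For reverse correlation, each frame is summarized as a sparse space-direction
histogram: dots are counted jointly by 1° x 1° patch (half-open boxes; the
default grid covers 39° x 29° of the monitor with boundaries on integer
degrees — an odd patch count cannot also be centered on fixation, so the
default spans [-19, 20) x [-14, 15)°) and by 64 direction bins of 5.625°
(lower edge inclusive, bin center as representative angle). Only nonzero
cells are stored: a session of F frames holds at most `n_dots` entries per
frame, against ~70,000 dense cells, and every downstream pass is linear in
the number of dots.

## From spikes to the selective response

Spikes are binned at the frame duration. Two non-selective components are
removed before correlation: (1) the trial-locked response — the cross-trial
mean per bin, smoothed with a Gaussian of sigma 10 ms ("10 ms width" is read
as the standard deviation, the conventional reading; the choice only affects
signal-to-noise, not the maps) — capturing onset transients and within-trial
adaptation; (2) the per-trial mean, capturing slower-than-trial adaptation.
The smoothing kernel is truncated at 4 sigma and renormalized at the trial
edges so a flat signal stays exactly flat, and the output has exactly zero
mean per trial. The subtraction order (trial-locked first, then per-trial
mean) follows the description of the procedure.

## Spike-triggered average and PD map

The STA at latency Δ is the cross-correlation of the selective response with
the histogram, STA(p, d) = Σ_t r(t+Δ)·S_t(p, d) / N, accumulated over the
sparse entries; lagged bins beyond the trial end are skipped. The
normalization (divide by the number of contributing frames) is a free
choice — every downstream quantity is either a ratio or compared against a
null computed with the same normalization.

Each patch's 64-bin tuning curve is reduced to its preferred-direction (PD)
vector: the vector sum of the bin values at the bin-center angles. Constant
(untuned) components cancel exactly in this sum, which is why the PD length
is a preprocessing-independent measure of tuning strength. The analysis
latency is chosen per cell by maximizing the summed PD length over patches
on a one-frame grid from 0 to 100 ms (ties toward the smaller lag). Because
the stimulus redraws directions only every 200 ms the latency profile is
smooth, and one-frame resolution is more than sufficient; per-patch latency
differences are not estimable with this stimulus and are not attempted.

A per-direction baseline (mean STA across patches) separates excitatory from
suppressive directions; a patch is labeled suppressive when summed
suppression exceeds summed excitation (ties excitatory), and suppressive
patches are excluded from the excitatory-RF analyses.

Reliability is quantified by the split-half similarity: the STA is computed
on two random halves of the trials (whole trials, preserving trial-locked
structure) and compared with the similarity index ⟨u/‖u‖, v/‖v‖⟩ ∈ [-1, 1].

## Null calibration and the RF

The null STA is computed after reversing the session-concatenated response
in time, which destroys the causal stimulus–response correlation while
preserving the marginals of both. A null PD vector is the resultant of many
weak, independent contributions, so its two components are approximately
Gaussian and the squared length is sigma²·chi² with df = 2 (the df is forced
by the 2-D resultant geometry); sigma² is estimated as mean(L²)/2 over the
patch pool, giving the closed form p(L) = exp(-L²/2sigma²). Patches with
p < 0.01 form the RF after a cluster correction: keep only patches with at
least three significant 8-connected neighbors (one pass over the raw mask;
8-connectivity is used consistently for all spatial operations).

## Bootstrap comparisons between patches

Two patches are compared with a percentile bootstrap on their raw polar
data: every dot-direction occurrence paired with the lagged selective
response, grouped into 200 ms blocks — the timescale at which the stimulus
is independent — which are the resampling unit. Only the per-block resultant
vectors are needed (every statistic used is linear in them), so each patch
reduces to an (n_blocks, 2) array.

* Direction test: each patch is normalized to unit resultant (so only
  angles matter); statistic = absolute circular difference of the PD
  angles; the null pools both patches' blocks and redraws sets of the
  original sizes with replacement.
* Strength test: one patch is rotated so the PDs align (so only strength
  matters); statistic = difference of resultant lengths, one-sided: a small
  p means the first patch is significantly stronger.

Replicates are drawn adaptively in doubling chunks until (a) the observed
statistic has been exceeded at least `min_exceedances` times, (b) the
p estimate has fallen below the caller's decision threshold (more replicates
cannot change a Bonferroni decision), or (c) a cap `n_boot_max` is reached;
p uses the (1 + exceedances)/(1 + n) estimator and is never exactly zero.
The cap is a parameter (the procedure is meaningful up to 10⁷ replicates);
the pipeline default of 2·10⁴ (10⁴ in the multi-seed calibration studies)
resolves p well below the Bonferroni thresholds at the pair counts these
analyses produce.

A known boundary case: when two patches' PDs are exactly 180° apart and
both are strongly tuned, the pooled resultant cancels and the null
replicates themselves concentrate near 180°, so the attainable p-value
plateaus at the percent level regardless of replicate count. At any
separation meaningfully below 180° the null collapses toward 0° and the
test is decisive.

## RF structure

* Multiple preferred directions: direction bootstrap over all unordered
  pairs of RF patches, Bonferroni-corrected at alpha = 0.05; positive if any
  pair differs. For speed, pairs are visited in order of decreasing observed
  angular difference and the scan stops at the first significant pair — the
  decision is identical, only unvisited p-values go unreported.
* Multiple peaks: the RF is re-derived at the strict p < 0.005 threshold;
  supercover lines (all patches a geometric segment touches) run from the
  most responsive patch to every other RF patch; for every ordered
  (closer, farther) RF pair on a line the strength bootstrap asks whether
  the farther patch is significantly stronger, Bonferroni over all compared
  pairs. A significant increase with distance rejects the single-hill null;
  a non-significant decrease does not (the conservative reading of a
  monotone-RF null hypothesis). Peak ties break to the first in row-major
  order.
* Peak count: 8-connected components of the cluster-corrected p < 0.01 map.
* Percent missing: patches whose centers fall inside (or on) the convex
  hull of the RF patch centers but are not themselves in the RF, as a
  percentage of all hull patches. Degenerate hulls (collinear RFs) are
  handled as segments.
* Valley-over-peak: a threshold descends through the sorted distinct
  strength values inside the hull until a second isolated component
  appears; the ratio is (minimum strength on the supercover line between
  the two peak patches) / (secondary peak strength). Single-hill maps
  return none. Note that on a 1° grid the sampled valley is generally
  shallower than the continuous profile's minimum, since patch centers
  rarely coincide with the exact valley floor.
* Sub-regions: K-means (K = 2, 20 restarts, seeded) on the rows of the
  direction-similarity matrix S (S_ij = direction-bootstrap p-value between
  RF patches i and j; p-values are used raw, untransformed). Region
  strength R = length of the vector sum of the member patches' PD vectors;
  the stronger region is primary; reported ratios are secondary/primary
  x 100% for strength, patch count, and size-normalized strength, plus the
  circular difference of the region resultant angles. The segmentation is
  only meaningful for cells that pass the multiple-directions test.
* Geometry: an elliptical 2-D Gaussian (amplitude, center, two sigmas,
  orientation) is least-squares fit to the tuning-strength map over the RF
  bounding box (+2 patches margin), moment-initialized; RF size = sigma_long
  + sigma_short, elongation = sigma_long/sigma_short, and the angle between
  the strength-weighted circular-mean PD and the long axis is folded into
  [0°, 90°]. Requires >= 6 RF patches; non-convergence is reported as an
  absent geometry.

## Single-dot control analyses

Control responses are deliberately not preprocessed (they estimate actual
firing rates): the epoch rate is the spike count in a 200 ms window after
stimulus onset shifted by the neuron's onset latency — the first PSTH bin
deviating from the baseline mean by more than five baseline standard
deviations in either direction, with the single shortest latency applied to
all patches. The baseline estimator window is a caller choice (the
recommended default is the last 100 ms of pre-stimulus fixation, which the
synthetic sessions do not model; simulated controls pass the known latency).
Grid maps average epoch rates per patch (unvisited patches are unmapped, not
zero); direction tuning curves are smoothed on the 64-point circle with a
wrapped Gaussian kernel (sigma 5°, renormalized over observed directions, so
unprobed directions are interpolated and flagged), and the per-patch PD is
the circular mean of the rate distribution. Agreement between paradigms is
quantified by the similarity index on the common patches and by the
Fisher–Lee circular correlation of paired PD estimates (rotation-invariant;
permutation p-value), the standard coefficient for paired circular data.

## The model neuron (synthetic ground truth)

Recovery tests need a neuron whose RF is known exactly; a
linear–nonlinear–Poisson (LNP) cascade is the simplest generative model
consistent with everything the analysis assumes. Per patch p the tuning is
von Mises: the drive per dot moving in direction θ is
gain_p·exp(kappa_p·(cos(θ - PD_p) - 1)), so `gain` is the drive (spikes/s)
per dot at the preferred direction (kappa default 2). Frame drive is the sum
over the histogram's nonzero cells; the rate at t + latency is
max(0, baseline + drive + onset transient)·adaptation^trial, with an
optional exponential onset transient (exercising the trial-locked
subtraction) and a per-trial multiplicative adaptation factor; spike counts
are Poisson per frame with uniform spike times within the frame. Suppressive
patches carry negative gains. Gains below 10% of the peak are truncated to
exactly zero so the true support {gain > 0} is compact and
intersection-over-union against the mapped RF is well-defined.

Presets: `homogeneous` (one Gaussian hill, sigma 1.5°, one PD);
`two_direction` (two adjacent lobes, PDs differing by 90° by default —
within the range typical of real inhomogeneous cells); `two_blob` (two
lobes whose separation is solved numerically so the continuous gain profile
on the inter-peak line bottoms out at 0.2 of the weaker peak — the typical
observed valley depth); combinations; and a suppressive surround. Note that
adjacent lobes in `two_direction` also produce a genuine dip in the summed
gain profile, so that preset legitimately triggers the multi-peak test too.

What the simulator does not emulate: eye-position jitter, spike-sorting
contamination, refractory structure, non-Poisson variability, and
center–surround nonlinearities. Passing recovery tests therefore shows the
estimators are correct and calibrated for an LNP world, not that real MT
data are LNP.

## Calibration studies and problem sizes

The package's validation experiments (`rfmotion.calibration`, also run by
`scripts/acceptance.py`):

* Type-I, patch level: an untuned 20 spikes/s Poisson cell watching the
  standard full-field stimulus for 10 simulated minutes on the full ~1100
  patch grid; the fraction of patches at p < 0.01 should sit within
  binomial error of 0.01 before cluster correction.
* Type-I, cell level: 200 homogeneous-preset neurons (reduced 16° x 12°
  field at the standard density, 25 trials each); both inhomogeneity tests
  should fire at no more than their nominal 5% rates (Bonferroni makes them
  conservative, so observed rates are near zero).
* Recovery: homogeneous preset, 10-minute sessions at the reference
  high-SNR operating point (peak gain 120 spikes/s/dot); median PD error
  < 10°, latency within one frame, RF IoU >= 0.6.
* Power: `two_direction` (Δ = 90°) and `two_blob` (valley 0.2) at the
  reference operating point, 100-trial sessions; each detected in >= 80% of
  seeds.

The reduced field keeps the stimulus density and all timescales identical
to the full configuration and only shrinks the screen area, so per-patch
statistics are unchanged; it is what makes hundreds of complete
stimulus-to-decision replicates affordable. The reference operating point
(gain 120, compact sigma 0.9–1.5° RFs, baseline 5 spikes/s) corresponds to
a strongly driven, well-isolated cell — the regime in which the
inhomogeneity tests are meant to operate.

## Known limitations

* The bootstrap's 180°-separation boundary case (above).
* The valley-over-peak ratio is measured on the 1° patch lattice and is
  biased upward relative to the continuous valley depth.
* The 2-D Gaussian geometry is only fit for reasonably large (>= 6 patch)
  RFs and is not meaningful for multi-peaked cells.
* Split-half similarity on short synthetic sessions is noise-dominated (the
  full flattened STA includes every off-RF cell); it approaches 1 only as
  spike counts grow.
* Bootstrap p-values are resolved only to the configured replicate cap;
  decisions near a Bonferroni threshold at very large pair counts require
  raising `n_boot_max`.
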
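# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `bftrack`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Image model and band-pass filter

A bright-field frame is modeled as sparse, radially symmetric bright
objects (cells, ~30–50 px across at 0.977 µm/px) on a background with two
nuisance components: slowly varying illumination (scale ≫ cell size) and
fine-scale noise — per-pixel sensor noise and, on nanostructured
substrates, a grainy speckle with a correlation length well below the cell
size. Dark-on-bright data are handled by an `invert` flag.

The filter is `(I∘G∘G) − (I∘B∘B)` with `∘` separable 2-D convolution,
`G` a normalized 1-D Gaussian of standard deviation `noise_scale` and `B`
a normalized 1-D boxcar of full width `2·object_scale + 1`; each kernel is
applied twice. Both kernels are normalized, so constants cancel exactly,
and by symmetry linear ramps cancel in the interior too. Numerical
choices:

* Gaussian kernels are sampled at integers and truncated at radius
  `ceil(4σ)`, then renormalized; beyond 4σ the truncated mass is < 10⁻⁴
  of the kernel and invisible at float64 working precision.
* Convolution uses reflect (symmetric) padding. Padding only influences a
  band near the frame edge; a border margin of `object_scale` pixels is
  zeroed afterwards, which both hides the padding-dependent band and makes
  edge objects explicitly inaccessible to segmentation. Counts from small
  frames are therefore biased low near edges by construction — by design,
  not accident.
* Defaults: `noise_scale = 3` px (flat substrates), `object_scale = 40` px.
  The grainy preset raises `noise_scale` to 8 px: smoothing at 8 px costs
  blob amplitude (a σ≈7.5 px cell blob keeps ~30% of its peak) but crushes
  speckle with a 1–2 px correlation length by a much larger factor, which
  is exactly why band-pass filtering makes grainy substrates trackable.

## Segmentation

Peaks are 8-neighborhood local maxima at or above the peak exclusion
threshold, reported in descending brightness; an equal-valued plateau is
reported once, at its lexicographically smallest (x, y). The footprint is
the 8-connected component, containing the peak, of pixels at or above
`contour_cutoff × peak`; the cell position is the *unweighted* mean of
footprint pixel coordinates. Intensity weighting is available behind a
flag but off by default: the plain footprint centroid is the quantity the
rest of the pipeline (and the comparison statistics) are defined on, and
it is insensitive to the filter rescaling the intensity profile.

Selection order: (1) detections sharing one footprint collapse to the
brightest peak (prevents double-counting one object whose isohypses
merged); (2) area limits; (3) any two detections closer than
`min_separation` are *both* removed — a deliberately conservative rule so
that only unambiguous, independent cells enter tracking. Per-frame
settings between the user-tuned first and last frame: the threshold is
linearly interpolated, the contour cutoff is the mean of the two
endpoints, everything else comes from the first frame. Coordinates are
0-based, x = column, y = row, pixel centers at integers.

For grainy scenes a higher contour cutoff (0.6–0.7 instead of 0.5)
confines the footprint to the high-signal core of the blob and reduces
centroid noise; the tests use 0.6 on the grainy preset.

## Tracking

Linking is per-frame-pair optimal assignment (Hungarian algorithm,
squared-displacement cost) with links longer than `max_displacement`
(default 20 px) forbidden; unmatched detections open new tracks, and a
track end survives `memory` frames (default 0) so short detection gaps can
be bridged, with the gating radius scaled by the gap length. Optimal
assignment rather than greedy nearest-neighbor keeps the result
deterministic and correct in the sparse scenes this tool targets; it makes
no attempt at dense-culture or division-aware tracking.

The RMSD filter computes `sqrt(Σ|r_i − r̄|²/(N−1))` per track (note the
N−1) and discards tracks below the threshold (default 15 px ≈ half a cell
diameter). This removes immobilized and dead cells automatically; it also
removes genuinely slow cells, whose contribution to the velocity
autocovariance would be near zero, but their exclusion *can* inflate φ₀ —
users should state the threshold used. Manual post-processing is an
exclusion-list text file (`track_id [frame_start frame_end] reason`);
flagged intervals are skipped by the statistics (they split velocity
segments), keeping human judgment out of the automated path.
`round_track_coordinates` (nearest integer, ties to even) reproduces the
coordinate-truncation behavior of integer-output trackers for sensitivity
studies.

## Motility model and estimators

The motility model is the persistent random walk: stationary velocity
process with autocovariance `φ(τ) = φ₀ e^{−τ/P}`. Its integrated form is
the Fürth MSD, extended with a constant offset for white centroid
measurement noise of per-coordinate standard deviation σ_pos:

    MSD(τ) = 2 φ₀ P [τ − P (1 − e^{−τ/P})] + 4 σ_pos²   (τ > 0)

Estimator choices:

* Velocity is the forward difference over one frame interval (µm/min);
  gaps and excluded intervals split a track into uniformly sampled
  segments. This is the simplest estimator for which φ(0) equals the mean
  squared velocity by construction.
* φ(τ) averages the full 2-D dot product `v(t)·v(t+τ)` over all cells and
  time origins (units µm²/min²); MSD(τ) averages `|r(t+τ) − r(t)|²` over
  all origins. Per-lag standard errors are the naive (sample std)/√n of
  the contributing products — knowingly an underestimate at long lags,
  where products overlap in time (see error correction below).
* Fits are weighted least squares (`scipy.optimize.curve_fit`,
  `absolute_sigma=True`, weights 1/stderr²). The acov fit excludes τ = 0
  by default (noise-inflated; a flag re-includes it) and iterates its lag
  window once: an initial log-linear decay estimate P₀ sets the window
  Δt…3P₀. The Fürth fit uses all τ > 0 up to the configured `max_lag`
  (default ⅓ of the longest track duration); its noise offset is fitted
  unconstrained and, if negative, σ_pos is clamped to 0 and the fit
  flagged. A negative fitted P flags the fit invalid rather than raising.

## Error correction and pooling

Autocovariance/MSD points from one track set are mutually correlated, so
the WLS covariance underestimates parameter errors — the worked example in
the README shows a ~25× gap on P. Corrected errors come from a seeded
cell-level bootstrap: cells are resampled with replacement (n_boot ≥ 100,
default 200), per-cell lag statistics are pre-accumulated so each
replicate only re-sums moments and refits with the original fit window,
and the corrected error is the bootstrap standard deviation times the
small-sample factor √(n/(n−1)), floored at the raw error. Fewer than three
cells is refused — a cell-level bootstrap over one or two cells estimates
nothing. The bootstrap is a methodological choice for quantifying the
redundancy effect; its calibration is itself verified by coverage tests
(corrected 1σ intervals cover the truth at a rate inside [50%, 85%],
nominal 68%, over 50 simulated studies).

Multi-movie pooling is the inverse-variance weighted mean with pooled
error `sqrt(1/Σσᵢ⁻²)`, computed on corrected errors. One caveat is
documented and measured rather than hidden: for exponential-decay fits the
error estimate scales with the estimate itself, so inverse-variance
weights slightly overweight low-P movies and bias the pooled P downward by
a few percent at the 5-movie scale; the acceptance run reports both pooled
and combined-dataset (union of tracks) values so the effect is visible.

## Comparison toolkit

Co-identification between two centroid sets is mutual-nearest-neighbor
matching with a distance gate. Translational alignment subtracts the mean
pair displacement (the least-squares-optimal translation — an instrument
offset such as a filter-cube light-path shift is removed, rotation/scaling
deliberately not). The mismatch measure is the pairwise RMSD with
denominator N (unlike the track-excursion RMSD's N−1). Under the
measurement model `r = r_true + ξ` with white noise of per-coordinate
variance σ², the expected squared RMSD between two programs i, j is
`2σᵢ² + 2σⱼ²` plus systematic terms; `noise_decomposition` returns that
residual exactly. Isotropy of mismatch directions is tested by a χ²
test on the polar-angle histogram (8 bins by default; the χ² test is a
choice, any uniformity test would do). Track-level matching declares two
tracks the same cell when their mean distance over shared frames is below
a threshold (default 10 µm); common subsets across ≥3 programs require all
pairwise matches to agree.

The focus-stack analysis takes the same cells' centroids in each z-plane,
subtracts each plane's mean centroid (stage drift), and reports the RMS
of each cell's 2-D displacement from its stack-mean position, per plane
and overall. With n planes, subtracting the per-cell stack mean shrinks a
true jitter of RMS magnitude J to an expected measured √(1−1/n)·J (≈0.94
at n = 8); the 15% test tolerance absorbs this.

## Synthetic data generator

The generator exists so that recovery can be tested against known truth;
its defaults are the reference study conditions: Δt = 2 min, 0.977 µm
pixels, 1024×768 frames, P = 35 min, φ₀ = 0.18 µm²/min²,
σ_pos = 1.40 µm, ~12–15 cells per ~12 h movie, cells rendered as Gaussian
blobs of σ = cell_radius/2 with cell_radius = 15 px.

* Motion is the exact discrete Ornstein–Uhlenbeck velocity update
  `v_{n+1} = a v_n + b η_n`, `a = e^{−Δt/P}`, per-component stationary
  variance φ₀/2 (so E[v·v] = φ₀), `b = √((φ₀/2)(1−a²))`, initialized from
  the stationary law. Its autocovariance is *exactly* φ₀e^{−τ/P} and its
  MSD exactly the Fürth curve, so any recovery bias is attributable to the
  estimators, not model mismatch. Start positions are uniform with a
  minimum mutual spacing (default 80 µm) and an optional edge margin so
  short rendered movies keep cells clear of the filter's zeroed border.
* Measurement noise is i.i.d. Gaussian per coordinate (σ_pos µm), total
  variance 2σ_pos² per point.
* Backgrounds: `flat` (constant 20 + pixel noise σ=2), `gradient` (linear
  ramp, amplitude 50 across the frame), `grainy` (unit-variance speckle =
  white noise smoothed at `grain_scale`, scaled by `grain_contrast`). The
  silicon-black-like preset uses background level 100, grain_scale 1.5 px
  and contrast 20 (speckle std = 20% of the cell peak 100): strong enough
  that raw-image thresholding drowns in false maxima, fine-grained enough
  that the 8 px band-pass suppresses it — the regime the grainy-substrate
  problem actually presents. Frames are quantized to 8 or 16 bit.
* `make_comparison_fixture` produces two independently noisy copies of one
  truth plus a constant offset — the exact generative model behind the
  pairwise-RMSD decomposition, enabling the closed-form check
  E[RMSD²] = 2σ_a² + 2σ_b² after alignment.

What the generator does **not** emulate: cell morphology and deformation,
lamellipodia, division and contact events, photobleaching, focus drift,
and intensity fluctuations of individual cells. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every behavior of real cultures; the manual
exclusion-list mechanism exists precisely because division/contact
screening is not automated.

## Problem sizes used in tests and acceptance runs

Segmentation accuracy is measured on 5-frame, 20-cell movies at full frame
size (flat and grainy); motility recovery on 50 replicates of 5 movies ×
12 cells × 360 frames with 100 bootstrap replicates per fit (per-cell lag
moments are pre-accumulated, which makes the 25 000 bootstrap refits
cheap); σ_pos recovery on 15 cells × 360 frames; the RMSD closed form on
10⁴ points; the focus stack on 92 cells × 8 planes. These sizes match the
reference study's scale where one exists and are otherwise chosen to make
Monte-Carlo tolerances comfortable.

## Known limitations

* No watershed splitting of touching cells and no model-shape fitting:
  merged footprints resolve to one (brighter) object, and close pairs are
  dropped rather than disentangled.
* The linker is not probabilistic; it will mis-link if cells move more
  than the gating radius per frame or cross paths within it.
* The bootstrap correction quantifies sampling error given the model; it
  does not detect model misspecification (e.g. genuinely non-exponential
  persistence, anomalous diffusion).
* Inverse-variance pooling inherits the small downward P bias discussed
  above; with handfuls of movies an unweighted mean is a useful
  cross-check.
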
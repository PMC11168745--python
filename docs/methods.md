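# Methods

This note documents the models, the algorithmic choices and the limits of the
synthetic data, in the package's own terms. Units throughout: µm for space,
s for time, camera counts for intensity.

## Live-branch processing chain

**Background subtraction.** Each z-slice is background-subtracted with the
rolling-ball algorithm (default radius 80 px). For radii above ~10 px the
image is first reduced by a block-minimum (shrink factor `min(8, radius/10)`),
the ball is rolled on the reduced image, and the background is bilinearly
interpolated back — the same acceleration the classic ImageJ implementation
uses. The ball's *spatial* radius shrinks with the image but its *intensity*
radius does not (an ellipsoid kernel), otherwise steep backgrounds are no
longer followed. The estimated background is clipped to the image so output is
non-negative. The choice to subtract per z-slice before projection (rather
than once on the projection) is configurable (`background_mode`); per-slice is
the default.

**Blur and projection.** A 3D Gaussian blur (σ = 1 px isotropic) precedes a
brightest-point (maximum-intensity) projection along z. Tracking operates on
the 2D projection; z is retained for rendering and geometry but not used in
the linking distance.

**Detection.** A punctum is a regional maximum that stands at least the
prominence threshold (default 20 counts) above *both* (a) the lowest saddle
separating it from any higher region — exact topographic prominence, computed
by a union-find flood over pixels in descending intensity order, which
guarantees one detection per spot — and (b) the median intensity of its local
neighbourhood (21×21 px window). Condition (b) is the "over background
intensity" part of the threshold: by convention the topographic prominence of
an image's global maximum is its height above the global minimum, so without
a local-background condition the brightest ripple of any smooth background
(e.g. residual cytosolic signal the rolling ball cannot fully remove from a
cell-sized plateau) would always be reported as one spurious punctum per
frame. Detected maxima are localised to sub-pixel precision by centre of mass
in a 5×5 window (configurable off); detection counts are monotonically
non-increasing in the threshold.

**Linking.** Crocker–Grier-style frame-to-frame assignment solved exactly per
frame with the Hungarian algorithm on an augmented cost matrix: squared
displacement for feasible links (hard cutoff at the search range, default
8 px = 0.85 µm), a penalty of `search_range²` for each unlinked track and
each unlinked detection (so linking a feasible pair is never worse than
leaving both unlinked), and zero for dummy-dummy pairs. A track may vanish
for up to `memory` frames (default 6 = 60 s) and be continued; the search
range applies to the displacement from its last known position regardless of
gap length. Ties are broken toward continuing the longer existing track via
an infinitesimal (10⁻⁹ px²-scale) cost bonus, making the output deterministic
and independent of detection order within a frame (detections are also sorted
by position before assignment). Tracks with fewer than `min_length` (default
2) detections are discarded.

**Lifetimes and first formation.** Frames are indexed from 0 internally; all
user-facing outputs are seconds. A track spanning frames [first, last] has
lifetime (last − first + 1)·Δt, fixed by equating a 2-frame track with 20 s
at Δt = 10 s. Tracks present in frame 0 are "pre-formed": their formation
time is unobserved and they are excluded from formation-time and lifetime
statistics. The first-formation time is the earliest remaining track start
(frame index × Δt); a movie with no eligible tracks reports "no formation
observed" rather than an error. Tracks still present in the final frame are
flagged right-censored in the outputs but are not excluded or corrected for —
at the simulated margins the censored fraction is well under 1%.

**Cell geometry and classification.** The cell is segmented from the raw
brightest-point projection: Otsu's threshold computed on the time-median
image (so transient puncta cannot skew it), each frame smoothed (Gaussian
σ = 2 px) before thresholding (single noise pixels in a max-projection
otherwise seed speckles), morphological closing, hole filling, largest
connected component. The boundary is the sub-pixel 0.5-level contour; the
centroid re-expresses every localisation in the cell frame (drift
correction). Distance to the boundary is the 2D Euclidean distance to the
nearest contour point of the frame-matched boundary (a 3D option exists but
2D is the default, matching the projected trajectories). A localisation
within 1.4 µm of the boundary is "membrane", otherwise "cytoplasm"; the
comparison is inclusive (≤). Trajectories whose *first* localisation is
cytoplasmic are excluded from downstream kinetics; for occupancy-over-time
counts each localisation is re-classified per frame, so a punctum that
internalises after assembly moves from the membrane to the cytoplasm count.

## Lifetime kinetics

The two-step degradation model is the hypoexponential distribution: the sum
of two independent exponential waiting times with rates k₁ and k₂,

P(τ) = k₁k₂/(k₂−k₁)(e^(−k₁τ) − e^(−k₂τ)), ⟨τ⟩ = 1/k₁ + 1/k₂,
Var = 1/k₁² + 1/k₂².

The density is symmetric under k₁ ↔ k₂; rates are reported in canonical order
k₁ ≤ k₂. When |k₁ − k₂| < 10⁻⁶·min(k₁,k₂) the Erlang-2 limit k²τe^(−kτ) is
evaluated instead to avoid catastrophic cancellation; the log-likelihood uses
the log1p form throughout.

Fitting: maximum likelihood on raw lifetimes (default; Nelder–Mead on
log-rates, tolerance 10⁻⁹, initialised from the method of moments — when the
sample coefficient of variation falls below the hypoexponential range the
Erlang point 2/mean is used as the start). A histogram least-squares variant
fits P(τ) to the unit-normalised lifetime histogram for parity with
figure-style fits; on well-sampled data the two agree within 10%. Because
observed lifetimes are multiples of Δt, an interval-censored likelihood
(CDF differences over each frame bin) is available; the continuous
approximation is the default and differs negligibly at Δt = 10 s.

A fit is flagged `near_degenerate` when the fitted rates are effectively
indistinguishable (k₂ − k₁ < 10⁻³k₁, the Erlang limit) *or* effectively
single-step (k₂/k₁ > 50). The second arm matters because for genuinely
exponential data the hypoexponential likelihood is maximised on the boundary
k₂ → ∞ (which reproduces the exponential exactly), not at k₁ = k₂; either
way the two-step model is not identifiable from such data and the flag says
so. Bootstrap confidence intervals (default 1000 seeded resamples, percentile
2.5/97.5) are attached to k₁, k₂ and ⟨τ⟩. Distributions are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p-value).

## Fixed branch (cluster morphometry)

The super-resolved image is thresholded (Otsu by default) into binary cluster
masks; the matched widefield reference channel is thresholded into ROIs
(bounding boxes around blobs, expanded by 2 px), and only clusters whose
centroid falls inside an ROI are analysed — the colocalisation criterion is
centroid-in-ROI, and the filter can only remove clusters. dSTORM
reconstruction itself is consumed, not implemented.

Shape factor: 4πA/p² with A = pixel count × pixel area and p = the
marching-squares contour length of a lightly Gaussian-smoothed (σ = 1 px)
copy of the mask. The half-level contour of a *raw* binary mask is a
45°-staircase polygon whose length overestimates a smooth boundary by up to
~5% (and plain pixel-edge counting by up to ~27%), which would bias every
shape factor low; contouring the smoothed mask recovers disk perimeters to
well under 1%. Masks too small to survive smoothing fall back to the raw
contour. Discretisation can still push raster values marginally above 1, so
values are capped at 1. Classifying a *pixelated* cluster as "spherical" uses
a tolerance of 0.05 below 1 (the documented residual discretisation spread at
the smallest cluster sizes, ~5 px radius); exact-geometry values use 10⁻³.

Sizing: a 1D Gaussian with offset is least-squares fitted to the intensity
profile along x through the cluster centroid (an option averages x and y);
FWHM = 2√(2 ln 2)σ and the reported diameter is d = FWHM/2.355. Per
condition and timepoint the pipeline reports n, mean and median sizes, and
unpaired two-sided Student's t-tests between conditions (groups with n < 2
excluded).

## Synthetic data: what it emulates and what it does not

The generator reproduces the acquisition geometry of the study it mirrors:
z-stacks of 100 slices at 200 nm spacing every 10 s (defaults; tests use
smaller stacks), pixel size 0.10625 µm (so that 8 px = 0.85 µm), a single
adherent cell 10–20 µm across modelled as a circular footprint extruded into
a ~2 µm fluorescent slab, optionally drifting rigidly. Puncta nucleate as a
Poisson process after a configurable stimulus delay, with an optional finite
nucleation window (the agonist is delivered as a short local pulse, so a
bounded burst is the realistic default for recovery studies); lifetimes are
drawn exactly from the two-step model as the sum of two exponentials.
Placement: a fraction `membrane_fraction` of events is placed within 0.7 µm
of the boundary — membrane-bound complexes sit *at* the membrane, well inside
the 1.4 µm analysis threshold, so classification accuracy on synthetic data
reflects boundary-estimation error rather than coin flips at the decision
edge — and the rest at least 2 µm into the interior. Nucleation sites keep a
minimum separation (default 1 µm, just above the 0.85 µm search range):
puncta closer than the linking search range are unresolvable by construction
and ground-truth trajectories would be ill-defined. If dart-throwing cannot
satisfy the separation (overcrowded configurations), the most isolated
candidate is used instead of failing.

Rendering: each live punctum is a 3D Gaussian (σxy = 0.15 µm, σz = 0.4 µm)
of peak `photon_amplitude` on the cell background; voxel values are
Poisson(photon expectation) plus Gaussian read noise (σ = 2 counts), rounded
to uint16. The background is `background_level` (100 counts) inside the cell
slab and `outside_level` (85 counts) outside; the 15-count cellular excess is
deliberately modest, because a diffuse cytosolic plateau much taller than the
rolling ball can sag under a cell-sized disk would survive background
subtraction as a dome — which real cytosolic MyD88-YFP, imaged with a
camera offset near 100 counts, does not.

Not emulated: punctum photobleaching, dSTORM blinking photophysics and
reconstruction, sub-punctum structure, non-circular or 3D-curved cell shapes,
punctum mobility (static by default; Brownian motion with configurable D is
available), and intensity heterogeneity between puncta. Passing
recovery tests therefore demonstrates the correctness of the *analysis* under
the stated imaging model, not robustness to every property of real
recordings. All randomness flows from one seeded generator per simulation
call; identical config (including seed) reproduces bit-identical stacks,
events and masks.

## Problem sizes used in the automated checks

The end-to-end recovery study runs ten cells of 160 frames × 12 z × 160² px
(17 µm field, 7 µm cell), a 100 s nucleation burst at 0.25 events/s after a
300 s delay, 90% membrane placement and k₁ = 0.005/s, k₂ = 0.02/s
(⟨τ⟩ = 250 s), pooling ~250 tracks — enough that the mean-lifetime standard
error (~5%) sits well inside the 15% recovery tolerance while each cell
renders and analyses in seconds. Rate-recovery checks use 10⁴ directly
simulated lifetimes; morphometry checks use 200 rasterised clusters at 10 nm
pixels. The tracker is validated against a brute-force oracle that
exhaustively enumerates every feasible per-frame assignment on instances of
up to 5 detections per frame × 10 frames, over 200 random instances.

## Outputs and determinism

All tabular outputs are CSV with a fixed float format, and JSON reports and
manifests carry no timestamps, so rerunning any pipeline with the same
config, seed and inputs is byte-identical. Manifests record the package
version, the config and its hash, the seed, and SHA-256 checksums of file
inputs. Stage logs record counts into and out of every filter (detections,
tracks surviving the minimum length, pre-formed removed, membrane-initiated
retained, censored) so the filtering cascade is auditable.
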
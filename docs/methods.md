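# Methods

## Task geometry and kinematics

The workspace is 1000 × 1000 px with the home target at (500, 500)
(radius 75 px). Peripheral targets are annular sectors at 8 directions
(45° spacing) in three sizes: *large* (45° span, 250–450 px), *shallow*
(45°, 325–375 px) and *narrow* (15°, 250–450 px). Cursor position is
sampled at 100 Hz.

Speed is computed by filtering x and y independently with a first-order
10-Hz low-pass Butterworth applied forward and backward (zero phase lag;
reflect padding at the edges, where the filter is otherwise undefined),
then taking the five-point central difference
(coefficients (1, −8, 0, 8, −1)/12 per sample, scaled by the sample rate;
second-order one-sided differences at the two samples on each edge) and
the Euclidean norm. Bidirectional first-order filtering attenuates a
bell-shaped bump of 250-ms full-width-half-max by about 2%; statistics are
computed on the filtered speed.

Submovement peaks are local maxima with height > 250 px/s and prominence
≥ 50% of the height, prominence being the height above the larger of the
two adjacent troughs (each trough the minimum before encountering a larger
sample). Plateau ties resolve to the earliest sample. Onset/offset are the
half-maximum crossings found by linear interpolation (avoiding 10-ms
quantization); a missing crossing is flagged open-ended. The first peak
whose movement end — the cursor position at the half-max offset — lies
≥ 150 px from the center is the initial submovement ("movement end" is
not further specified by the segmentation rule, so this choice is
configurable); earlier peaks are rejected as pre-initial. A later peak is
corrective only if part of its acceleration phase (preceding speed trough
to peak) lies outside the peripheral target.

## CI phase

Spikes are counted in 10-ms bins, converted to spikes/s, smoothed with a
Gaussian kernel (σ = 30 ms, truncated at ±4σ and renormalized), and
square-root transformed to equalize variance across firing-rate scales.
Smoothing precedes the transform (counts are the natural smoothing domain;
the ordering is configurable via `bin_smooth_sqrt(..., sqrt=False)` plus a
manual transform).

The condition-independent (CI) trajectory is the average of unit rates
across all submovement speed peaks, −500…+300 ms, regardless of direction
or target size: with balanced conditions, cosine-tuned components cancel
and the average isolates timing-related modulation.

jPCA: the trajectory is centered per unit, projected onto its top six
principal components, differentiated by central differences, and fitted
with the least-squares skew-symmetric dynamics matrix M. The stationarity
condition for min‖Ẋ − MX‖ over skew M is the Sylvester equation
`M·XXᵀ + XXᵀ·M = ẊXᵀ − XẊᵀ`, solved in closed form; tests verify it
against an independent design-matrix least squares and direct numerical
minimization. All eigenplanes of a skew matrix rotate (purely imaginary
eigenvalues), so "the plane with the most rotational activity" is taken as
the conjugate-pair eigenplane capturing the largest projected trajectory
variance; ranking by eigenvalue magnitude alone can select a low-amplitude
fast harmonic of the traveling CI bump, which made the iterative refit
oscillate in development.

Conventions: +CIx points at the plane angle with the largest population
mean firing rate (pre-transform rates, binned over 100 plane-angle
intervals; empty bins filled by circular interpolation), and the rotation
sign is chosen so the phase increases on average (counter-clockwise, CIy
lagging CIx by π/2). The alignment rate is the raw (pre-sqrt) population
mean; the sqrt-domain alternative shifts the alignment by < 1 bin on
synthetic sessions.

CIφ: CIx and CIy are projected over the whole session, and the analytic
signal is computed per contiguous segment (per trial when trial spans are
known). Instantaneous phase from the Hilbert transform is only meaningful
for a locally zero-mean signal; subtracting one per-segment mean leaves
the small corrective cycles riding the slow amplitude envelope of the
large initial cycle, which biases their phase ≈ 40 ms early (measured on
noise-free synthetic rates). Each segment's Gaussian-smoothed trend
(σ = 400 ms, about half a rotation cycle) is therefore subtracted first;
this restored unbiased lead recovery for both submovement classes and is
the package's numerical choice where the procedure is otherwise
unspecified. CIφ is the circular mean of φx and φy + π/2; segments
shorter than 10 bins get missing phase.

Iteration: corrective movements are not time-locked to trial events, so
after the event-aligned fit the unit rates are re-averaged within 36 CIφ
bins (occupancy-weighted; empty bins circularly interpolated), jPCA is
refit on this phase-indexed (circular, wrap-around differences)
trajectory, and the loop runs three times; the principal angle between
successive planes is reported and typically falls below 2° by the last
iteration. Cross-validation partitions trials into 5 seeded folds; each
fold's plane is fitted on the other four (trials as separate Hilbert
segments) and applied to the held-out trials, and each fold is aligned by
the same +CIx/sign rule so phases pool consistently.

## Timing models

The CIφ predictor marks upward zero crossings of CIφ (wrap jumps across
±π excluded; crossing time by linear interpolation). The comparator is an
ordinary least-squares regression of submovement peak speed on per-unit
rates averaged −300…+100 ms around the peak — a single neural dimension
with no per-unit lags — whose local maxima serve as predictions. For both
models, predictions within −300…+100 ms of a speed peak count as aligned;
several candidates resolve to the one nearest the peak (latest before,
else earliest after), the same tie rule for both models. Aligned offsets
are summarized by their SD; SDs are compared with a two-sided variance-
ratio F test (n₁−1, n₂−1 dof, normality assumed; the CI is
F/F₀.₉₇₅…F/F₀.₀₂₅). The regression is fitted in-sample per session; a
cross-validated mode is available for symmetry but is not the default.

Circular–linear correlation between CIφ and speed uses
r = √((r²cs + r²ss − 2 r_cs r_ss r_cc)/(1 − r²cc)) with the χ²(2)
approximation n·r² for the p-value, plus the phase bin of maximum mean
speed.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes,
with full ground truth for parameter recovery:

* **Trials**: 8 directions × 3 sizes cycled for exact balance. Initial
  peak speed ~ N(1350, 200) px/s (clipped at 1000); speed profiles are
  Gaussian bumps, FWHM 250 ms (initial) / 200 ms (corrective); the cursor
  path is the sum of displacement segments (each the bump's closed-form
  integral). A trial has ≥ 1 corrective with probability 0.3 (repeated,
  capped at 3).
* **Misses**: corrective-flagged trials are constructed to miss — a
  radial over/undershoot when the sampled extent already falls outside the
  target's radial span, otherwise an angular miss just past the half-span —
  so the corrective's acceleration phase verifiably starts outside the
  target. Intermediate corrections in multi-correction trials step away
  from the target midpoint (direction rotated until the endpoint clears
  the target region), keeping the following correction classifiable.
* **Timing**: inter-peak intervals are a shifted gamma (shape 3) with
  mean 570 ms and minimum 420 ms — the minimum chosen so consecutive bell
  profiles remain resolvable under the 50%-prominence rule, matching the
  observation that distinct low-speed troughs separate almost all
  submovements. Trial tails (final hold + intertrial) vary uniformly
  600–1200 ms so the session is not quasi-periodic.
* **Ground truth** records the analytic local maxima of the summed
  velocity profile (not the nominal bump centers): overlapping bumps and
  partially cancelling directions shift the true kinematic peak by up to
  ~10 ms, and ground truth must describe the generated kinematics.
* **Units**: 100 units by default (the scale of multielectrode-array
  sessions with single- and multiunits pooled), baseline 2–15 spikes/s,
  lead times uniform on [−200, 0] ms, per-unit gain 0.5–1.5 × 0.025
  (spikes/s)/(px/s), cosine tuning depth uniform on [0, 0.5]. Unit rate =
  baseline + Σ over submovements of gain · peak-speed · tuning ·
  Gaussian bump centered lead-time before the speed peak, rectified at 0;
  spikes are an inhomogeneous Poisson process sampled exactly per 1-ms
  bin (Poisson counts with uniform jitter). Optional lognormal per-trial
  gain noise is off by default (no per-trial variability model is
  otherwise specified).
* **Seeding**: one root seed fans out to per-trial and per-unit
  substreams, so output is bit-reproducible and earlier trials are
  unchanged when trials are added.

What the generator does **not** emulate: limb biomechanics, non-Poisson
spiking (refractoriness, bursting), slow nonstationarities, correlated
noise across units, unbalanced condition sampling, or sorting artifacts.
Passing parameter-recovery tests therefore shows the pipeline is correct
and well-calibrated under its own assumptions — not that real cortical
data satisfy those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run sessions of 120–200 trials with
100–200 units (a few minutes of simulated time per session), the scale at
which unit-sampling noise in the mean lead time (SE ≈ 58/√n_units ms)
sits well inside the ±20-ms recovery tolerance. Degenerate inputs:
rank-deficient trajectories reduce the PCA rank with a warning; constant
population rates leave alignment at identity with a warning; zero-variance
speed profiles return missing correlations; events whose averaging window
leaves the session are dropped and counted.

## Known limitations

* The rate-regression comparator counts any local maximum of its weighted
  signal; under Poisson noise such maxima almost always exist, so its
  aligned fraction on synthetic sessions is ≈ 1 and the aligned-fraction
  comparison between models is less informative than the SD comparison.
* CIφ occasionally (≲ 0.1% of submovements) lacks a zero crossing in the
  evaluation window when the trajectory transiently reverses (clockwise
  motion past ±π) — the analysis's own "unaligned" category, reported,
  not imputed.
* The Hilbert trend-removal scale (400 ms) assumes rotation cycles near
  1–2 Hz; markedly slower dynamics would need a wider trend window.
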
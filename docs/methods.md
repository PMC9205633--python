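# Methods

This note documents the models, algorithms, parameters, and numerical
choices in `minicnmf`, and what the simulation-based tests do and do not
demonstrate about real recordings.

## Data model

Video is an `xarray.DataArray` with dims `("frame", "height", "width")`,
float32, non-negative, kept on the raw 8-bit scale (0–255); `fps` lives in
`attrs`. The factorization containers are `A` (unit, height, width), `C`
and `S` (unit, frame), background `b` (height, width) and `f` (frame). The
residual `E = Y − AC − bf` is computed on demand (`CNMFModel.residual`) and
never stored. Arrays persist to Zarr through the xarray backend (the
documented default store; round trips are bit-exact including axis names
and coordinates).

Chunked execution: `rechunk` records a per-axis chunk plan in `attrs`, and
the stage implementations iterate over frame/pixel blocks of that size.
Chunking is an execution detail only — every stage's output is identical
(within float tolerance) under any plan, which the test suite checks
explicitly. The arrays themselves are held in memory (a 3,000-frame
128×128 float32 video is ~190 MB); out-of-core operation over longer
recordings is reached by persisting each stage's output to Zarr and
processing one stage at a time, not by a task scheduler.

## Preprocessing

1. **Vignetting removal** — subtract each pixel's temporal minimum. Exact,
   idempotent, preserves the linear intensity scale.
2. **Denoising** — per-frame 2-D median filter, square window `denoise_wnd`
   (odd). The window should be about the average cell *radius* in pixels:
   big enough to kill salt-and-pepper sensor noise, small enough not to
   fuse adjacent cells.
3. **Background removal** — per-frame top-hat: subtract the grayscale
   opening (erosion then dilation) with a flat disk of diameter
   `background_wnd` ≈ the expected cell *diameter*. The opening acts as a
   size filter: anything smaller than the disk (the cells) is removed from
   the background estimate, so subtracting it keeps cells and drops
   out-of-focus fluorescence. Output is non-negative by construction.

All filters use reflected boundaries. On integer-valued frames (the normal
case for 8-bit input — the simulator also quantizes to integers) both
filters run through histogram-based rank filters on a symmetric-padded
frame, which is exact and several times faster than the generic float
path; the two paths agree bit-for-bit on integer data (tested).

## Motion correction

Integer-pixel rigid translation only. A frame's shift against a template
is the argmax of normalized cross-correlation over
`[−max_shift, max_shift]²`, computed by correlating the template interior
(cropped by the search radius) against the shifted frame window
(`skimage.feature.match_template` supplies the NCC; an exhaustive-search
oracle checks it in the tests). Ties break toward the smallest L∞ shift,
then row before column.

The whole movie is registered divide-and-conquer: leaf chunks of
`chunk_nfm` frames (default 3) register every frame to the chunk's middle
frame; then chunks merge in groups of three, registering the outer chunks'
max projections to the middle chunk's max projection, recursively until one
chunk spans the movie (chunk counts shrink by 3 per level). Max projections
make stable templates because they accumulate cellular activity over time.
At every merge the shift between the two *consecutive border frames* is
also estimated; if it disagrees with the max-projection shift by more than
`fallback_thres` px (default 5) on either axis, the consecutive-frame shift
wins — this catches the pathological case where the two chunks' projections
are dominated by different cells.

Numerical choices: the internal search radius is capped at a quarter of the
frame side so the template core keeps at least half the frame (a tiny core
correlates with noise); degenerate (zero-variance) comparisons inside the
recursion count as evidence of no motion, while the public
`match_template_shift` raises on flat images; final shifts are re-referenced
to frame 0 and clipped to `±max_shift`. Frames with no visible activity can
register arbitrarily against noise — harmless, since nothing in them
contributes to the factorization. `apply_shifts` translates by the negated
shift with a constant fill (default 0); no interpolation.

## Seed initialization

* `seeds_init` — max projections over rolling windows (`wnd_size` 1,000
  frames, `step_size` 200; or `n_iter` random draws). A pixel seeds if it
  equals the maximum within a `max_wnd`-diameter neighborhood and exceeds
  `diff_thres` (default 3 on the 0–255 scale — the video is
  background-subtracted, so a low absolute threshold suffices). Windowed
  projections catch cells that fire only briefly; the union over windows is
  deliberately over-complete.
* `pnr_refine` — split each seed trace at `noise_freq` (default 1 Hz) with
  an exact brick-wall FFT filter (low + high components sum to the input);
  keep seeds whose peak-to-peak(signal)/peak-to-peak(noise) exceeds
  `pnr_thres` (default 1: real fluctuations should at least match the noise
  floor). A zero noise band keeps the seed (ratio +∞).
* `ks_refine` — one-sample Kolmogorov–Smirnov test of the z-scored trace
  against a standard normal; keep seeds with p < `ks_sig` (default 0.05).
  A calcium trace is a Gaussian noise floor plus sparse large transients,
  hence non-normal; pure-noise seeds are normal and get dropped.
* `seeds_merge` — link active seeds within `merge_dist` px (default 8)
  whose low-pass-smoothed traces (same 1 Hz cutoff) correlate ≥
  `merge_corr` (default 0.8); keep the brightest seed per connected
  component.
* `init_spatial` — footprint weights are the cosine similarity between the
  seed trace and each pixel trace within a `init_wnd`-radius square
  (default 10 ≈ cell diameter), zeroed below `sim_thres` (default 0.5);
  the seed pixel is 1 by definition. Similarity is computed on raw traces;
  zero-norm pixels get 0.
* `init_temporal` — `C[i] = A_i·Y / ‖A_i‖²`.
* `init_background` — `b` and `f` are the mean spatial/temporal projections
  of the non-negative residual `Y − AC`.

The pipeline default `max_wnd` is 6 px: the FWHM diameter of the default
simulated cell (2.355 σ at σ = 2.5), which also equals the generator's
minimum legal center separation (2 σ) rounded up — a larger suppression
window cannot seed both members of the closest legal cell pairs. When the
expected cell diameter of a dataset is larger, set `max_wnd` accordingly.

## Noise estimation

`sn(p)` is the standard deviation of the trace's brick-wall high-pass
component above `noise_freq`, divided by the square root of the fraction of
spectral weight in that band, so i.i.d. white noise of sd σ yields
`sn → σ` unbiasedly (tested at ±5% for n = 3,000). The same estimator
provides per-unit noise levels in the temporal update.

## Spatial update

Each pixel's non-negative lasso runs over the units whose footprint
support, dilated by a disk of diameter `dl_wnd` (default 10 ≈ cell
diameter — the maximum distance a footprint may grow per update), covers
that pixel; the background is an extra component active everywhere and
penalized identically. Solver: cyclic coordinate descent with non-negative
clipping, warm-started from the current footprints (so the per-pixel
objective never increases), vectorized over all pixels that share a unit
pattern, converged when the largest coefficient change drops below 1e-5 or
after 500 sweeps. `λ_p = sparse_penalty_spatial · sn(p) · √T` (default
multiplier 0.1); the √T factor keeps the ℓ1 term commensurate with a
squared error that grows linearly in T. Units whose footprints empty out
are dropped; `f` is then recomputed as the projection of `Y − AC` onto the
new `b` (clipped at 0 to respect the model's sign constraint).

## Temporal update

`project_traces` computes
`y_ra(i) = [A_i·(Y − bf) − Σ_{j≠i}(A_i·A_j)C(j,:)]/(A_i·A_i)` — the raw
per-unit trace with the background and overlapping neighbours removed.
Footprint-support Jaccard overlap (`jac_thres`, default 0.2) partitions
units into groups that could be solved concurrently; because every unit's
problem depends only on the fixed projected traces, the result is
order-invariant regardless of grouping (tested by permutation).

**AR estimation.** The Yule–Walker recursion `r_k = Σ_j γ_j r_{k−j}` is
solved in least squares over lags `p+1 … 20` of the raw autocovariance.
White noise contaminates only lag 0, so starting above lag p removes the
noise bias that motivates pre-smoothing in other implementations — and
avoids the smoother's own distortion of the short-lag autocovariance,
which in practice destabilized the AR(2) fit. Estimates with spectral
radius ≥ 1 are shrunk to 0.99; AR(2) fits with complex or negative roots
(oscillating kernel, so the impulse response `d` would go negative) fall
back to AR(1). The default order is 2 (calcium indicators at 30 fps have a
visible rise time); the simulator's kernel uses τ_rise 0.1 s, τ_decay 1 s.

**Deconvolution.** Substituting `c = conv(d, s)` turns the constrained
problem into non-negative least squares with a linear term in
`x = (s, b₀, c₀)`: all three constraints become `x ≥ 0` (valid because
`d ≥ 0`). It is solved by projected FISTA with monotone restart; `conv(d,·)`
and its adjoint are O(T) recursive filters, the step size comes from a
power iteration on the operator, and iteration stops at a relative
objective change ≤ 1e-12 (cap 5,000). The spike-domain optimum matches a
generic `trust-constr` solve of the original calcium-domain QP (constraints
`c ≥ 0`, `Gc ≥ 0`) to ≤ 1e-4 relative objective gap in the tests.
`λ = sparse_penalty_temporal · noise_sd · √T` (default multiplier 0.008).
The post-hoc scale `α = argmin_{α≥0}‖y_ra − α(c + b₀ + c₀d)‖²` multiplies
`c, s, b₀, c₀`. Units with all-zero fitted calcium are dropped; `b₀`/`c₀`
are reported in the unit table but excluded from `C`.

## Merging, curation, iteration order

Units sharing ≥ 1 footprint pixel with trace correlation >
`unit_merge_corr` (default 0.8) merge: footprint sum, trace mean, smallest
unit id (ids are never reused). Merging runs between CNMF iterations only,
never after the final temporal update — a merged trace is no longer a
model fit. The default schedule is two cycles of spatial-then-temporal
updates. `apply_unit_labels` applies curation labels (`keep`/`drop`/merge
group) with the same merge semantics without modifying its input.

## Cross-registration

Sessions align by translating a summary image (summed footprints by
default, or a max projection) to a chosen template session. Cells match
across a pair when their intensity-weighted footprint centroids are mutual
unique nearest neighbours within `param_dist` (default 5 px); exact
distance ties discard all tied candidates. Distances are only evaluated
inside 100-px moving windows with 50% overlap (pairs straddling a window
are caught by the overlap). Pairwise matches extend transitively; a
transitive group survives only if every pair of member sessions has the
direct pairwise match, otherwise the whole group dissolves into singletons
— conservative by design, so a single bad link cannot chain cells across
sessions.

## Simulator

`simulate_miniscope` builds, deterministically from `(params, seed)`:

1. Cell centers uniform with minimum separation 2 σ; footprints are
   isotropic Gaussians (σ = `cell_sigma`, default 2.5 px, truncated at
   4 σ), peak 1.
2. Spikes Bernoulli per frame at `spike_rate` (default 0.2 Hz — a
   realistically active hippocampal-style event rate that still yields
   ~20 events per cell in a 100 s desk-scale recording); calcium is the
   AR(2) filter of the spikes (τ 0.1 s/1.0 s). A burn-in of 10 τ_decay of
   pre-recording spiking puts the calcium process in its stationary regime,
   so the movie does not open on an unrealistically dark field; the filter
   state at frame 0 is stored (`truth_c_init`) so `truth_C` remains exactly
   the AR filtering of `truth_S` given that state.
3. Clean signal = `signal_level` × footprints ⊗ calcium, scaled so an
   isolated spike peaks at 25 gray levels at `signal_level` 1. With noise
   sd fixed at 1, `signal_level` is a direct peak-SNR dial.
4. Background: a low-spatial-frequency Gaussian random field (σ = FOV/4,
   amplitude 10) times a slow temporal modulation (±20%), plus a static
   radial vignetting profile (amplitude 40) and a constant offset.
5. Rigid motion: a Gaussian-smoothed integer random walk (per-step sd
   `motion_sigma`, default 0.1; smoothed over ~10 frames) clipped to ±4 px,
   applied with edge replication; ground truth is stored unshifted and
   referenced to frame 0.
6. Additive Gaussian noise (sd 1), clipping to [0, 255], and rounding to
   integers (8-bit sensor).

**What the simulator does not emulate:** non-rigid tissue deformation,
photobleaching, blood-vessel occlusions and anchored artifacts, spatially
correlated (shared) noise, skewed cell-size distributions, overlapping
out-of-focus cells, and dropped frames. Passing the simulated-data tests
therefore shows the pipeline recovers its own generative model class at
realistic SNR — it does not certify performance on any particular real
recording, where parameter choices (especially the cell-size-linked
windows and the noise cutoff) must be revisited.

## Problem sizes and reproducibility

The end-to-end checks run 30-cell, 128×128 px, 3,000-frame (100 s at
30 fps) datasets per signal level — the same generative family as a full
512×512/20,000-frame run at roughly 1/100 the pixel-time volume, chosen so
a complete multi-level sweep stays a desk-scale computation. At these
conditions the default pipeline reaches F1 ≥ 0.95 and median footprint
correlation ≥ 0.95 for signal levels ≥ 0.6, and the binned spike-signal
correlation rises monotonically from signal 0.2 to 2.0; the exact numbers
are recomputed by `tests/test_acceptance.py` and `scripts/acceptance.py`
rather than recorded here. Every random draw in the package flows from an
explicit integer seed; reruns with the same config and seed are
bit-identical (tested).

## Known limitations

* Rigid integer translation only; no subpixel, rotation, or non-rigid
  registration.
* A single rank-one background term; no ring/CNMF-E background model, so
  heavily structured out-of-focus fluorescence must be removed by the
  morphological step.
* The KS refinement assumes long traces; on very short recordings (tens of
  seconds) its power is limited and silent cells are undetectable in
  principle.
* AVI ingestion requires an imageio backend with a codec for the file; the
  portable interchange format is multi-page TIFF (and Zarr between
  stages).
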
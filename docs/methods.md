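# Methods

`cardiopiv` quantifies intracardiac hemodynamics from time-lapse movies of
tracer particles (fluorescently labeled red blood cells) in the beating
zebrafish heart, together with the standard ROI/area quantitation formulas
used around such experiments. This note documents the models, the defaults
and why they were chosen, the numerics, and what the synthetic benchmark
does and does not establish.

## Cardiac-phase alignment

A beating heart is imaged far faster than it beats, so the movie samples
many near-identical repetitions of one cycle. The period is estimated from
whole-image temporal self-similarity: every frame is mean-subtracted and
unit-normalized, the mean correlation ⟨corr(frame_k, frame_{k+L})⟩ is
computed for every lag L, and the period is taken as the smallest local
maximum within 0.05 of the best peak — smallest, because every multiple of
the true period peaks equally well. The integer peak is refined by
parabolic interpolation and then polished against the peak near m×period
(largest power-of-two multiple that fits in the lag range), which divides
the interpolation error by m; on the synthetic benchmark this recovers a
29.4-frame period to a few thousandths of a frame. A stack is declared
aperiodic when no lag rises at least 0.2 above the baseline (median)
similarity — a constant or pure-noise movie fails here by design.

Frames are then assigned phases k/T mod 1 and grouped into round(T) phase
bins by default, one frame pair per bin per cycle, which maximizes pooling
while keeping bins phase-homogeneous. Binning adds a small epsilon before
flooring because k/T·B lands exactly on bin boundaries for integer periods
and float rounding would otherwise scatter frames into neighboring bins.

## Ensemble correlation

Each velocity vector comes from matching a square interrogation window of
one frame against a search region of the next by zero-mean normalized
cross-correlation (ZNCC). Normalized correlation was chosen over plain
cross-correlation because its values are bounded in [−1, 1], which makes
averaging planes across windows of very different brightness meaningful.
The ensemble step averages the correlation *planes* (not the vectors) of
all window pairs sampling the same cardiac phase across all cycles, then
locates one peak in the averaged plane. At seeding densities where a third
of single-pair windows produce spurious peaks, pooling 17 cycles recovers
the true displacement in ≥ 99% of windows on the synthetic benchmark.

The implementation computes all windows of a frame pair in one batched FFT
pass (correlation numerators via `scipy.fft`, local means and variances via
integral images); this is necessary because the final pass evaluates
thousands of windows per pair and per-window library calls dominate the
runtime. Correctness is pinned by two independent routes in the tests: a
naive double loop over lags, and `skimage.feature.match_template`.

Frame pairing is consecutive (k, k+1), so Δt is one frame interval; the
pairing stride is not exposed as a tuning knob. Windows with zero intensity
variance are flagged degenerate and produce no vector.

## Multigrid refinement and peak location

Passes run coarse to fine, by default 48×48 px windows at 24-px spacing,
then 32×32/12, then 16×16/4 — the intermediate stage roughly halves the
window geometrically and limits the loss of matched particle pairs between
the endpoints. Each pass interpolates the previous validated field onto its
finer grid (bilinear, edge-clamped), rounds to integer pixel offsets, and
correlates only the residual displacement, so subpixel precision enters
once, at the peak fit. The search radius is 12 px in pass 1 (no predictor)
and 4 px thereafter. At the default calibration of 1.75 µm/px the final
4-px vector spacing corresponds to 7 µm.

The correlation peak is refined independently per axis by a three-point
Gaussian fit (log-parabola), falling back to a plain parabola when a
neighbor is non-positive; ties between equal maxima break toward the
smaller displacement magnitude, then lexicographically. Peaks on the search
border carry no subpixel fit and are flagged. A peak ratio (highest local
maximum over second highest) is stored per vector as a quality diagnostic.

Outliers are removed by the normalized-median test over the 8-neighborhood
(residual threshold 2.0, noise floor 0.1 px/frame). Flagging requires at
least six valid neighbors: with fewer, the neighborhood median is dominated
by one side of any local gradient and the test misfires — grid edges are
therefore replace-only. Flagged and unmeasured vectors are filled with the
component-wise median of their valid neighbors and tagged `interpolated`,
so downstream consumers can exclude them.

## Flow rates and the fundamental harmonic index

Flow through a drawn line from a to b is the discrete line integral
Q_raw = Σ v⃗·n⃗ dl with dl = 4 px by default, sampled as a left Riemann sum
over [0, |b−a|) — the far endpoint is excluded so each sample owns exactly
dl of section length; including it would double-weight the wall and bias a
full-lumen Poiseuille integral by ~2%. The headline Q divides by the
integrated length, giving the mean normal velocity in µm/s (the unit flow
traces are plotted in); the raw µm²/s integral is retained alongside. The
normal is the 90° CCW rotation of the a→b direction, flippable per section
so anterograde flow is positive. Velocities are interpolated bilinearly
onto section samples; a sample is excluded unless all four surrounding grid
nodes hold valid (measured) vectors, and a section failing on more than
half its samples errors out. Profiles average 3–5 sections per region and
any number of z-stacks with equal weight (fewer warns but proceeds).

The fundamental harmonic index summarizes one cycle of Q(t): with
c_m = (1/N) Σ Q_k e^(−2πikm/N), Q₀ = Re c₀ (signed mean flow),
Q₁ = 2|c₁| (so a pure cosine of amplitude A yields Q₁ = A), and
FHI = Q₁/|Q₀|. The absolute value in the denominator keeps FHI positive
for net-retrograde profiles; |Q₀| below 1e−9 of the waveform scale raises
an explicit error rather than returning an unstable ratio. FHI is invariant
under positive scaling and cyclic phase shifts, and — because the modeled
flow is separable, u(x, y, t) = w(t)·f(y) — also under the choice of which
part of the lumen a section spans. Non-uniformly phased profiles are
linearly resampled onto a uniform grid before the FFT.

## Synthetic movies

The generator emulates the acquisition the analysis was designed for:
512×128 px frames at 1.75 µm/px, 15 ms/frame, 500-odd frames covering ~17
cardiac cycles of ~30 frames (~2.2 Hz). Flow is a prescribed, exactly
periodic 2-D field in an axis-aligned channel lumen: plug, linear-shear or
parabolic profile times a cosine waveform. Two regimes bracket the biology:
*control* (oscillation amplitude below the mean; forward-only flow,
analytic FHI 0.5) and *ablated* (amplitude above the mean; flow reverses
for a third of the cycle, analytic FHI 2.0). Regime speeds are set so the
peak inter-frame displacement is ~4 px, one quarter of the final window —
the standard PIV capture-range rule; that corresponds to centerline speeds
of a few hundred µm/s, in the physiological range.

Tracers are ideal point followers of the flow (no inertia or interaction),
seeded only inside the lumen at 0.012 particles/µm² — about nine per final
16×16-px window, the classic seeding guideline; the sparse-seeding
benchmark drops this tenfold to make single-pair PIV fail on purpose.
Particles advect by fixed-step RK4 (step ≤ Δt/4) and recycle through a
margin band at the inflow edge so density stays stationary; the channel is
treated as extending axially beyond the imaged crop, so margin particles
keep their y-profile velocity rather than stalling at the crop boundary.
Rendering integrates an isotropic Gaussian spot (σ = diameter/2.355,
diameter 3 px) exactly over pixels via error functions, adds a constant
background and Gaussian read noise, and clips at zero. The default noise
gives particle-peak SNR ≈ 5.

A band of brighter, denser "tissue" particles outside the lumen follows a
small elliptical trajectory (±5 px in x, ±2 px in y) locked to the cardiac
period with zero net drift. It stands in for the myocardial wall: whole-
image temporal alignment works in vivo because heart structures move
periodically, whereas drifting tracers alone decorrelate from cycle to
cycle and leave nothing to align on. The elliptical (two-component) path
matters — a purely 1-D sinusoidal offset re-correlates at mirrored phases
and blurs the period peak. A side effect is realistic near-wall
contamination: windows overlapping the wall track tissue motion rather than
blood, which is why the bundled cross-sections sample the inner ~64% of the
lumen.

What the generator does *not* emulate: out-of-plane motion through the
confocal slice, deformable chamber walls and the moving lumen boundary,
Poisson shot noise, tracer size dispersity, and cycle-to-cycle variability
of the heartbeat. Passing the synthetic benchmarks therefore shows the
estimator chain is correct and well-conditioned under its own assumptions,
not that in-vivo recordings of arbitrary quality will yield equally small
errors.

Exact frame periodicity (frame k identical to frame k+P) holds by
construction for periodic flows with zero net drift per cycle — pure
oscillation — and is tested there; flows with net transport are periodic in
the *field* but not in the particle *configuration*, which is the honest
behaviour for ensemble PIV (the alternative, tiling one simulated cycle,
would inject a large spurious displacement into the cycle-boundary phase
bin).

## Quantitation formulas

All ROI arithmetic is exact pixel arithmetic, bit-stable across runs:
maximum intensity projection (pixelwise max over planes); background-
corrected mean fluorescence (ROI sum minus pooled-background mean times ROI
area, divided by ROI area — invariant to adding a constant to the image;
negative values kept, with a warning); fold increase over the mean of a
control pool; FAC = (EDA − ESA)/EDA × 100 with negative values warned, not
clipped; labeled-area coverage = |labeled ∩ region|/|region| × 100; and
ventricular area normalized to the mean control area. Polygons rasterize by
the even–odd rule on pixel centers; background ROIs are pooled pixelwise
rather than averaged per ROI (the choice is arbitrary; pooling weights
every background pixel equally).

## Problem sizes and runtime

The cycle-alignment and ensemble benchmarks run at full acquisition scale
(512×128 px, 500–511 frames, 17 cycles). The end-to-end FHI-recovery runs
use a 192×96-px field of view with 310 frames (10 cycles), which preserves
every pipeline stage — alignment, three multigrid passes, section
integration, FHI — while keeping a full run under a minute; the acceptance
script reports the FHI recovery errors these runs actually achieve. The
reproducibility checks use 150-frame (5-cycle) runs.

## Known limitations

- One global period is fitted per movie; hearts with beat-to-beat period
  drift would smear phase bins (per-cycle alignment is not implemented).
- The 2-D velocity field is per z-plane; no stereo/3-D reconstruction, no
  combination rule across planes beyond averaging flow profiles.
- Vectors within half a window of the wall blend blood and tissue motion;
  sections should avoid the outer ~20% of the lumen (the auto-generated
  demo sections do).
- The normalized-median validator cannot flag vectors with fewer than six
  valid neighbors (grid corners/edges); such vectors pass through
  unflagged and are only caught if their support was never measured.
- `flow_profile` assumes all stacks share one phase-bin count; stacks
  binned differently must be resampled by the caller.
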
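# Methods

This note documents the models behind `wormloop`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was open.

## Synthetic worm model

**Posture.** The worm is a ribbon around an analytic centerline. The
tangent angle along the body is

θ(s, t) = θ₀ + B · sin(2π k (s − φ(t))),

with s ∈ [0, 1] the arclength fraction from the anterior tip, bend
amplitude B = 0.55 rad and k = 1.3 wavelengths along the body — values in
the range reported for crawling adults. The phase φ advances at the
scheduled bend-wave speed v (body lengths/s); positive v drives the wave
anterior → posterior, i.e. forward crawling, and a reversal is simply a
negative-v interval. The centerline is the arclength integral of θ, so its
parameterisation is exactly uniform and its length exactly the nominal
body length (default 200 px at a nominal scale of a few µm/px; max body
width 20 px, i.e. a 10:1 aspect close to an adult's).

**Width profile.** Half-width along the body is `w_max · sin(π q(s))` with
the warped argument `q = s^α / (s^α + κ(1−s)^α)`, α ≈ 0.576 and κ chosen so
the maximum sits at 30 % of body length. The fractional exponent gives both
tips a steep (vertical-tangent) taper, so they rasterise as sharp, clearly
visible spikes instead of sub-pixel slivers — important both for realism
(worm tips are distinct under dark field) and because the segmenter finds
tips as boundary-curvature extrema. Any smooth tapered profile would serve;
this one was chosen once for those two properties.

**Rendering.** Frames are 8-bit, 256 × 256 by default: background 8 ± 2
(Gaussian), worm 200 — emulating the high contrast of dark-field
illumination. Stage tracking is emulated by pinning the centroid at the
frame centre; an optional per-frame drift moves it (residual stage error or
a deliberately translating target), and the generator raises — naming the
frame — if the worm would leave the frame. The self-touching "omega turn"
pose is rendered by stamping disks along a coiled centerline (a polygon
fill would even-odd-cancel the self-overlap), producing a silhouette with
an enclosed hole, which is exactly how the segmenter detects the failure.

**What is not emulated.** No optics (PSF, vignetting, shading), no
neurites or pharynx, no inhomogeneous body compression, no plate debris or
bubbles, no multi-worm scenes. Passing tests therefore demonstrate the
correctness of the geometry and analysis chain, not robustness to the full
variability of real dark-field movies.

## Segmentation and body coordinates

Frames are thresholded with Otsu (adequate for dark-field contrast); the
largest bright component is the worm. A silhouette whose filled area
differs from its raw area (i.e. one containing holes) is flagged
`ok=False, reason="self-intersection"` rather than raising — downstream
traces show these frames as gaps. Head and tail are the two boundary
points of locally extremal curvature on a smoothed contour (σ = 3 contour
samples), at least a quarter perimeter apart, each refined on the raw
subpixel contour as the sharpest corner within a ±12-sample window.

The centerline starts as midpoints of the two arclength-resampled side
arcs and is then refined (2 iterations) by intersecting each node's normal
ray with the subpixel contour and recentring between the two crossings.
This removes the systematic drift of paired-midpoints on body bends and
measures half-width perpendicular to the body axis; on synthetic bouts it
brings the centerline RMS error from ≈ 0.4 px to ≈ 0.16 px, with tip
errors ≈ 0.5 px. The final centerline has N = 100 uniformly spaced points.

Head identity is anchored on frame 0 by an annotation (ground truth in
simulation, a user click in practice) and propagated frame-to-frame by tip
proximity. The ventral side cannot be determined from a silhouette, so it
too is an input: a single pixel known to lie ventrally on frame 0 fixes
the sign, which then travels with head identity.

Body coordinates (s, w): s is the arclength fraction from the anterior
tip; w the fraction across the local width, 0 on the ventral edge, 1
opposite. The forward map displaces the centerline point along the local
normal; the inverse projects onto a 10×-oversampled midline. Round-trips
are exact to ≤ 1 px inside the body; at the tips the width degenerates and
w defaults to 0.5.

**Velocity.** The bend-wave phase velocity between consecutive frames is
the spatial shift that maximises the Pearson correlation of their
tangent-angle-vs-arclength profiles (lags up to 30 % of the body, refined
by parabolic interpolation), times the frame rate — in body lengths/s,
positive for forward locomotion. Frames adjacent to segmentation failures
yield NaN. Per-frame estimates carry pixel-level jitter (SD ≈ 0.1 BL/s at
30 fps), so the workflow layer smooths the series with a σ = 3-frame
(0.1 s) gap-aware Gaussian before any thresholding at zero; behavioural
timescales are an order of magnitude slower, so this does not distort
bouts.

## Targeting

The built-in regions, in fractions of body length/width measured from the
anterior tip and the ventral edge:

| region | center_s | length_frac | width_frac | center_w |
|--------|---------|-------------|------------|----------|
| AVA    | 0.10    | 0.10        | 0.90       | 0.50     |
| AVM    | 0.355   | 0.13        | 0.50       | 0.35     |
| ALM    | 0.425   | 0.13        | 0.50       | 0.65     |

"35 % from the lateral edge" for ALM is interpreted as 35 % from the edge
opposite the ventral one (center_w = 0.65 in ventral-origin coordinates);
the region can be constructed with any other center_w if a different
reading is wanted. The AVM and ALM s-intervals ([0.29, 0.42] and
[0.36, 0.49]) overlap by construction; the regions are implemented exactly
as specified and `check_separation` reports pairwise overlap areas and
minimum gaps (µm at the configured 0.62 µm/px) instead of silently
altering them.

Region masks are rasterised by tracing the region quad through the posture
(so the s-edges follow the body's curvature) and clipping to the worm
silhouette — no light falls outside the animal, and a full-body region
reproduces the silhouette exactly. On segmentation failure all
illumination is blanked (the conservative choice). The camera → DMD
calibration is a user-supplied invertible affine (or fitted from ≥ 3 point
pairs); masks are warped by nearest neighbour into the 1024 × 768 mirror
frame.

**Closed-loop latency** is modelled in whole frames: the mask at frame t
is computed from the segmentation of frame t − k. The default k = 2
corresponds to a ≈ 29 ms loop at a 75 fps behaviour camera (~13 ms per
frame). The simulator logs per-frame IoU of every active mask against the
ground-truth region rasterised from the true posture; the latency itself
is measured, as on the real instrument, by counting frames between a
step-translation of a static worm image and the corresponding translation
of the mask.

## Fluorescence quantification

The implementation follows the ratiometric recipe exactly: ROI = pixel
centres within 8 px of the tracked intensity maximum of the
Gaussian-smoothed (σ = 2 px — the locator σ is a free choice) red channel;
I = median of the ⌈0.4 N⌉ brightest ROI pixels; B = median over the
annulus with 20 < d ≤ 22 px (boundary inclusivity is a free choice,
fixed as ≤ for the disk and (inner, outer] for the annulus); R is defined
only where I_red − B_red > 0; R₀ is the mean of *raw* R over the
pre-stimulus window (≥ 15 s); ΔR/R₀ is smoothed last, with a σ = 5-frame
Gaussian truncated at 4σ and renormalised over valid samples, so gaps stay
gaps and constants pass unchanged. 2048² stacks are 2×2 mean-binned first
(mean, not sum, keeps the intensity scale). Frames whose annulus would be
clipped by the image edge become gaps, not errors.

Two invariances are the point of the design and are tested exactly: a
per-frame gain common to both channels cancels in R, and constant
per-channel gains scale R but leave ΔR/R₀ untouched.

One bias is worth stating: the σ = 5-frame smoothing rounds the sharp
onset of the transient by roughly (4A/τ₁)·σ_t/√(2π) (≈ 0.09 for A = 1,
τ₁ = 3 s at 30 fps). This is a property of the prescribed smoothing, not
of the quantification: the pre-smoothing ratio tracks the generating
transient to ≲ 0.002 on noiseless scenes, and the smoothed output matches
the identically smoothed truth to ≲ 5 × 10⁻⁴. Fitted τ₁ inherits a
percent-level bias from the same smoothing.

The GFP control path quantifies calcium-insensitive animals with the same
metric; the pooled mean and SD of their apparent ΔR/R₀ during reversals
give the threshold (mean + 1 SD) a real signal must exceed. With purely
common-mode gain jitter the ratio cancels it exactly — the apparent
activity of controls comes from additive camera noise (whose effect grows
slowly with jitter width, as E[1/g²]) and motion.

## Transient model and trial statistics

The piecewise RC-style transient (0 / saturating rise / exponential decay)
is implemented verbatim, including the A·e⁻⁴ (≈ 1.8 %) disagreement of the
two branches at t = τ₁ — the discontinuity is not smoothed. Fitting
minimises the sum of squared residuals from stimulus onset to trace end by
Nelder–Mead on (A, log τ₁, log(τ₂ − τ₁)), which enforces τ₂ > τ₁ > 0
without constraints. Initialisation (a free choice): A₀ = post-stimulus
maximum, τ₁₀ = time-to-max, and three deterministic starts with
(τ₂ − τ₁)₀ ∈ {τ₁₀, 2τ₁₀, 4τ₁₀}; convergence at simplex size 10⁻⁶ or 2000
iterations; best SSE wins. Noiseless traces are recovered to ≲ 10⁻⁵
relative error; at noise SD 0.05 the median per-parameter error is ≈ 1 %.

Classification is automated — reverser iff the minimum valid velocity in
[t₀, t₀ + 5 s] is negative (the window length is configurable; a
`manual_class` override preserves a manual-review workflow). Trials are
excluded for any negative velocity in the 15 s before the stimulus, or for
more than 2 distinct negative bouts (each ≥ 0.2 s) in the response window;
all three thresholds are parameters, as none is uniquely determined.
Mean velocity uses the fit-defined window [t₀, t₀ + τ₁] with inclusive
endpoints, valid samples only, NaN when empty. The amplitude–velocity
Pearson correlation pools reversers and non-reversers; reversal fractions
carry σ_f = √(f(1−f)/n).

## Problem sizes and determinism

Synthetic checks use 200-frame behaviour bouts (≈ 6.7 s at 30 fps),
900-frame fluorescence scenes (30 s at the two-channel camera's 30 fps),
50-trace Monte-Carlo fits and 40-trial cohorts — sizes at which every
estimate is comfortably resolvable while a full run of the suite and the
acceptance script completes in a few minutes on one CPU. The behaviour
camera of the real instrument runs at 75 fps; the simulations use 30 fps
throughout so behaviour and fluorescence share a clock, which changes no
algorithm (latency is expressed in frames). Every generator draws from a
single seeded NumPy Generator per scene; identical seeds give bit-identical
stacks and byte-identical TIFFs.

## Known limitations

- Head/tail and ventral identity require a frame-0 annotation; there is no
  appearance-based disambiguation.
- Segmentation handles one worm on a clean background; omega-turn frames
  are detected and skipped, not resolved.
- The latency model is whole-frame; sub-frame (exposure/readout phase)
  effects are not represented.
- No photobleaching correction and no sub-pixel channel registration
  beyond the configured affine/split.
- The velocity sign convention assumes the bend wave, not the centroid,
  defines locomotion direction; centroid-based speed is not computed.
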
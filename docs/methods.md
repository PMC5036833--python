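# Methods

This note documents the models, numerical choices, and known limitations of
the package, in the spirit of a methods supplement.

## Ground-truth flow model

The simulator represents a vessel cross-section as a rigid circular tube of
radius R carrying fully developed pulsatile laminar flow of a Newtonian
fluid (water: μ = 1.0·10⁻³ Pa·s, ρ = 1000 kg/m³). The flow waveform Q(t)
is a truncated Fourier series (default K = 8 harmonics); the default
carotid-like pulse is built from a systolic peak plus dicrotic shoulder
template, rescaled so the truncated series has mean 2.7 mL/s and peak
9.1 mL/s over a 1 s cycle — the calibration of the flow phantom this
pipeline emulates. The amplitude rescaling iterates after truncation so the
*reconstructed* peak, not the template's, hits the target; the default
pulse never reverses (minimum ≈ 0.66 mL/s).

Each harmonic drives a Womersley mode normalised to carry exactly its
prescribed flow amplitude; harmonic 0 contributes the Poiseuille profile.
At R = 2.8 mm and ν = 10⁻⁶ m²/s the Womersley number is α ≈ 7.0 at the
fundamental — strongly unsteady, with the annular near-wall velocity
overshoot that makes temporal effects on wall shear non-trivial. No-slip
holds exactly by construction. The modes are validated against an
independent finite-difference Crank–Nicolson solver of the axisymmetric
Stokes equation (time-stepped 10 periods, Fourier-analysed, matched through
its *numerically integrated* flow rate so no Bessel identity is shared);
agreement is ~0.02%, asserted at 1%.

The skewed ("ICA-like") profile is quasi-steady: parabolic along every ray
from an apex displaced from the lumen centre (default 0.8 mm toward the
bottom-right image quadrant), zero on the wall, rescaled each instant so
its area integral equals Q(t). With zero offset it reduces exactly to the
parabolic profile. It reproduces the *spatial* asymmetry of a bifurcation
branch (high shear on the apex side), not its secondary flows.

## Acquisition emulation

A rendered cine series is the analytic through-plane field box-averaged
over an 8× supersampled grid per pixel (partial volume) and over 9 midpoint
time samples per frame window (temporal binning; the 9-point midpoint rule
is within ~0.5% of a dense quadrature for this waveform's harmonics).
Retrospective gating tiles the full cycle with round(T/Δt) frames — every
protocol frame duration is 1000/k ms, so the tiling is exact; a prospective
mode covering a configurable cycle fraction exists, with OSI then computed
over the available frames under a logged warning. The sweep uses
retrospective tiling for all 30 settings so cycle-averaged quantities are
directly comparable across frame durations.

Velocity noise is zero-mean Gaussian, σ_v = √2·venc/(π·SNR) per component
(the standard PC-MRI velocity-noise relation), default venc 100 cm/s and
SNR 20 — the SNR is a configuration knob, not a measured property. An
optional first-order phase-offset error adds a plane a·x + b·y + c per
component; `phase_offset_correct` removes it by least squares over a static
background mask (exact on noise-free data). Phase wrapping is not
simulated: all velocities stay far below venc. In-plane velocity components
are zero before noise (purely axial flow).

Coordinates project-wide: image frame, x right, y down, origin at the grid
corner, pixel centres at (i+0.5)·spacing; mm, ms, m/s, Pa. The field of
view is 12.8 mm square with the vessel axis at its centre, which leaves a
static background annulus ≥ 3.5 mm wide at every protocol resolution.

## Lumen segmentation

Initialisation clusters pixels into fluid/static with k-means (k = 2) on
two temporal statistics: the magnitude of the cycle-mean through-plane
velocity (averaging before rectification suppresses the noise floor by
√n_frames) and the temporal standard deviation. Both features get a
median-based noise-floor subtraction before standardisation — the image is
background-dominated, so the median estimates the rectified-noise floor;
without it the floor biases the cluster threshold upward and the mask
systematically loses the low-velocity rim. Cluster seeds are the 10th/90th
feature percentiles, so segmentation is deterministic. The fluid cluster is
reduced to its largest connected component and hole-filled. On a parabolic
velocity disk, 2-means intrinsically under-segments (it thresholds near
half the fluid-cluster mean velocity); the snake stage corrects this.

Refinement is a classic closed snake in physical (mm) coordinates:
semi-implicit internal update (elasticity 0.05, stiffness 0.1, periodic
pentadiagonal system solved by a precomputed inverse), explicit external
force (weight 1.0, step 0.1), stopping when the maximum vertex displacement
falls below 10⁻³ mm or after 500 iterations; 64 vertices, resampled to
uniform arc length every 15 iterations to prevent bunching.

The external force is the gradient of an edge-strength functional of the
temporal-mean speed image: E = |∇((I_s − floor)^γ)| with I_s the
Gaussian-smoothed (σ = 0.75 px) magnitude of the cycle-mean velocity and
floor = 3·median(I_s). The image is represented as a bicubic spline so E
and its gradient are evaluated in continuous coordinates rather than
quantised to the pixel grid. The exponent γ is scale-adaptive: when the
strongest image gradient is consistent with an unresolved step at the blur
scale (sharpness statistic ≈ 0.34 for a true step, ≤ 0.29 for resolved
profiles; threshold 0.32), γ = 1 and the ridge of E sits on the step
inflection — correct for high-contrast edges. Otherwise γ = 1/3: a
parabolic profile vanishes at the wall with finite slope, so the gradient
ridge of the raw image sits well inside the lumen (the profile's shear
keeps growing toward the wall and blur shifts the asymmetric peak inward);
the compressed profile instead has unbounded slope at its zero crossing,
pinning the ridge at the wall. A per-iteration displacement cap of half a
pixel, annealed after iteration 50, damps the overshoot oscillation around
the sharp ridge so the displacement criterion can actually trigger.

On noise-free synthetic disks the segmented area converges to πR² as the
grid is refined (errors 0.85 → 0.39 → 0.02 mm² at 0.5/0.2/0.1 mm); at the
finest protocol setting with SNR 20 the area is within ~2% of the true
24.6 mm². At 0.8–1.0 mm spacing the heavily blurred edge localises less
sharply and the contour drifts slightly outward of the true wall; flow is
then nearly conserved while WSS is strongly under-read — see Limitations.

The "best segmentation" is the contour from the finest-resolution
rendering, re-applied to any other grid by rasterising the polygon with
the pixel-centre-in-polygon rule (matching the flow summation convention).
Rasterisation quantisation at 1.0 mm can reach a few pixel-areas for
unluckily aligned circles.

## Flow, WSS, OSI

Flow is Q(t) = Σ_mask v_z·ΔA (m/s·mm² = mL/s identically); the mean is the
frame average, the peak the maximum frame value with no interpolation.
Retrospective binning preserves the cycle mean essentially exactly while
flattening the peak — hence peak flow degrades with frame duration but
mean flow does not.

WSS: inward normals from central-difference tangents oriented toward the
centroid; velocities bilinearly interpolated at d₁, d₂ along each normal
(defaults 1.5/3.0 mm as in the emulated protocol — note these reach past
the centreline for R ≈ 2.8 mm, a faithful but aggressive choice; both are
configurable and the oracle tests use R/4, R/2); wall velocity pinned to
zero; per component, the derivative at 0 of the interpolating spline
through (0,0),(d₁,v₁),(d₂,v₂) — three points admit exactly one quadratic,
equal to the not-a-knot cubic (cross-checked against scipy in tests).
WSS = μ·WSR with the component along the inward normal projected out;
cycle averaging is mean-of-magnitudes per wall point, then the
circumferential mean (the vector time-mean is what OSI's numerator
captures instead). OSI uses the full 3-component tangential vectors;
a wall point with identically zero WSS maps to OSI 0 (no direction change
observable); tiny negative values from floating-point cancellation are
clipped into [0, 0.5].

Regional statistics partition wall vertices into image-frame quadrants
about the contour centroid (top-left/top-right/bottom-left/bottom-right);
vertices exactly on a quadrant boundary go to the counterclockwise-prior
sector (as displayed), with sub-nm centroid offsets snapped to zero so the
tie rule is reproducible. Extreme-sector ties resolve to the lowest sector
index. Concordance counts measurements whose highest/lowest sector matches
a reference.

## Resolution sweep and regression

The sweep renders, segments and quantifies each of the 30 protocol
(spacing, frame duration) pairs; per-measurement noise seeds are spawned
from one master seed, so runs are bit-reproducible. Stage failures skip
the record with a logged diagnostic. Regressions are single-predictor OLS
(statsmodels) of each response on spacing (mm) or frame duration (ms);
slopes are normalised by the response maximum over the record set and
reported in %/mm or %/100 ms; two-sided slope p-values at α = 0.05, no
multiple-testing correction. A constant response reports slope 0, r² 0.

On noise-free sweeps the pipeline reproduces the expected directions: peak
flow falls with frame duration (~−30%/100 ms, r² ≈ 0.8), mean WSS falls
with spacing (~−20%/mm, r² ≈ 0.9) and is frame-duration-insensitive
(< 3% spread within a spacing group), and mean flow is independent of
frame duration (|slope| < 0.1%/100 ms, r² ≈ 0.00).

## What the generator does and does not emulate

Emulated: partial volume, temporal binning, venc-scaled Gaussian noise,
planar phase offsets, retrospective/prospective gating, circular and
skewed profiles at the protocol's 30 spatiotemporal resolutions. Not
emulated: k-space acquisition and reconstruction (point-spread sidelobes,
Gibbs ringing), signal-magnitude weighting of intravoxel phase (a boundary
voxel here averages velocity with zero-velocity fluid fraction weights,
not spin-density/T1 weights), wall motion and compliance, secondary and
through-plane-varying flows, and phase wrapping. Passing tests therefore
demonstrate the measurement chain's behaviour under idealised velocity
images, not under full MR physics; in particular the segmentation contrast
differs from real magnitude images, and conclusions about segmentation-
driven flow bias at coarse grids transfer only qualitatively.

One consequence worth stating explicitly: with this generator the
per-measurement contours at coarse grids capture the rim flow (mild
flow-vs-spacing slope), while re-applying the fixed best contour loses
3–4% of rim flow at 0.8–1.0 mm through the pixel-centre rasterisation of
box-averaged boundary pixels — so the fixed-contour mode has a *built-in*
negative flow-vs-spacing slope of ~−5%/mm. On real data the ordering is
reversed (per-measurement segmentation degrades faster than
rasterisation); the package reports both modes so the comparison itself is
reproducible.

## Numerical choices

- Womersley Bessel modes tabulated on 4097 radial nodes and linearly
  interpolated when evaluating > 4096 points; max table error is far below
  the 1% oracle tolerance.
- Skewed-profile normalisation uses the closed-form radial integral and a
  spectrally accurate periodic trapezoid rule in angle (8192 nodes).
- Bilinear interpolation for velocity sampling (reproduces affine fields
  exactly); bicubic spline only inside the snake's edge functional.
- Degenerate inputs raise typed errors (`ConfigurationError`,
  `OutOfDomainError`, `SegmentationError`, `FormatError`) rather than
  returning sentinel values.
- Problem sizes: the default test suite and the acceptance script run the
  full 30-measurement sweeps (a sweep takes a few seconds; the whole suite
  under a minute on one CPU), so no scaled-down surrogate grids are used.

## Known limitations

- The 1.5/3.0 mm sampling offsets exceed the lumen radius direction-wise;
  for this geometry the second sample lands beyond the centreline. The
  estimates remain well-behaved (the quadratic is fitted, not
  extrapolated), but WSS magnitudes are smoother than a near-wall-only
  estimator would give. Use smaller offsets for small vessels.
- OSI of the default non-reversing waveform is zero up to noise; OSI
  values in noisy sweeps are noise-driven, which mirrors the way low-OSI
  vessels behave in practice but means OSI regressions on synthetic data
  have no deterministic ground truth.
- The skewed profile is quasi-steady; its wall shear has no independent
  phase lag across the circumference.
- Segmentation quality degrades qualitatively, not quantitatively, like
  real PC-MRI segmentations at coarse resolution (see above).
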
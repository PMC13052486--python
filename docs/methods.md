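# Methods

## The measurement

Spatial speckle contrast is computed per pixel as K = σs/⟨I⟩ over a sliding
window (default 5×5), with the *sample* standard deviation (divisor n−1,
n = 25).  Which divisor an acquisition system uses is rarely reported; the
choice is a fixed √(25/24) ≈ 1.02 factor, immaterial for group comparisons,
and is recorded in the map metadata so the brute-force oracle and the
vectorized map always agree.  The windowed second moment is computed on
globally mean-centered data to avoid catastrophic cancellation on
high-offset integer counts; variance below 1e−12 of the local second moment
is snapped to exactly zero so constant windows report K = 0.

Border policy: no padding — K is undefined (NaN) wherever the full window
does not fit (a 2-pixel border for 5×5) and in windows with non-positive
mean.  Padded borders would bias ROI means, and ROIs of interest are
interior.  Undefined pixels are excluded from all ROI and whole-frame
statistics.  Contrast is scale-invariant, so integer camera counts are used
without normalization.

ROI traces take each frame's ROI-mean K as one observation over the first
30 frames (the standard trial length at 40 frames/s with 5 ms exposure).
Group differences use a two-sample two-sided Student's t-test, pooled
variance by default ("Student" form), with a Welch option because trace
variances plainly differ between perfused and static conditions.  Frames
are treated as exchangeable despite temporal autocorrelation; every
comparison carries this caveat in its metadata.  The classifier labels the
lower-contrast group "perfused-like" when p < α (default 0.05) and
"indeterminate" otherwise; it never asserts an absolute flow speed, since K
is a qualitative flow indicator.

## The simulator

The detected field is a band-limited circular complex Gaussian random
field: white complex noise in the frequency domain restricted to a circular
pupil of cutoff 1.22/d cycles/pixel, where d is the requested speckle
diameter in pixels.  This puts the first zero of the field autocorrelation
at d/2, matching the Airy convention of the diffraction formula
ρ = 2.44·λ·(1+M)·f/# (full first-zero diameter).  The test suite verifies
the realized autocovariance width to within 20%.

Temporal decorrelation uses a per-pixel order-1 autoregressive update

    E(t+δt) = a·E(t) + √(1−a²)·ξ,   a = exp(−δt/τc),

with ξ a fresh band-limited unit-variance field, realizing
g1(τ) = exp(−τ/τc) exactly on the sub-step grid (Lorentzian line shape —
the standard single-scattering model for flow).  A camera frame averages
|E|² over N sub-steps spanning the exposure T; the field then advances
through the inter-frame dead time in one exact AR step.  N is chosen so
δt ≤ min(τc)/10 with a floor of 20; an explicit smaller N is refused with
the required count, which bounds the integration bias well below test
tolerances (measured closed-form agreement is ≲1%).

For this model the exposure-averaged contrast is

    K²(T, τc, β) = β · (e^(−2x) − 1 + 2x) / (2x²),   x = T/τc,

the triangular-weighted integral (2/T)∫₀ᵀ(1−τ/T)|g1(τ)|²dτ.  This is the
form the package exposes as `speckle_contrast_model` and the tests use as
oracle.  The older short-hand K² = β(τc/2T)(1−e^(−2T/τc)) omits the
triangular weighting and disagrees with any true exposure integral by ~40%
in K for τc ≲ 0.1·T, so it is not used: a time-integrating simulator can
only be self-consistent with the triangular form.

**Coherence factor β** (default 1, fully polarized detection) models the
fraction of detected light that interferes; different cross-polarizer
extinction ratios between instruments motivate exposing it.  Partial
coherence is realized as coherent speckle plus a constant incoherent
background at the level that makes the global contrast exactly √β for
fully developed speckle.

**Static scatterers** use τc = ∞ (the IEEE infinity as the reserved
sentinel: exp(−δt/∞) = 1 exactly, no overflow, no innovation drawn).  A
static region keeps a frozen pattern across frames — so its per-frame trace
has zero variance, which is the correct frozen-speckle limit, not an
artifact.

**Detector model.**  By default the field is sampled at pixel centers and
intensities are floats with no shot noise (no noise model is specified for
the reference systems; adding Poisson noise is left to the caller on the
written stacks).  `generate_static_speckle(..., oversample=q)` synthesizes
the field on a q-times finer grid and integrates intensity over each pixel
area; this reproduces the contrast loss of spatially undersampled speckle
(< 2 px per speckle) that explains why systems with small speckle-to-pixel
ratios read out lower K.  Point sampling is accurate for the adequately
sampled (≥ 4 px/speckle) grids used everywhere else.

**Hand motion** is a rigid in-plane translation accumulated uniformly
across the exposure, applied as an exact Fourier phase shift of the
periodic synthesized field (sub-pixel, non-negative by construction,
consumes no random numbers — so uncorrupted frames are bit-identical with
and without events).  Rotation and tilt are deliberately out of scope.
`inject_motion` re-renders at field level when the stack carries its
simulation spec; for stacks loaded from disk it falls back to an
exposure-resolved intensity-domain blur, exact for static speckle and
approximate otherwise.  The blur magnitude is validated against an
independent 1-D uniform-motion oracle built from the measured
autocovariance of the clean frame.

**Flow phantom.**  `make_flow_phantom` builds a static scattering block
with one horizontal channel of configurable width and τc (∞ for no flow),
emulating a single-channel flow phantom.  The mapping from pump speed
(mm/s) to τc is deliberately not modeled — no calibration exists — so flow
conditions are parameterized by τc directly; "slow" and "fast" in the tests
(1.0 and 0.1 ms at T = 5 ms) are chosen to bracket the contrast range
observed on real channel phantoms (K roughly 0.1–0.4 against a ~0.9 static
background).  Channel/background ROIs are eroded by two speckle diameters
plus the window border so neither straddles the boundary blur.

## Motion-rejection study conditions

The frame-rejection threshold (0.025 on the whole-frame mean K, strictly
below rejects, equality keeps) is applied to the same 5×5 map used for
analysis, and to the whole frame rather than the ROI, since global motion
is a whole-frame effect.  The filter is intended for handheld acquisitions;
it is off by default and enabled per run.

The simulated rejection scenario is a 30-frame "perfused tissue"
acquisition at 5 ms/40 Hz with β = 0.25 and τc = 0.125 ms — chosen from the
closed form so the clean whole-frame mean K ≈ 0.075, the regime of real
handheld perfused-tissue recordings — with one frame corrupted by an
800-pixel translational jerk.  Corrupted-frame contrast is set by β and the
displacement alone (the jerk out-runs the temporal decorrelation), landing
at K ≈ 0.022; displacements of tens of pixels do *not* drive a perfused
scene below 0.025, because contrast already blurred by fast temporal
decorrelation loses little more until the motion crosses a speckle faster
than τc.  The filter then rejects exactly the corrupted frame: 1/30 ≈ 3.3%,
inside the "under 5% removed" operating regime.  Grid sizes here
(128×192) and elsewhere (96²–256²) keep full runs to seconds per stack
while leaving thousands of independent speckles per frame.

## Numerical and design notes

* Determinism: all randomness flows from one `numpy` PCG64 generator seeded
  by the spec; identical specs give bit-identical stacks, and identical
  pipeline configs give byte-identical CSV/JSON outputs.
* The global contrast estimator (std/mean, ddof = 1) is used for
  uniform-field validation; windowed K is biased slightly low when the
  window holds few independent speckles (real LSCI behavior), which is why
  closed-form checks use the global statistic.
* Zero-variance traces (frozen static speckle) make the pooled t-test
  degenerate only when *both* groups are constant; that case returns t = 0,
  p = 1.
* Rendering clips K to [0, 0.4] by default and maps linearly onto the jet
  colormap (blue → red); undefined pixels render neutral gray.  The range
  and colormap are configurable.
* Nyquist criterion for sampling adequacy: ≥ 2 pixels per speckle diameter,
  the standard minimum; the ratio itself is always reported so callers can
  apply stricter cutoffs.
* Speckle-size formula accepts M = 0 (diffraction at unit conjugate) and
  requires all other arguments positive.

## What the simulator does and does not show

Passing tests demonstrate that the analysis chain is correct for the model:
Gaussian speckle statistics, single exponential g1 per pixel, rigid global
motion, no detector noise, no multiple-layer or depth effects.  Real tissue
adds static scattering layers over moving blood (mixed dynamics), shot and
read noise, spatially varying illumination, and non-rigid motion — none of
which are claimed here.  Contrast values from the simulator are therefore
comparable across its own conditions (ordering, separation, significance),
not calibrated predictions of any specific instrument's readout.
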
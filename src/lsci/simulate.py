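"""Physics-based dynamic-speckle video synthesis.

The simulator produces grayscale speckle video with a *known* ground-truth
decorrelation structure so that every downstream stage (contrast mapping,
motion rejection, group statistics) can be validated without access to raw
clinical recordings.

Model
-----
The optical field on the detector is a circular complex Gaussian random field
whose spatial band limit sets the speckle size: white complex noise is drawn
in the frequency domain, restricted to a circular pupil of cutoff
``f_c = 1.22 / speckle_size_px`` cycles/pixel, and inverse-transformed.  The
first zero of the resulting field autocorrelation sits at
``speckle_size_px / 2``, so ``speckle_size_px`` is the full (Airy-like)
speckle diameter — the same convention as the diffraction formula
``rho = 2.44 * lambda * (1 + M) * f/#``.

Scatterer motion is modeled per pixel by a correlation time ``tau_c``: the
field evolves as an order-1 autoregressive process,

    E(t + dt) = a * E(t) + sqrt(1 - a^2) * xi,   a = exp(-dt / tau_c),

with ``xi`` a fresh band-limited unit-variance field.  This realizes a field
autocorrelation ``g1(tau) = exp(-tau / tau_c)`` exactly at the sub-step grid.
A camera frame is the exposure-time average of the instantaneous intensity
``|E|^2`` over ``n_substeps`` sub-steps spanning the exposure T; regions with
``tau_c`` comparable to or below T are blurred within the frame and show
reduced spatial contrast, while static regions (``tau_c = inf``) retain the
full contrast of frozen speckle.

For this model the exposure-averaged contrast has the closed form

    K^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c,

(the triangular-weighted integral of ``|g1|^2`` over the exposure), which
:func:`speckle_contrast_model` evaluates and the test suite uses as the
quantitative oracle.  ``beta`` is the coherence factor: the fraction of
detected light that interferes, which caps the maximum contrast at
``sqrt(beta)``.  Partial coherence is realized as coherent speckle riding on
a constant incoherent background.

Global hand motion is a rigid in-plane translation accumulated uniformly
across the exposure sub-steps, applied as an exact Fourier phase shift of the
(periodic) synthesized field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from lsci.core import InvalidInputError, RoiMask, SpeckleFrame, SpeckleStack, StackMetadata

#: Sentinel correlation time for static scatterers (frozen speckle).  The IEEE
#: infinity gives the exact AR coefficient exp(-dt/inf) == 1 with no overflow.
STATIC_TAU_C = np.inf


class SubstepError(InvalidInputError):
    """Exposure sub-stepping too coarse to resolve the fastest dynamics."""

    def __init__(self, requested: int, required: int):
        self.requested = requested
        self.required = required
        super().__init__(
            f"{requested} exposure sub-steps cannot resolve the smallest tau_c; "
            f"at least {required} are required (dt <= min(tau_c)/10 and >= 20 steps)"
        )


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-chain parameters of the speckle camera.

    Parameters
    ----------
    wavelength_nm : laser wavelength (785 nm near-infrared by default).
    magnification : system magnification M (dimensionless).
    f_number : working f-number f/# of the imaging optics.
    pixel_pitch_um : detector pixel size.
    exposure_ms : camera integration time T.
    coherence_factor : beta in (0, 1], fraction of detected light that is
        coherent speckle; contrast saturates at sqrt(beta).
    """

    wavelength_nm: float = 785.0
    magnification: float = 1.0
    f_number: float = 2.7
    pixel_pitch_um: float = 3.0
    exposure_ms: float = 5.0
    coherence_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "magnification", "f_number", "pixel_pitch_um", "exposure_ms"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.coherence_factor <= 1.0:
            raise InvalidInputError(
                f"coherence_factor must be in (0, 1], got {self.coherence_factor}"
            )


@dataclass
class DynamicsField:
    """Per-pixel correlation-time map in milliseconds.

    ``tau_c_map`` entries are positive decorrelation times; ``STATIC_TAU_C``
    (infinity) marks static scatterers.  Shorter tau_c means faster scatterer
    motion (e.g. blood flow) and lower measured contrast.
    """

    tau_c_map: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.tau_c_map = np.asarray(self.tau_c_map, dtype=float)
        if self.tau_c_map.ndim != 2:
            raise InvalidInputError("tau_c_map must be 2-D")
        if np.any(self.tau_c_map <= 0) or np.any(np.isnan(self.tau_c_map)):
            raise InvalidInputError("all tau_c values must be positive (inf = static)")

    @property
    def min_finite_tau_c(self) -> float:
        """Smallest finite tau_c, or inf for an all-static field."""
        finite = self.tau_c_map[np.isfinite(self.tau_c_map)]
        return float(finite.min()) if finite.size else np.inf


@dataclass(frozen=True)
class MotionEvent:
    """Rigid whole-field translation accumulated during one frame's exposure.

    ``displacement_px_per_exposure`` is the (row, col) displacement in pixels
    reached at the end of the exposure; sub-steps see a uniform ramp from 0.
    """

    frame_index: int
    displacement_px_per_exposure: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.displacement_px_per_exposure) != 2:
            raise InvalidInputError("displacement must be a (row, col) 2-vector")

    @property
    def magnitude(self) -> float:
        dr, dc = self.displacement_px_per_exposure
        return math.hypot(dr, dc)


@dataclass
class SimSpec:
    """Full specification of one simulated acquisition.

    A fixed ``seed`` makes the rendered stack bit-reproducible.
    """

    grid_shape: tuple[int, int]
    speckle_size_px: float
    optics: OpticalConfig
    dynamics: DynamicsField
    motion_events: list[MotionEvent] = field(default_factory=list)
    n_frames: int = 30
    seed: int = 0
    frame_rate_hz: float = 40.0

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise InvalidInputError(f"grid dimensions must be positive, got {self.grid_shape}")
        if self.speckle_size_px <= 0:
            raise InvalidInputError(f"speckle_size_px must be > 0, got {self.speckle_size_px}")
        if self.n_frames < 1:
            raise InvalidInputError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.dynamics.tau_c_map.shape != tuple(self.grid_shape):
            raise InvalidInputError(
                f"tau_c_map shape {self.dynamics.tau_c_map.shape} does not match "
                f"grid {self.grid_shape}"
            )
        if 1.0 / self.frame_rate_hz < self.optics.exposure_ms / 1000.0:
            raise InvalidInputError("frame period shorter than exposure time")
        for ev in self.motion_events:
            if not 0 <= ev.frame_index < self.n_frames:
                raise InvalidInputError(
                    f"motion event frame index {ev.frame_index} outside stack "
                    f"of {self.n_frames} frames"
                )

    def required_substeps(self) -> int:
        """Sub-steps needed so dt <= min(tau_c)/10, with a floor of 20."""
        tau_min = self.dynamics.min_finite_tau_c
        if np.isinf(tau_min):
            return 20
        return max(20, math.ceil(10.0 * self.optics.exposure_ms / tau_min))


# ---------------------------------------------------------------------------
# field synthesis


def _pupil_mask(shape: tuple[int, int], speckle_size_px: float) -> np.ndarray:
    """Boolean circular low-pass mask on the FFT frequency grid.

    Cutoff 1.22/speckle_size cycles/px puts the first zero of the field
    autocorrelation at speckle_size/2 (Airy convention: size = full diameter).
    """
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    cutoff = 1.22 / speckle_size_px
    return fr * fr + fc * fc <= cutoff * cutoff


def _fresh_field(rng: np.random.Generator, mask: np.ndarray, scale: float) -> np.ndarray:
    """One band-limited circular complex Gaussian field with E[|E|^2] = 1."""
    shape = mask.shape
    spec = np.zeros(shape, dtype=np.complex128)
    n = int(mask.sum())
    noise = rng.standard_normal((n, 2))
    spec[mask] = noise[:, 0] + 1j * noise[:, 1]
    return np.fft.ifft2(spec) * scale


def _field_scale(mask: np.ndarray) -> float:
    # ifft2 of iid CN(0,2) on the mask support has pixel variance
    # 2*sum(mask)/size^2; rescale to unit mean intensity.
    size = mask.size
    return size / math.sqrt(2.0 * mask.sum())


def _intensity(field: np.ndarray, coherence_factor: float) -> np.ndarray:
    """Instantaneous detected intensity with mean 1.

    Partial coherence (beta < 1) adds a constant incoherent background at the
    level that yields global contrast sqrt(beta) for fully developed speckle.
    """
    i_coh = np.abs(field) ** 2
    b = 1.0 / math.sqrt(coherence_factor) - 1.0
    return (i_coh + b) / (1.0 + b)


def _shift_field(field: np.ndarray, shift_rc: tuple[float, float]) -> np.ndarray:
    """Exact (periodic) sub-pixel translation via a Fourier phase ramp."""
    if shift_rc[0] == 0.0 and shift_rc[1] == 0.0:
        return field
    rows, cols = field.shape
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    phase = np.exp(-2j * np.pi * (fr * shift_rc[0] + fc * shift_rc[1]))
    return np.fft.ifft2(np.fft.fft2(field) * phase)


# ---------------------------------------------------------------------------
# public operations


def generate_static_speckle(
    grid_shape: tuple[int, int],
    speckle_size_px: float,
    coherence_factor: float = 1.0,
    seed: int = 0,
    oversample: int = 1,
) -> SpeckleFrame:
    """Generate one fully developed static speckle frame.

    The frame has unit mean intensity; for ``coherence_factor = 1`` and
    adequately sampled speckle (>= 2 px per speckle) its global contrast
    (std/mean) is ~1, the fully-developed-speckle limit.

    Parameters
    ----------
    grid_shape : (rows, cols) of the frame.
    speckle_size_px : target speckle diameter in pixels; values below 1 are
        allowed but produce undersampled speckle with reduced contrast (use
        ``oversample`` > 1 to model the pixel-integration loss).
    coherence_factor : beta in (0, 1]; global contrast ~ sqrt(beta).
    seed : RNG seed; identical arguments give bit-identical frames.
    oversample : detector-model fidelity.  1 (default) samples the field at
        pixel centers — accurate for adequately sampled speckle, where
        pixel-area integration is a small correction.  q > 1 synthesizes the
        field on a q-times finer grid and integrates the intensity over each
        pixel's area, reproducing the contrast loss of sub-pixel speckle.
    """
    r, c = grid_shape
    if r <= 0 or c <= 0:
        raise InvalidInputError(f"grid dimensions must be positive, got {grid_shape}")
    if speckle_size_px <= 0:
        raise InvalidInputError(f"speckle_size_px must be > 0, got {speckle_size_px}")
    if not 0.0 < coherence_factor <= 1.0:
        raise InvalidInputError(f"coherence_factor must be in (0, 1], got {coherence_factor}")
    if oversample < 1 or int(oversample) != oversample:
        raise InvalidInputError(f"oversample must be a positive integer, got {oversample}")
    q = int(oversample)
    rng = np.random.default_rng(seed)
    mask = _pupil_mask((r * q, c * q), speckle_size_px * q)
    field_ = _fresh_field(rng, mask, _field_scale(mask))
    i_fine = np.abs(field_) ** 2
    if q > 1:  # integrate intensity over each pixel's area
        i_fine = i_fine.reshape(r, q, c, q).mean(axis=(1, 3))
    b = 1.0 / math.sqrt(coherence_factor) - 1.0
    return SpeckleFrame(pixels=(i_fine + b) / (1.0 + b), frame_index=0)


def render_sequence(spec: SimSpec, n_substeps: int | None = None) -> SpeckleStack:
    """Render a dynamic-speckle stack by exposure-time integration.

    Each frame averages the instantaneous intensity over ``n_substeps``
    sub-steps spanning the exposure; the complex field advances between
    sub-steps by the per-pixel AR(1) update realizing g1(tau) = exp(-tau/tau_c)
    and continues to evolve (in a single exact step) through the dead time
    between frames.  Motion events translate the field by a uniform ramp
    across their frame's exposure.

    Parameters
    ----------
    spec : the acquisition specification.
    n_substeps : sub-steps per exposure.  ``None`` picks the smallest count
        satisfying dt <= min(tau_c)/10 (floor 20); an explicit value below
        that requirement raises :class:`SubstepError` reporting the required
        count.
    """
    required = spec.required_substeps()
    if n_substeps is None:
        n_substeps = required
    elif n_substeps < required:
        raise SubstepError(n_substeps, required)

    rng = np.random.default_rng(spec.seed)
    mask = _pupil_mask(spec.grid_shape, spec.speckle_size_px)
    scale = _field_scale(mask)
    beta = spec.optics.coherence_factor
    t_exp = spec.optics.exposure_ms
    dt = t_exp / n_substeps
    tau = spec.dynamics.tau_c_map

    # AR coefficients; static pixels (tau = inf) get a = 1 and no innovation.
    a_sub = np.exp(-dt / tau)
    gap_ms = 1000.0 / spec.frame_rate_hz - t_exp
    a_gap = np.exp(-gap_ms / tau) if gap_ms > 0 else np.ones_like(tau)
    innov_sub = np.sqrt(np.clip(1.0 - a_sub * a_sub, 0.0, None))
    innov_gap = np.sqrt(np.clip(1.0 - a_gap * a_gap, 0.0, None))
    fully_static = np.isinf(spec.dynamics.min_finite_tau_c)

    events = {ev.frame_index: ev for ev in spec.motion_events}

    field_ = _fresh_field(rng, mask, scale)
    frames = np.empty((spec.n_frames, *spec.grid_shape), dtype=np.float64)
    for f in range(spec.n_frames):
        ev = events.get(f)
        acc = np.zeros(spec.grid_shape, dtype=np.float64)
        for s in range(n_substeps):
            if s > 0 and not fully_static:
                field_ = a_sub * field_ + innov_sub * _fresh_field(rng, mask, scale)
            if ev is not None:
                # displacement ramps linearly over the exposure; sub-step
                # midpoint positions sample the ramp
                frac = (s + 0.5) / n_substeps
                dr, dc = ev.displacement_px_per_exposure
                snapshot = _shift_field(field_, (frac * dr, frac * dc))
            else:
                snapshot = field_
            acc += _intensity(snapshot, beta)
        frames[f] = acc / n_substeps
        if f + 1 < spec.n_frames and not fully_static:
            # advance through inter-frame dead time plus the last sub-step
            a_tot = a_gap * a_sub
            innov_tot = np.sqrt(np.clip(1.0 - a_tot * a_tot, 0.0, None))
            field_ = a_tot * field_ + innov_tot * _fresh_field(rng, mask, scale)

    meta = StackMetadata(
        exposure_ms=t_exp,
        frame_rate_hz=spec.frame_rate_hz,
        source=f"lsci.simulate seed={spec.seed}",
    )
    meta.log(
        "render_sequence",
        seed=spec.seed,
        n_frames=spec.n_frames,
        n_substeps=n_substeps,
        speckle_size_px=spec.speckle_size_px,
        coherence_factor=beta,
        motion_events=[
            {"frame_index": ev.frame_index, "displacement": list(ev.displacement_px_per_exposure)}
            for ev in spec.motion_events
        ],
    )
    return SpeckleStack(pixels=frames, metadata=meta, sim_spec=spec)


def make_flow_phantom(
    grid_shape: tuple[int, int],
    channel_width_px: int,
    tau_c_channel_ms: float,
    seed: int = 0,
    *,
    n_frames: int = 30,
    speckle_size_px: float = 4.0,
    optics: OpticalConfig | None = None,
    frame_rate_hz: float = 40.0,
) -> SimSpec:
    """Virtual single-channel flow phantom.

    A horizontal band of width ``channel_width_px`` centered in the grid
    carries decorrelating speckle with the given ``tau_c`` (pass
    ``STATIC_TAU_C`` for the no-flow condition); the background is static
    scattering material.  Mirrors a tissue-mimicking block with one fluid
    channel used to validate flow sensitivity.
    """
    rows, cols = grid_shape
    if channel_width_px <= 0:
        raise InvalidInputError(f"channel width must be positive, got {channel_width_px}")
    if channel_width_px > rows:
        raise InvalidInputError(
            f"channel width {channel_width_px} exceeds grid rows {rows}"
        )
    if tau_c_channel_ms <= 0:
        raise InvalidInputError(f"tau_c must be positive, got {tau_c_channel_ms}")
    tau_map = np.full(grid_shape, STATIC_TAU_C)
    top = (rows - channel_width_px) // 2
    tau_map[top : top + channel_width_px, :] = tau_c_channel_ms
    return SimSpec(
        grid_shape=grid_shape,
        speckle_size_px=speckle_size_px,
        optics=optics or OpticalConfig(),
        dynamics=DynamicsField(
            tau_c_map=tau_map,
            description=(
                f"flow phantom: {channel_width_px}px channel, "
                f"tau_c={tau_c_channel_ms} ms, static background"
            ),
        ),
        n_frames=n_frames,
        seed=seed,
        frame_rate_hz=frame_rate_hz,
    )


def phantom_rois(spec: SimSpec, margin_px: int | None = None) -> tuple[RoiMask, RoiMask]:
    """Channel and background ROIs for a :func:`make_flow_phantom` spec.

    Both ROIs are eroded away from the channel edge by ``margin_px``
    (default: 2x the speckle size plus the contrast-window border) so that
    neither straddles the boundary blur.
    """
    tau = spec.dynamics.tau_c_map
    in_channel = np.isfinite(tau)
    if not in_channel.any():  # no-flow phantom: the channel band is static too
        raise InvalidInputError(
            "phantom_rois needs a finite-tau_c channel; for the no-flow "
            "condition build the ROIs from the geometry (see channel_band_rois)"
        )
    rows_in = np.flatnonzero(in_channel.any(axis=1))
    return channel_band_rois(spec, int(rows_in[0]), int(rows_in[-1] + 1), margin_px)


def channel_band_rois(
    spec: SimSpec, top: int, bottom: int, margin_px: int | None = None
) -> tuple[RoiMask, RoiMask]:
    """ROIs for a horizontal channel band [top, bottom) regardless of tau_c."""
    rows, cols = spec.grid_shape
    if margin_px is None:
        margin_px = int(math.ceil(2 * spec.speckle_size_px)) + 2
    ch = np.zeros(spec.grid_shape, dtype=bool)
    ch[top + margin_px : bottom - margin_px, margin_px : cols - margin_px] = True
    bg = np.zeros(spec.grid_shape, dtype=bool)
    bg[margin_px : max(top - margin_px, margin_px), margin_px : cols - margin_px] = True
    bg[min(bottom + margin_px, rows - margin_px) : rows - margin_px, margin_px : cols - margin_px] = True
    if not ch.any() or not bg.any():
        raise InvalidInputError("margins leave an empty channel or background ROI")
    return RoiMask(ch, label="channel"), RoiMask(bg, label="background")


def inject_motion(
    stack: SpeckleStack, events: Sequence[MotionEvent], seed: int | None = None
) -> SpeckleStack:
    """Corrupt selected frames with global translational motion blur.

    When the stack carries its :class:`SimSpec` (i.e. it came from
    :func:`render_sequence`), the affected frames are re-rendered at field
    level with the translation ramped across the exposure sub-steps — exact
    on the periodic synthesized field, and unaffected frames stay
    bit-identical because the motion shift consumes no random numbers.

    For stacks without a spec (e.g. loaded from disk) the blur is applied in
    the intensity domain by averaging shifted copies of the recorded frame
    across the exposure; this is exact for static speckle and an
    approximation otherwise.

    ``seed`` is accepted for interface symmetry; the operation itself is
    deterministic given the stack.
    """
    events = list(events)
    for ev in events:
        if not 0 <= ev.frame_index < len(stack):
            raise InvalidInputError(
                f"motion event frame index {ev.frame_index} outside stack of {len(stack)}"
            )
    if not events:
        return stack

    if stack.sim_spec is not None:
        spec: SimSpec = stack.sim_spec
        merged = [ev for ev in spec.motion_events if ev.frame_index not in {e.frame_index for e in events}]
        merged.extend(events)
        return render_sequence(replace(spec, motion_events=merged))

    # intensity-domain fallback
    pixels = stack.pixels.copy()
    n_sub = 32
    for ev in events:
        dr, dc = ev.displacement_px_per_exposure
        if dr == 0.0 and dc == 0.0:
            continue
        src = pixels[ev.frame_index]
        acc = np.zeros_like(src, dtype=np.float64)
        for s in range(n_sub):
            frac = (s + 0.5) / n_sub
            acc += _shift_intensity(src, (frac * dr, frac * dc))
        pixels[ev.frame_index] = acc / n_sub
    meta = StackMetadata.from_dict(stack.metadata.to_dict())
    meta.log(
        "inject_motion",
        events=[
            {"frame_index": ev.frame_index, "displacement": list(ev.displacement_px_per_exposure)}
            for ev in events
        ],
    )
    return SpeckleStack(pixels=pixels, metadata=meta, frame_indices=stack.frame_indices)


def _shift_intensity(img: np.ndarray, shift_rc: tuple[float, float]) -> np.ndarray:
    """Periodic bilinear translation of an intensity image (nonnegative-safe)."""
    from scipy import ndimage

    return ndimage.shift(img.astype(np.float64), shift_rc, order=1, mode="grid-wrap")


def speckle_contrast_model(
    exposure_ms: float, tau_c_ms: float, coherence_factor: float = 1.0
) -> float:
    """Closed-form exposure-averaged speckle contrast K(T, tau_c, beta).

    For a field decorrelating as g1(tau) = exp(-tau/tau_c), averaging the
    intensity over an exposure T gives

        K^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c,

    the triangular-weighted integral of |g1|^2.  Limits: K -> sqrt(beta) as
    tau_c/T -> inf (static), K -> sqrt(beta * tau_c / T) as tau_c/T -> 0.
    """
    if exposure_ms <= 0 or tau_c_ms <= 0:
        raise InvalidInputError("exposure and tau_c must be positive")
    if not 0.0 < coherence_factor <= 1.0:
        raise InvalidInputError(f"coherence_factor must be in (0, 1], got {coherence_factor}")
    if np.isinf(tau_c_ms):
        return math.sqrt(coherence_factor)
    x = exposure_ms / tau_c_ms
    if x < 1e-6:  # series expansion to avoid cancellation
        k2 = 1.0 - 2.0 * x / 3.0
    else:
        k2 = (math.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x * x)
    return math.sqrt(coherence_factor * k2)


def global_contrast(frame: SpeckleFrame | np.ndarray) -> float:
    """Whole-frame contrast std/mean (sample std, ddof=1)."""
    px = frame.pixels if isinstance(frame, SpeckleFrame) else np.asarray(frame)
    m = float(px.mean())
    if m == 0:
        raise InvalidInputError("cannot compute contrast of an all-zero frame")
    return float(px.std(ddof=1)) / m
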
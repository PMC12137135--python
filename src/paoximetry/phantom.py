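"""Synthetic tumor phantom of fluence-rate-dependent PDT oxygen dynamics.

Generates ground-truth chromophore fields and noisy two-wavelength
photoacoustic frames for a 2D tumor cross-section under photodynamic therapy,
so that every pipeline stage can be exercised and validated without animal
data.  The kinetics are phenomenological: per pixel x with local therapy
fluence rate Phi(x), saturation S (in true %) follows the discrete update

    S(t+dt) = S + dt * [ -k_consume * Phi(x) * P(t) * S/100
                         + v(t) * (S0(x) - S)
                         - k_shutdown * w(t) * S
                         + r(x) * k_recovery * 1(t > t_trough) ]   (capped at S0)

clipped to [0, 100], where P(t) = exp(-k_bleach * mean(Phi) * t_light) is the
photosensitizer availability (photobleaching), v(t) a Gaussian-bump
vasodilation reflow shortly after light-on, w(t) a saturating vascular
shutdown ramp, and r(x) the programmed recovering region (a rim band plus an
optional interior patch) whose vasculature retains function.  Without a
photosensitizer (k_consume = 0, the light-only controls) there is no
photodynamic action: consumption, shutdown and recovery are all inactive and
S stays at S0.  Total hemoglobin is modulated +-20 % by the vasodilation and
shutdown waveforms.  Frames at 750/850 nm are rendered through the extinction
matrix with per-channel gain and additive Gaussian noise.

The default grid, schedule and fluence rates mirror the monitored treatment
protocol: a 5-min baseline, 15 min of light at 100 (LFR) or 400 (HFR)
mW/cm^2, 10 min of follow-up, frames every 4 s, tumors ~7-9 mm across.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .exceptions import StabilityError, ValidationError
from .kinetics import PDTTimeline, ROIMask
from .unmixing import ExtinctionTable, FramePair, FrameStack, default_extinction_table

__all__ = [
    "Fiber",
    "VasodilationSpec",
    "RecoverySpec",
    "KineticsSpec",
    "PhantomSpec",
    "PhantomTruth",
    "FixtureBundle",
    "simulate_dynamics",
    "render_frames",
    "make_fixture",
    "FIXTURE_CASES",
]


@dataclass(frozen=True)
class Fiber:
    """One therapy fiber: illumination direction and fluence rate (mW/cm^2).

    ``in_plane`` fibers illuminate the cross-section uniformly; ``left`` and
    ``right`` fibers have a linear lateral gradient (mean 1 across the image)
    peaking at their own side, which realizes asymmetric dose layouts.
    """

    direction: Literal["left", "right", "in_plane"]
    fluence_mw_cm2: float

    def __post_init__(self) -> None:
        if self.fluence_mw_cm2 < 0:
            raise ValidationError("fluence rate must be >= 0")
        if self.direction not in ("left", "right", "in_plane"):
            raise ValidationError(f"unknown fiber direction {self.direction!r}")


@dataclass(frozen=True)
class VasodilationSpec:
    """Transient reflow bump after light-on (relaxation toward S0, 1/min)."""

    amplitude_per_min: float = 0.45
    peak_min: float = 2.0
    width_min: float = 1.2


@dataclass(frozen=True)
class RecoverySpec:
    """Post-trough reoxygenation region and rate.

    Recovering pixels climb back toward their baseline saturation at a
    constant rate (capped at S0), emulating reperfusion through vasculature
    that retained function; ``onset_delay_s`` is the lag between the end of
    active PDT and the start of reperfusion when no explicit trough time is
    programmed.
    """

    rim_width_mm: float = 1.0
    rate_per_min: float = 6.0
    interior_fraction: float = 0.05
    onset_delay_s: float = 60.0


@dataclass(frozen=True)
class KineticsSpec:
    """Rate constants of the phenomenological PDT oxygen model."""

    k_consume: float = 0.035 # % StO2 per (mW/cm^2 * min) at S = 100 %
    k_bleach: float = 0.00042  # photobleaching, cm^2/(mW*min)
    vasodilation: VasodilationSpec = field(default_factory=VasodilationSpec)
    k_shutdown: float = 0.024  # vascular shutdown, 1/min at full ramp
    shutdown_dose: float = 1200.0  # photodynamic exposure for full shutdown, mW*min/cm^2
    recovery: RecoverySpec = field(default_factory=RecoverySpec)
    t_trough_s: float | None = None  # recovery onset; None -> light-off


def _default_timeline() -> PDTTimeline:
    return PDTTimeline(
        t_baseline_start=0.0, t_light_on=300.0, t_light_off=1200.0, t_end=1800.0
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full configuration of one simulated recording."""

    shape: tuple[int, int] = (128, 128)
    pixel_spacing_mm: tuple[float, float] = (0.1, 0.1)
    tumor_center: tuple[float, float] | None = None  # (row, col), px
    tumor_semiaxes: tuple[float, float] | None = None  # (row, col), px
    hbt_base: float = 1.0
    n_blobs: int = 30
    blob_amplitude: float = 1.5
    correlation_px: float = 2.0
    s0_mean: float = 70.0
    s0_sd: float = 8.0
    fibers: tuple[Fiber, ...] = (Fiber("in_plane", 400.0),)
    timeline: PDTTimeline = field(default_factory=_default_timeline)
    frame_period_s: float = 4.0
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    noise_sd: float = 0.01  # additive, relative to mean in-tumor signal
    gain: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_period_s <= 0:
            raise ValidationError("frame period must be positive")
        if not 0 < self.s0_mean < 100:
            raise ValidationError("s0_mean must lie in (0, 100)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def center(self) -> tuple[float, float]:
        h, w = self.shape
        return self.tumor_center or ((h - 1) / 2.0, (w - 1) / 2.0)

    @property
    def semiaxes(self) -> tuple[float, float]:
        h, w = self.shape
        return self.tumor_semiaxes or (0.28 * h, 0.35 * w)


@dataclass
class PhantomTruth:
    """Ground-truth fields and milestones of one simulated recording."""

    t: np.ndarray  # (T,) seconds
    sto2_true: np.ndarray  # (T, H, W) true saturation, %
    hbt_true: np.ndarray  # (T, H, W) true total hemoglobin, a.u.
    roi: ROIMask
    recovery_mask: np.ndarray  # r(x), bool
    fluence: np.ndarray  # Phi(x), mW/cm^2
    milestones: PDTTimeline  # t_active_end = true ROI-mean trough time
    spec: PhantomSpec

    @property
    def c_hbo(self) -> np.ndarray:
        return self.hbt_true * self.sto2_true / 100.0

    @property
    def c_hbd(self) -> np.ndarray:
        return self.hbt_true * (1.0 - self.sto2_true / 100.0)

    @property
    def recovering_fraction(self) -> float:
        """Programmed fraction of ROI pixels in the recovering region."""
        roi = self.roi.mask
        return float((self.recovery_mask & roi).sum() / roi.sum())

    def roi_mean_sto2(self) -> np.ndarray:
        """Noiseless ROI-mean saturation trace (true %, per frame)."""
        roi = self.roi.mask
        return self.sto2_true[:, roi].mean(axis=1)


@dataclass
class FixtureBundle:
    """A named simulation case bundled with everything the pipeline needs."""

    case: str
    spec: PhantomSpec
    truth: PhantomTruth
    stack: FrameStack
    roi: ROIMask
    ext: ExtinctionTable


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semiaxes: tuple[float, float],
) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return ((rows - center[0]) / semiaxes[0]) ** 2 + (
        (cols - center[1]) / semiaxes[1]
    ) ** 2 <= 1.0


def _smooth(field: np.ndarray, sigma_px: float) -> np.ndarray:
    from scipy import ndimage

    return ndimage.gaussian_filter(field, sigma=sigma_px) if sigma_px > 0 else field


def fluence_map(spec: PhantomSpec) -> np.ndarray:
    """Total local fluence rate Phi(x) in mW/cm^2 (sum over fibers)."""
    h, w = spec.shape
    u = np.linspace(0.0, 1.0, w)[None, :] * np.ones((h, 1))
    phi = np.zeros(spec.shape)
    for f in spec.fibers:
        if f.direction == "in_plane":
            profile = np.ones(spec.shape)
        elif f.direction == "left":
            profile = 2.0 * (1.0 - u)
        else:  # right
            profile = 2.0 * u
        phi += f.fluence_mw_cm2 * profile
    return phi


def _baseline_fields(
    spec: PhantomSpec, rng: np.random.Generator, roi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline HbT texture (vessel blobs on a base level) and S0 field."""
    h, w = spec.shape
    hbt0 = np.full(spec.shape, spec.hbt_base)
    rows = rng.uniform(0, h, size=spec.n_blobs)
    cols = rng.uniform(0, w, size=spec.n_blobs)
    amps = rng.uniform(0.3, 1.0, size=spec.n_blobs) * spec.blob_amplitude
    rr, cc = np.ogrid[:h, :w]
    for r0, c0, a in zip(rows, cols, amps):
        hbt0 += a * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * (2.5 * spec.correlation_px) ** 2)
        )
    hbt0 = _smooth(hbt0, spec.correlation_px)
    hbt0 = np.where(roi, hbt0, 0.0)

    s0 = spec.s0_mean + spec.s0_sd * _smooth(
        rng.standard_normal(spec.shape), 2.0 * spec.correlation_px
    ) * (2.0 * spec.correlation_px)  # rescale: smoothing shrinks the SD
    s0 = np.clip(s0, 20.0, 95.0)
    return hbt0, np.where(roi, s0, 0.0)


def _recovery_region(
    spec: PhantomSpec, roi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rim band plus an optional interior patch in the upper-right quadrant."""
    rec = spec.kinetics.recovery
    cy, cx = spec.center
    ay, ax = spec.semiaxes
    rim_px = rec.rim_width_mm / spec.pixel_spacing_mm[0]
    inner = _ellipse_mask(
        spec.shape, (cy, cx), (max(ay - rim_px, 1.0), max(ax - rim_px, 1.0))
    )
    region = roi & ~inner
    if rec.interior_fraction > 0:
        target = rec.interior_fraction * roi.sum()
        radius = np.sqrt(target / np.pi)
        rr, cc = np.ogrid[: spec.shape[0], : spec.shape[1]]
        patch_center = (cy - 0.45 * ay, cx + 0.45 * ax)  # upper-right quadrant
        patch = (rr - patch_center[0]) ** 2 + (cc - patch_center[1]) ** 2 <= radius**2
        region |= patch & roi
    return region


def simulate_dynamics(spec: PhantomSpec) -> PhantomTruth:
    """Integrate the PDT oxygen model and return ground-truth fields.

    Raises
    ------
    StabilityError
        If the frame period is too large for the configured rate constants
        (explicit Euler would over- or undershoot); the message suggests a
        stable step.
    """
    kin = spec.kinetics
    tl = spec.timeline
    rng = np.random.default_rng(spec.seed)

    roi_mask = _ellipse_mask(spec.shape, spec.center, spec.semiaxes)
    phi = fluence_map(spec)
    hbt0, s0 = _baseline_fields(spec, rng, roi_mask)
    recovery_mask = _recovery_region(spec, roi_mask, rng)

    t = np.arange(tl.t_baseline_start, tl.t_end + 1e-9, spec.frame_period_s)
    dt_min = spec.frame_period_s / 60.0
    phi_mean = float(phi[roi_mask].mean()) if roi_mask.any() else 0.0
    # recovery is excluded: the capped climb cannot overshoot S0
    rate_bound = (
        kin.k_consume * float(phi.max()) / 100.0
        + kin.vasodilation.amplitude_per_min
        + kin.k_shutdown
    )
    if rate_bound * dt_min > 0.5:
        raise StabilityError(
            "frame period too large for the rate constants; use a period "
            f"below {0.5 / rate_bound * 60.0:.1f} s"
        )

    ps_active = kin.k_consume > 0
    t_trough = (
        kin.t_trough_s
        if kin.t_trough_s is not None
        else tl.t_light_off + kin.recovery.onset_delay_s
    )
    vas = kin.vasodilation
    light_duration_min = (tl.t_light_off - tl.t_light_on) / 60.0

    sto2 = np.empty((t.size,) + spec.shape)
    hbt = np.empty_like(sto2)
    s = s0.copy()
    pd_dose = 0.0  # accumulated photodynamic exposure, mW*min/cm^2
    for i, ti in enumerate(t):
        t_light = np.clip((ti - tl.t_light_on) / 60.0, 0.0, None)  # min of light
        lit = tl.t_light_on <= ti < tl.t_light_off
        elapsed = min(t_light, light_duration_min)
        v = vas.amplitude_per_min * np.exp(
            -((t_light - vas.peak_min) ** 2) / (2.0 * vas.width_min**2)
        ) if ti >= tl.t_light_on else 0.0
        p_avail = np.exp(-kin.k_bleach * phi_mean * elapsed) if ps_active else 0.0
        # shutdown tracks delivered photodynamic dose (fluence x available PS),
        # so a high fluence rate shuts vessels sooner and harder than a low one
        w = min(1.0, pd_dose / kin.shutdown_dose) if ps_active else 0.0
        if lit:
            pd_dose += phi_mean * p_avail * dt_min

        sto2[i] = s
        hbt[i] = np.where(
            roi_mask,
            hbt0 * (1.0 + 0.2 * (v / vas.amplitude_per_min) - 0.2 * w),
            0.0,
        )

        ds = np.zeros(spec.shape)
        if lit:
            ds -= kin.k_consume * phi * p_avail * s / 100.0
            ds += v * (s0 - s)
        # shutdown persists after light (damaged vessels stay shut) but spares
        # the recovering region, whose vasculature retains function
        ds -= kin.k_shutdown * w * (~recovery_mask) * s
        if ps_active and ti > t_trough:
            # constant-rate reperfusion, capped so S never overshoots S0
            climb = np.minimum(
                kin.recovery.rate_per_min,
                np.maximum(s0 - s, 0.0) / dt_min,
            )
            ds += climb * recovery_mask
        s = np.clip(np.where(roi_mask, s + dt_min * ds, 0.0), 0.0, 100.0)

    roi = ROIMask(roi_mask, label="tumor")
    truth = PhantomTruth(
        t=t,
        sto2_true=sto2,
        hbt_true=hbt,
        roi=roi,
        recovery_mask=recovery_mask,
        fluence=phi,
        milestones=replace(tl),
        spec=spec,
    )
    trace = truth.roi_mean_sto2()
    in_light = (t >= tl.t_light_on) & (t <= tl.t_light_off)
    truth.milestones.t_active_end = float(t[in_light][np.argmin(trace[in_light])])
    return truth


def render_frames(
    truth: PhantomTruth, ext: ExtinctionTable | None = None
) -> FrameStack:
    """Render noisy two-wavelength frames from ground-truth chromophores.

    img_lambda = gain_lambda * (eps_HbO c_HbO + eps_HbD c_HbD) + N(0, sd),
    with sd = noise_sd times the mean noiseless in-tumor signal of that
    channel.  Outside the tumor the signal is noise only.  The noise stream
    is seeded from the phantom seed, so identical specs render bit-identical
    stacks.
    """
    spec = truth.spec
    ext = ext or default_extinction_table()
    E = ext.matrix
    if E.shape[0] != 2:
        raise ValidationError("rendering expects a two-wavelength table")
    rng = np.random.default_rng([spec.seed, 9173])
    c_hbo, c_hbd = truth.c_hbo, truth.c_hbd
    roi = truth.roi.mask
    frames = []
    clean = [E[j, 0] * c_hbo + E[j, 1] * c_hbd for j in range(2)]
    for j in range(2):
        mean_sig = float(clean[j][:, roi].mean())
        noise = rng.normal(0.0, spec.noise_sd * mean_sig, size=clean[j].shape)
        clean[j] = spec.gain[j] * clean[j] + noise
    for i, ti in enumerate(truth.t):
        frames.append(FramePair(img_750=clean[0][i], img_850=clean[1][i], t=float(ti)))
    return FrameStack(frames=tuple(frames), pixel_spacing_mm=spec.pixel_spacing_mm)


#: Study fluence-rate arms: 15-min light at the stated total mW/cm^2.
FIXTURE_CASES = ("LFR", "HFR", "light_only", "asymmetric")

_TROUGH_HFR_S = 720.0  # programmed trough: 7 min into light (12-min mark)


def _case_spec(case: str, seed: int, shape: tuple[int, int]) -> PhantomSpec:
    kin = KineticsSpec()
    if case == "LFR":
        fibers = (Fiber("in_plane", 100.0),)
    elif case == "HFR":
        fibers = (Fiber("in_plane", 400.0),)
        kin = replace(kin, t_trough_s=_TROUGH_HFR_S)
    elif case == "light_only":
        fibers = (Fiber("in_plane", 400.0),)
        kin = replace(kin, k_consume=0.0)
    elif case == "asymmetric":
        fibers = (
            Fiber("left", 150.0),
            Fiber("right", 50.0),
            Fiber("in_plane", 100.0),
            Fiber("in_plane", 100.0),
        )
        kin = replace(kin, t_trough_s=_TROUGH_HFR_S)
    else:
        raise ValidationError(
            f"unknown case {case!r}; expected one of {FIXTURE_CASES}"
        )
    return PhantomSpec(shape=shape, fibers=fibers, kinetics=kin, seed=seed)


def make_fixture(
    case: str, seed: int = 0, shape: tuple[int, int] = (128, 128)
) -> FixtureBundle:
    """Deterministic named fixture: spec + truth + rendered stack + ROI.

    Cases: ``LFR`` (100 mW/cm^2), ``HFR`` (400), ``light_only`` (400, no
    photosensitizer) and ``asymmetric`` (left 150 / right 50 / two face
    fibers at 100).  All use a 5-min baseline, 15-min light, 10-min
    follow-up at 4-s frames.
    """
    spec = _case_spec(case, seed, shape)
    truth = simulate_dynamics(spec)
    ext = default_extinction_table()
    stack = render_frames(truth, ext)
    return FixtureBundle(
        case=case, spec=spec, truth=truth, stack=stack, roi=truth.roi, ext=ext
    )
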
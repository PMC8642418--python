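"""Dynamic speckle stack generator.

Emulates the raw CCD frames of a speckle-flow acquisition: a fully developed
complex Gaussian speckle field whose grain size is set by a circular pupil in
the frequency domain, evolved in time as an AR(1) process with field
correlation exp(-dt/tau_c), where the decorrelation time maps to flow speed
as tau_c = a / v.  The detected field mixes a static component (overlying
tissue) with the dynamic one:

    E(t) = sqrt(rho_s) * E_static + sqrt(1 - rho_s) * E_dyn(t)

Each frame integrates intensity over sub-intervals of the exposure, the fine
grid is binned down to sensor pixels (so grains smaller than a pixel lose
contrast, as on a real detector), and optional read/photon noise is added.

The generator is a modeling stand-in for camera data: it reproduces the
ordinal relationships between flow speed, decorrelation, static-light
dilution and temporal contrast, not any absolute velocity calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .speckle_analysis import DEFAULT_EXPOSURE_MS, DEFAULT_N_FRAMES, FrameStack

__all__ = [
    "SceneSpec",
    "GeneratorParams",
    "correlated_field",
    "evolve_field",
    "render_stack",
    "make_phantom_scene",
    "pupil_fraction_for_speckle_size",
    "DEFAULT_DECORR_CONSTANT",
]

log = logging.getLogger(__name__)

# tau_c = a / v; a in ms * mm/s.  At the default 20-ms exposure, v = 4 mm/s
# gives tau_c = exposure / 10, placing the fastest phantom flow deep in the
# exposure-blurring regime.
DEFAULT_DECORR_CONSTANT = 8.0


@dataclass(frozen=True)
class SceneSpec:
    """Spatial description of a synthetic flow scene at sensor resolution."""

    velocity_map: np.ndarray          # mm/s, >= 0
    static_fraction_map: np.ndarray   # fraction of detected intensity that is static, [0, 1]
    background_velocity: float = 0.0  # perfusion floor added everywhere, mm/s
    tube_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity_map, dtype=np.float64)
        r = np.asarray(self.static_fraction_map, dtype=np.float64)
        if v.shape != r.shape:
            raise ValueError("velocity and static-fraction maps must share a shape")
        if np.any(v < 0):
            raise ValueError("velocities must be >= 0")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("static fractions must lie in [0, 1]")
        if self.background_velocity < 0:
            raise ValueError("background velocity must be >= 0")
        object.__setattr__(self, "velocity_map", v)
        object.__setattr__(self, "static_fraction_map", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.velocity_map.shape


@dataclass(frozen=True)
class GeneratorParams:
    """Acquisition and speckle-statistics parameters of the generator."""

    exposure_ms: float = DEFAULT_EXPOSURE_MS
    n_frames: int = DEFAULT_N_FRAMES
    substeps: int = 20
    decorr_constant: float = DEFAULT_DECORR_CONSTANT  # a in tau_c = a/v, ms*mm/s
    pupil_fraction: float = 0.41   # fraction of Nyquist on the fine grid
    oversample: int = 2            # fine-grid pixels per sensor pixel (linear)
    read_noise: float = 0.0        # gaussian sigma, units of mean intensity
    photon_noise_scale: float = 0.0  # mean detected photons per unit intensity (0 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if not 0.0 < self.pupil_fraction <= 1.0:
            raise ValueError("pupil fraction must lie in (0, 1]")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def pupil_fraction_for_speckle_size(size_px: float, oversample: int = 2) -> float:
    """Pupil fraction (of Nyquist, fine grid) giving ~``size_px`` grains at
    sensor resolution.

    The field coherence of a circular-pupil-filtered white field is a jinc
    whose squared modulus reaches half maximum near 1.616 rad, giving an
    intensity-autocovariance FWHM of about 1.03 / pupil_fraction fine pixels.
    """
    if size_px <= 0:
        raise ValueError("speckle size must be > 0")
    return float(np.clip(1.029 / (size_px * oversample), 1e-3, 1.0))


def correlated_field(
    shape: tuple[int, int],
    pupil_fraction: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Fully developed complex Gaussian speckle field with unit mean intensity.

    White circular complex Gaussian noise is low-pass filtered by a circular
    pupil of radius ``pupil_fraction`` x Nyquist in the frequency domain and
    renormalized; single-frame intensity contrast is ~1 regardless of pupil.
    """
    if not 0.0 < pupil_fraction <= 1.0:
        raise ValueError("pupil fraction must lie in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    white = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    if pupil_fraction >= 1.0:
        field_ = white
    else:
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.fftfreq(shape[1])[None, :]
        mask = (fy * fy + fx * fx) <= (0.5 * pupil_fraction) ** 2
        field_ = np.fft.ifft2(np.fft.fft2(white) * mask)
    power = np.mean(np.abs(field_) ** 2)
    return field_ / np.sqrt(power)


def evolve_field(
    field_: np.ndarray,
    dt: float,
    tau_c: float | np.ndarray,
    rng: np.random.Generator | int,
    pupil_fraction: float = 0.41,
) -> np.ndarray:
    """One AR(1) step: E' = rho * E + sqrt(1 - rho^2) * E_new with
    rho = exp(-dt/tau_c) (per pixel if ``tau_c`` is a map; tau_c = inf leaves
    the field unchanged).  Preserves unit mean intensity in expectation and
    yields exact exponential field autocorrelation over steps."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau = np.asarray(tau_c, dtype=np.float64)
    if np.any(tau <= 0):
        raise ValueError("tau_c must be > 0 (use np.inf for a frozen field)")
    rho = np.exp(-dt / tau)
    if np.all(rho >= 1.0):
        return field_
    innovation = correlated_field(field_.shape, pupil_fraction, rng)
    return rho * field_ + np.sqrt(1.0 - rho * rho) * innovation


def _upsample(a: np.ndarray, k: int) -> np.ndarray:
    return np.repeat(np.repeat(a, k, axis=0), k, axis=1)


def _bin_down(a: np.ndarray, k: int) -> np.ndarray:
    r, c = a.shape
    return a.reshape(r // k, k, c // k, k).mean(axis=(1, 3))


def render_stack(scene: SceneSpec, params: GeneratorParams) -> FrameStack:
    """Render a frame stack for a scene; deterministic given ``params.seed``.

    The dynamic field evolves continuously across frames; per frame, intensity
    is averaged over ``substeps`` sub-intervals of the exposure, then binned
    from the fine grid to sensor pixels.
    """
    k = params.oversample
    rows, cols = scene.shape
    fine_shape = (rows * k, cols * k)

    v_eff = _upsample(scene.velocity_map + scene.background_velocity, k)
    rho_s = _upsample(scene.static_fraction_map, k)
    with np.errstate(divide="ignore"):
        tau_c = np.where(v_eff > 0, params.decorr_constant / v_eff, np.inf)

    dt = params.exposure_ms / params.substeps
    finite = tau_c[np.isfinite(tau_c)]
    if finite.size and dt > 0.5 * finite.min():
        log.warning(
            "temporal undersampling: substep dt=%.3g ms exceeds tau_c/2=%.3g ms; "
            "increase substeps for faithful exposure integration",
            dt,
            0.5 * finite.min(),
        )

    rng = np.random.default_rng(params.seed)
    e_static = correlated_field(fine_shape, params.pupil_fraction, rng)
    e_dyn = correlated_field(fine_shape, params.pupil_fraction, rng)

    amp_s = np.sqrt(rho_s)
    amp_d = np.sqrt(1.0 - rho_s)
    rho = np.exp(-dt / tau_c)
    mix = np.sqrt(1.0 - rho * rho)
    dynamic = bool(np.any(mix > 0))

    frames = np.empty((params.n_frames, rows, cols), dtype=np.float64)
    for fi in range(params.n_frames):
        acc = np.zeros(fine_shape)
        for _ in range(params.substeps):
            if dynamic:
                innovation = correlated_field(fine_shape, params.pupil_fraction, rng)
                e_dyn = rho * e_dyn + mix * innovation
            det = amp_s * e_static + amp_d * e_dyn
            acc += np.abs(det) ** 2
        frames[fi] = _bin_down(acc / params.substeps, k)

    if params.photon_noise_scale > 0:
        frames = rng.poisson(frames * params.photon_noise_scale) / params.photon_noise_scale
    if params.read_noise > 0:
        frames = frames + rng.normal(0.0, params.read_noise * frames.mean(), frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames=frames, exposure_ms=params.exposure_ms)


def make_phantom_scene(
    static_fraction: float,
    tube_velocity: float,
    shape: tuple[int, int] = (96, 96),
    tube_width_px: int = 24,
    tube_static_attenuation: float = 0.8,
    background_velocity: float = 0.2,
) -> SceneSpec:
    """Capillary-tube-in-turbid-medium scene: a horizontal flow band over a
    quasi-static background.

    ``static_fraction`` is the depth proxy — the fraction of detected light
    that never decorrelates (overlying scattering medium).  Inside the tube it
    is multiplied by ``tube_static_attenuation`` (the tube sits below less
    overburden than the surrounding field sees in reflection).  The background
    keeps a perfusion-floor velocity so it decorrelates slowly (Brownian
    motion, tissue perfusion) rather than freezing; the default floor
    decorrelates within the 40-frame acquisition, as quasi-static tissue does.
    """
    if not 0.0 <= static_fraction <= 1.0:
        raise ValueError("static_fraction must lie in [0, 1]")
    if tube_velocity < 0:
        raise ValueError("tube velocity must be >= 0")
    rows, cols = shape
    r0 = rows // 2 - tube_width_px // 2
    r1 = r0 + tube_width_px
    tube = np.zeros(shape, dtype=bool)
    tube[r0:r1, :] = True

    velocity = np.where(tube, tube_velocity, 0.0)
    rho_s = np.where(tube, static_fraction * tube_static_attenuation, static_fraction)
    return SceneSpec(
        velocity_map=velocity,
        static_fraction_map=rho_s,
        background_velocity=background_velocity,
        tube_mask=tube,
    )
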
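# Methods

## Problem

Conventional laser speckle contrast imaging (LSCI) illuminates and detects on
the same tissue face.  For targets more than a few hundred micrometres deep,
the statically scattered light from the overlying layers overwhelms the
dynamically scattered signal from moving blood, and contrast collapses.
Transmissive-detected LSCI (TR-LSCI) instead illuminates the far face and
detects on the near face, trading total intensity for a much more favourable
signal composition at depth.  This package implements the computational
machinery needed to compare the two arrangements: a layered-tissue photon
Monte Carlo with a two-step signal-to-background (SBR) analysis, the
temporal-contrast LSCI processing chain, and a synthetic dynamic-speckle
generator that stands in for camera data.

## Photon transport

`photon_mc` is a standard weight-based (MCML-style) random walk through a
laterally infinite layered slab: exponential free paths with total
interaction coefficient mu_t = mu_a + mu_s, Henyey–Greenstein deflection
sampled by the closed-form inverse CDF (isotropic branch at g = 0), uniform
azimuth, unpolarized Fresnel reflection/refraction at every index mismatch
(total internal reflection included), weight drop mu_a/mu_t per interaction,
and Russian roulette below weight 1e-4 with survival chance 1/10.  Specular
reflection at pencil-beam entry is deducted at launch and booked as escape
through the entry face, so escaped_top + escaped_bottom + absorbed = 1 up to
roulette noise.  Layers with mu_t = 0 propagate ballistically.  The core loop
is a numba kernel; a run is bitwise-deterministic in (geometry, source, seed,
photon count).

Fluence is scored by a track-length estimator — summed weight x path length
per bin — which is unbiased, lower-variance than absorption scoring, and
well defined in non-absorbing layers.  Paths are split exactly at depth-bin
boundaries (10-um bins by default).  Two views are tallied:

* **planar fluence** `fluence_z`: laterally integrated, relative to the
  incident irradiance;
* **near-axis flux density** `fluence_rz`: cylindrical (z, r) bins (5 um
  radial resolution by default) around the pencil-beam axis.

The distinction matters.  The reference dermis slab (n 1.40, mu_a 0.28 cm^-1,
mu_s 80.6 cm^-1, g 0.82, 520 um) is only ~0.8 transport mean free paths thick
with single-scattering albedo 0.997, so the *planar* fluence is essentially
flat with depth (we measure surface/200 um ~ 0.99).  What decays with depth
is the flux density near the axis of a narrow beam, which is the quantity a
2-D "light distribution" map of a pencil beam displays.  All layer-flux and
signal-return readings therefore use the near-axis density.

**Axis radius calibration.**  The near-axis density of a singular pencil beam
depends on the radius it is averaged over (ratios at 200 um depth range from
~3.3 within 10 um of the axis to ~1.0 beyond 300 um).  The averaging radius
is fixed once, at 35 um, so that the simulated illumination map reproduces
the one stated anchor of the depth-decay model — surface flux about twice
the 200-um flux in the 520-um dermis (we measure 1.91).  All downstream
retention results are then out-of-sample with respect to this calibration.
The radius is exposed as `axis_radius_um` everywhere it is used.

## Two-step SBR

The SBR of a signal layer is the proportion of detector-reaching light that
originates at that layer relative to all candidate layers:

    SBR_k = f_k * r_k / sum_j f_j * r_j

* **Step 1 (illumination), f_k** — near-axis flux at plane k of a pencil
  beam entering the face implied by the mode (top for reflective, bottom for
  transmissive), normalized at the entry face.
* **Step 2 (signal return), r_k** — attenuation suffered by light re-emitted
  at plane k on its way to the detector face (always the top).  The default
  `flux_return` model reads this from a dedicated top-launched flux map: the
  return over thickness z decays like the illumination map over depth z.
  One 1e6-photon map run serves all planes of a geometry and is shared
  between modes.

An alternative step-2 model, `isotropic_escape` (isotropic point emitter at
the plane, total weight escaping the top face), is retained as a sensitivity
control and as `escape_fraction_to_detector`.  It is *not* the default
because total escape is nearly depth-blind in this regime — we measure
escape-to-top 0.49 at the surface vs 0.45 at the 520-um face — which is
physically correct for an angle- and radius-integrated ideal detector, but
cannot produce the characteristic retention losses of a finite-field,
narrow-beam imaging system: under it, transmissive retention under top
thickening stays ~100 % and the two modes are far from comparable at 200 um.
The `flux_return` model reproduces the full qualitative structure (steep
reflective decay; stable transmissive profile; mode crossover with
comparability at 200 um; top-thickening hurting the reflective mode,
bottom-thickening the transmissive mode; reflective immunity to bottom
thickening), and the retention magnitudes to within about ten percentage
points.  Residual mismatch concentrates in the transmissive top-thickening
branch, which this realization underestimates by roughly 10 points —
consistent with the remaining ambiguity in the return step's angular
distribution and scoring.

SBR values of one configuration are normalized shares, so they sum to 1
exactly and lie in [0, 1] by construction.

## Thickness sweeps

The signal layer stays fixed in the material while dermis is added above or
below in 100-um steps (to +400 um); the phantom variant adds 0.5-mm steps to
a 3.5-mm slab.  At each step the candidate-layer set is re-gridded at the
base spacing (100 um) over the whole thickened slab plus the bottom face —
the rule that reproduces the unthickened plane sets (0, 100, ..., 520 um)
exactly — so added tissue both attenuates and contributes background signal.
The alternative `plane_strategy="fixed"` (original layer set only) is kept
as a knob; it weakens the sweep response and was not adopted.  Retention is
reported as 100 x SBR/SBR(+0).

A note on one ordering property: upper-layer thickening dominates
lower-layer thickening for the reflective mode in this realization, but for
the transmissive mode the two sides are nearly equal (bottom thickening
slightly stronger), because bottom thickening directly attenuates the
illumination path.  The layered skin preset also shows a small sub-surface
SBR *rise* under the stratum corneum before the monotone decay (flux
buildup below the highly scattering 20-um layer); monotone reflective decay
holds for the homogeneous presets.

## Temporal-contrast analysis

K_t(x, y) = sigma(x, y)/<I(x, y)> over the frame axis (default 40 frames at
20 ms).  sigma uses the sample (N-1) denominator — the common acquisition
default — with ddof exposed; constant pixel series are forced to exactly
zero to keep the static-scene contract independent of float rounding, and
zero-mean pixels are flagged NaN rather than raising.  The flow index
1/K_t^2 is clamped at a ceiling (default 1e4) so static pixels stay finite;
K_t is scale-invariant by construction.  DeltaFlow = (I_i - I_BL)/I_BL with
I_BL the mean over the pre-stimulus baseline window.  Speckle size is the
FWHM (linear interpolation between lags, averaged over the two axes) of the
central peak of the FFT-based normalized autocovariance of the
mean-subtracted frame; the circular (periodic) autocovariance is used, which
is indistinguishable from the unbiased form at the few-pixel lags that
matter.  ROI metrics: vessel-mean/background-mean flow index (the package's
operational vessel-to-background ratio; the in vivo estimator behind the
published tables is unstated) and background-subtracted signal; line
profiles are bilinear.

## Synthetic speckle generator

The generator emulates the acquisition geometry of the phantom experiments:
a capillary tube (flow band) under a turbid overburden, imaged as 40-frame,
20-ms stacks.

* **Field**: circularly symmetric complex Gaussian white noise, low-pass
  filtered by a circular pupil in the frequency domain and renormalized to
  unit mean intensity — fully developed speckle (single-frame contrast ~1)
  with grain size ~1.03/pupil_fraction pixels.
* **Dynamics**: per-pixel AR(1) evolution E' = rho E + sqrt(1-rho^2) E_new
  with rho = exp(-dt/tau_c): the simplest process with exact exponential
  field decorrelation.  tau_c = a / v with a = 8 ms*mm/s by default, chosen
  so the fastest phantom speed (4 mm/s) gives tau_c = exposure/10 — deep in
  the exposure-blurring regime; only ordinal velocity behavior is claimed.
* **Static mixing**: detected field sqrt(rho_s) E_static +
  sqrt(1-rho_s) E_dyn; rho_s is the depth proxy (fraction of detected light
  from the static overburden).  Inside the tube rho_s is attenuated (x0.8).
* **Background floor**: 0.2 mm/s everywhere (tau_c = 40 ms), so "static"
  tissue decorrelates within the 0.8-s acquisition, as quasi-static tissue
  with Brownian/perfusion motion does.  Without it, a frozen background's
  *measured* K_t is biased low (correlated frames shrink the sample
  standard deviation), which would invert the low-velocity ordering.
* **Exposure integration**: each frame averages intensity over `substeps`
  (default 20) sub-intervals; a log warning flags dt > tau_c/2.
* **Detector**: fields are rendered at 2x linear oversampling and binned to
  sensor pixels, so grains comparable to a pixel lose contrast exactly as on
  a real detector — this is what makes temporal contrast grow with speckle
  size.  Optional Gaussian read noise (sigma relative to mean intensity) and
  Poisson photon noise; the suite's sweeps use 15 % read noise, which sets
  the realistic saturation of the flow index at high velocity.

What the generator does **not** model: physical propagation of fields
through the Monte Carlo medium (no coupling of photon paths to phases),
polarization, absolute velocity calibration, vessel cross-sectional flow
profiles, or camera nonlinearity.  Passing tests therefore validate the
analysis chain's statistical contracts and ordinal flow sensitivity, not
absolute flow quantification on real tissue.

## Problem sizes and numerics

Step-1/return maps use 1e6 photons (standard errors on retentions ~0.2
percentage points); property-level checks run at 2e5-3e5 photons.
Isotropic-escape runs default to 1e5 photons per plane.  Synthetic scenes
are 96x96 sensor pixels (192x192 fine grid), large enough that ROI means of
K_t are stable to <1 %.  Depth bins 10 um, radial bins 5 um; boundary planes
read the adjacent interior bin so entry-face normalization is exact.  Seeds
are split from a master seed by SHA-256 over a tag path; every stochastic
output records its seeds and sample sizes.

## Known limitations

* The step-2 return model is a reconstruction of an under-specified
  procedure; its transmissive-branch retentions carry a ~10-point systematic
  uncertainty (see above).
* Optical properties are the 633-nm skin values; no spectral extrapolation
  to the 785/850-nm imaging wavelengths is attempted.
* The phantom medium defaults to dermis coefficients (stated only as
  "similar reduced scattering"); override via the config interface.
* The in vivo/clinical analyses (vessel maps, reactive hyperemia traces)
  depend on camera data that were never deposited; the operations that would
  process them are implemented and validated synthetically.
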
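"""Two-step depth-resolved signal-to-background ratio (SBR) analysis.

The SBR of a signal layer is the fraction of detector-reaching light that
originated at that layer, relative to all candidate layers of the slab:

    SBR_k = flux_k * ret_k / sum_j flux_j * ret_j

Step 1 (illumination): a pencil beam is launched at the face implied by the
detection mode (top for reflective, bottom for transmissive) and the
near-axis flux density reaching each signal plane is read off the depth map,
normalized at the entry face.

Step 2 (signal return): the light re-emitted at each plane must cross the
tissue above it to reach the detector, which is always at the TOP face.  Two
models of this return attenuation are provided:

* ``"flux_return"`` (default) — the same near-axis flux-map decay, read from
  a dedicated top-launched transport run: light returning from depth z is
  attenuated like a narrow beam traversing thickness z.  This mirrors the
  two-step flux-map procedure the depth analysis is built on and reproduces
  its characteristic steep reflective decay.
* ``"isotropic_escape"`` — total weight escaping the top face from an
  isotropic point emitter at the plane.  Physically complete but nearly
  depth-blind in thin, weakly absorbing slabs (most multiply scattered light
  eventually escapes), so it cannot produce the observed retention losses;
  kept as a sensitivity control.  See docs/methods.md.

Thickness sweeps keep the signal layer fixed in the material while medium is
added above or below it, and report the retained SBR as a percentage of the
zero-added-thickness value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .photon_mc import (
    DEFAULT_AXIS_RADIUS_UM,
    FluxRatios,
    Source,
    fluence_at_planes,
    run_transport,
)
from .tissue_optics import (
    DepthPlanes,
    DetectionMode,
    LayeredTissue,
    make_layer,
    preset_geometry,
    regrid_planes,
)

__all__ = [
    "SbrProfile",
    "ThicknessSweepResult",
    "layer_flux_ratios",
    "escape_fraction_to_detector",
    "return_flux_ratios",
    "compute_sbr",
    "sbr_profile",
    "thickness_sweep",
    "relative_sbr_change",
    "DEFAULT_STEP1_PHOTONS",
    "DEFAULT_STEP2_PHOTONS",
]

DEFAULT_STEP1_PHOTONS = 1_000_000
DEFAULT_STEP2_PHOTONS = 100_000


def layer_flux_ratios(
    tissue: LayeredTissue,
    mode: DetectionMode | str,
    planes: DepthPlanes,
    n_photons: int = DEFAULT_STEP1_PHOTONS,
    seed: int = 0,
    axis_radius_um: float = DEFAULT_AXIS_RADIUS_UM,
    weighting: str = "axis",
) -> FluxRatios:
    """Step 1: illumination flux at each plane, normalized at the entry face."""
    mode = DetectionMode(mode)
    planes.validate_within(tissue)
    tallies = run_transport(tissue, Source.pencil(mode.source_face), n_photons, seed)
    return fluence_at_planes(
        tallies, planes, entry_face=mode.source_face,
        weighting=weighting, axis_radius_um=axis_radius_um,
    )


def return_flux_ratios(
    tissue: LayeredTissue,
    planes: DepthPlanes,
    n_photons: int = DEFAULT_STEP1_PHOTONS,
    seed: int = 0,
    axis_radius_um: float = DEFAULT_AXIS_RADIUS_UM,
) -> np.ndarray:
    """Step 2, flux-return model: attenuation of signal light returning from
    each plane depth to the top (detector) face, taken as the near-axis
    flux-map decay over that thickness (one top-launched transport run)."""
    planes.validate_within(tissue)
    tallies = run_transport(tissue, Source.pencil("top"), n_photons, seed)
    fr = fluence_at_planes(
        tallies, planes, entry_face="top", weighting="axis", axis_radius_um=axis_radius_um
    )
    return fr.values


def escape_fraction_to_detector(
    tissue: LayeredTissue,
    plane_depth_um: float,
    n_photons: int = DEFAULT_STEP2_PHOTONS,
    seed: int = 0,
) -> float:
    """Step 2, isotropic-escape model: fraction of an isotropic unit emission
    at ``plane_depth_um`` that escapes through the top (detector) face."""
    tallies = run_transport(
        tissue, Source.isotropic_point(plane_depth_um), n_photons, seed, score_fluence=False
    )
    return tallies.escaped_top


def compute_sbr(
    flux_ratios: np.ndarray, escape_fractions: np.ndarray, target_plane_index: int
) -> float:
    """Normalized signal share of one target plane; the shares over all planes
    of a configuration sum to exactly 1."""
    flux = np.asarray(flux_ratios, dtype=float)
    esc = np.asarray(escape_fractions, dtype=float)
    if flux.shape != esc.shape:
        raise ValueError("flux and escape arrays must have equal length")
    signal = flux * esc
    denom = signal.sum()
    if denom <= 0:
        raise ValueError("all flux*escape products are zero; SBR undefined")
    return float(signal[target_plane_index] / denom)


@dataclass(frozen=True)
class SbrProfile:
    """Per-plane SBR for one geometry and detection mode.

    ``escape_fractions`` holds the step-2 per-plane values under whichever
    return model produced the profile (normalized return-flux decay for
    ``flux_return``, top-escape probabilities for ``isotropic_escape``).
    """

    geometry: str
    mode: DetectionMode
    planes_um: tuple[float, ...]
    flux_ratios: np.ndarray
    escape_fractions: np.ndarray
    sbr: np.ndarray
    n_photons_step1: int
    n_photons_step2: int
    return_model: str = "flux_return"
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.sbr)
        if not np.isclose(s.sum(), 1.0, atol=1e-9):
            raise ValueError("SBR values must sum to 1")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("SBR values must lie in [0, 1]")

    def sbr_at(self, depth_um: float) -> float:
        idx = list(self.planes_um).index(depth_um)
        return float(self.sbr[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "geometry": self.geometry,
                "mode": self.mode.value,
                "plane_um": list(self.planes_um),
                "flux_ratio": self.flux_ratios,
                "escape_fraction": self.escape_fractions,
                "sbr": self.sbr,
            }
        )


def _profile_from_arrays(geometry, mode, planes, flux, esc, n1, n2, model, seeds) -> SbrProfile:
    signal = np.asarray(flux) * np.asarray(esc)
    denom = signal.sum()
    if denom <= 0:
        raise ValueError("all flux*escape products are zero; SBR undefined")
    return SbrProfile(
        geometry=geometry,
        mode=DetectionMode(mode),
        planes_um=tuple(planes.depths_um),
        flux_ratios=np.asarray(flux, dtype=float),
        escape_fractions=np.asarray(esc, dtype=float),
        sbr=signal / denom,
        n_photons_step1=n1,
        n_photons_step2=n2,
        return_model=model,
        seeds=seeds,
    )


def _step2_values(
    tissue, planes, return_model, n_photons, master_seed, tag
) -> tuple[np.ndarray, dict]:
    if return_model == "flux_return":
        s = derive_seed(master_seed, tag, "return")
        return return_flux_ratios(tissue, planes, n_photons, s), {f"{tag}/return": s}
    if return_model == "isotropic_escape":
        esc = np.empty(len(planes))
        seeds = {}
        for i, d in enumerate(planes.depths_um):
            s = derive_seed(master_seed, tag, "step2", d)
            seeds[f"{tag}/step2/{d}"] = s
            esc[i] = escape_fraction_to_detector(tissue, d, n_photons, s)
        return esc, seeds
    raise ValueError(f"unknown return model {return_model!r}")


def sbr_profile(
    geometry_name: str,
    mode: DetectionMode | str,
    n_photons_step1: int = DEFAULT_STEP1_PHOTONS,
    n_photons_step2: int | None = None,
    seed: int = 0,
    tissue: LayeredTissue | None = None,
    planes: DepthPlanes | None = None,
    return_model: str = "flux_return",
) -> SbrProfile:
    """Full two-step SBR profile for a preset (or explicit) geometry.

    Step 1 runs once per mode.  Step 2 runs one return-map transport
    (``flux_return``) or one isotropic-point transport per plane
    (``isotropic_escape``); by default it uses the step-1 photon count for the
    former and ``DEFAULT_STEP2_PHOTONS`` for the latter.  All seeds are split
    deterministically from ``seed``.
    """
    mode = DetectionMode(mode)
    if tissue is None or planes is None:
        tissue, planes, _meta = preset_geometry(geometry_name)
    if n_photons_step2 is None:
        n_photons_step2 = (
            n_photons_step1 if return_model == "flux_return" else DEFAULT_STEP2_PHOTONS
        )
    s1 = derive_seed(seed, geometry_name, "step1", mode.value)
    flux = layer_flux_ratios(tissue, mode, planes, n_photons_step1, s1)
    esc, seeds2 = _step2_values(
        tissue, planes, return_model, n_photons_step2, seed, geometry_name
    )
    seeds = {f"step1/{mode.value}": s1, **seeds2}
    return _profile_from_arrays(
        geometry_name, mode, planes, flux.values, esc,
        n_photons_step1, n_photons_step2, return_model, seeds,
    )


def sbr_profile_pair(
    geometry_name: str,
    modes: tuple[str, ...] = ("reflective", "transmissive"),
    n_photons_step1: int = DEFAULT_STEP1_PHOTONS,
    n_photons_step2: int | None = None,
    seed: int = 0,
    tissue: LayeredTissue | None = None,
    planes: DepthPlanes | None = None,
    return_model: str = "flux_return",
) -> dict[DetectionMode, SbrProfile]:
    """SBR profiles for several detection modes of one geometry, sharing the
    step-2 computation (which depends only on the geometry)."""
    if tissue is None or planes is None:
        tissue, planes, _meta = preset_geometry(geometry_name)
    if n_photons_step2 is None:
        n_photons_step2 = (
            n_photons_step1 if return_model == "flux_return" else DEFAULT_STEP2_PHOTONS
        )
    esc, seeds2 = _step2_values(
        tissue, planes, return_model, n_photons_step2, seed, geometry_name
    )
    out: dict[DetectionMode, SbrProfile] = {}
    for mode in (DetectionMode(m) for m in modes):
        s1 = derive_seed(seed, geometry_name, "step1", mode.value)
        flux = layer_flux_ratios(tissue, mode, planes, n_photons_step1, s1)
        out[mode] = _profile_from_arrays(
            geometry_name, mode, planes, flux.values, esc,
            n_photons_step1, n_photons_step2, return_model,
            {f"step1/{mode.value}": s1, **seeds2},
        )
    return out


def relative_sbr_change(sbr: float, sbr0: float) -> tuple[float, float]:
    """(percent change, retention percent) of an SBR relative to its baseline."""
    if sbr0 == 0:
        raise ValueError("baseline SBR is zero")
    return 100.0 * (sbr - sbr0) / sbr0, 100.0 * sbr / sbr0


@dataclass(frozen=True)
class ThicknessSweepResult:
    """SBR of a fixed signal layer as medium is added above or below it."""

    base_geometry: str
    side: str
    added_um: tuple[float, ...]
    modes: tuple[DetectionMode, ...]
    sbr: dict                 # mode -> array over added_um
    retention_pct: dict       # mode -> 100 * sbr / sbr[0]
    profiles: dict            # (mode, added) -> SbrProfile
    target_um: float

    def retention_at(self, mode: DetectionMode | str, added_um: float) -> float:
        mode = DetectionMode(mode)
        idx = list(self.added_um).index(added_um)
        return float(self.retention_pct[mode][idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode in self.modes:
            for i, a in enumerate(self.added_um):
                rows.append(
                    {
                        "geometry": self.base_geometry,
                        "side": self.side,
                        "mode": mode.value,
                        "added_um": a,
                        "sbr": self.sbr[mode][i],
                        "retention_pct": self.retention_pct[mode][i],
                    }
                )
        return pd.DataFrame(rows)


def _sweep_geometry(
    material: tuple,
    base_thickness_um: float,
    side: str,
    added_um: float,
    target_um: float,
    grid_um: float,
    plane_strategy: str,
) -> tuple[LayeredTissue, DepthPlanes, int]:
    """Thickened single-material slab, its plane set, and the target index.

    ``plane_strategy='regrid'`` places background planes on the base grid over
    the whole thickened slab (added tissue both attenuates and emits);
    ``'fixed'`` keeps only the original layer set (added tissue attenuates
    but contributes no background signal).
    """
    total = base_thickness_um + added_um
    n, mu_a, mu_s, g = material
    tissue = LayeredTissue(layers=(make_layer(n, mu_a, mu_s, g, total),))
    target_depth = target_um + added_um if side == "top" else target_um
    if plane_strategy == "regrid":
        planes = regrid_planes(total, grid_um)
    elif plane_strategy == "fixed":
        shift = added_um if side == "top" else 0.0
        base = list(np.arange(0.0, base_thickness_um, grid_um)) + [base_thickness_um]
        planes = DepthPlanes(tuple(d + shift for d in base))
    else:
        raise ValueError(f"unknown plane_strategy {plane_strategy!r}")
    depths = list(planes.depths_um)
    if target_depth not in depths:
        raise ValueError(f"target depth {target_depth} um not on the plane grid")
    return tissue, planes, depths.index(target_depth)


def thickness_sweep(
    base_geometry: str = "dermis_top_sweep",
    which_side: str | None = None,
    step_um: float | None = None,
    max_added_um: float | None = None,
    modes: tuple[str, ...] = ("reflective", "transmissive"),
    n_photons_step1: int = DEFAULT_STEP1_PHOTONS,
    n_photons_step2: int | None = None,
    seed: int = 0,
    plane_strategy: str = "regrid",
    return_model: str = "flux_return",
) -> ThicknessSweepResult:
    """Recompute the fixed target layer's SBR at each added-thickness step.

    Defaults come from the preset's sweep metadata (dermis sweeps: target at
    200 um of the 520-um dermis, +100-um steps to +400 um; phantom sweep:
    target at 0 mm of the 3.5-mm slab, +0.5-mm steps to +2 mm).  Step-2
    values depend only on geometry and are shared between modes.
    """
    _tissue0, _planes0, meta = preset_geometry(base_geometry)
    sweep_meta = meta.get("sweep")
    if sweep_meta is None:
        raise ValueError(f"preset {base_geometry!r} has no thickness-sweep schedule")
    side = which_side or sweep_meta["side"]
    if side not in ("top", "bottom"):
        raise ValueError(f"which_side must be 'top' or 'bottom', got {side!r}")
    step = step_um if step_um is not None else sweep_meta["step_um"]
    max_added = max_added_um if max_added_um is not None else sweep_meta["max_added_um"]
    target_um = sweep_meta["target_um"]
    material = sweep_meta["material"]
    base_thickness = sweep_meta["base_thickness_um"]
    grid_um = meta["grid_um"]
    mode_objs = tuple(DetectionMode(m) for m in modes)
    if n_photons_step2 is None:
        n_photons_step2 = (
            n_photons_step1 if return_model == "flux_return" else DEFAULT_STEP2_PHOTONS
        )

    added = tuple(np.arange(0.0, max_added + step / 2, step))
    sbr: dict = {m: np.empty(len(added)) for m in mode_objs}
    profiles: dict = {}

    for ai, a in enumerate(added):
        tissue, planes, target_idx = _sweep_geometry(
            material, base_thickness, side, a, target_um, grid_um, plane_strategy
        )
        tag = f"sweep/{side}/{a:g}"
        esc, seeds2 = _step2_values(tissue, planes, return_model, n_photons_step2, seed, tag)
        for mode in mode_objs:
            s1 = derive_seed(seed, "sweep", side, f"{a:g}", "step1", mode.value)
            flux = layer_flux_ratios(tissue, mode, planes, n_photons_step1, s1)
            prof = _profile_from_arrays(
                f"{base_geometry}+{a:g}um_{side}",
                mode,
                planes,
                flux.values,
                esc,
                n_photons_step1,
                n_photons_step2,
                return_model,
                {f"step1/{mode.value}": s1, **seeds2},
            )
            profiles[(mode, a)] = prof
            sbr[mode][ai] = prof.sbr[target_idx]

    retention = {m: 100.0 * sbr[m] / sbr[m][0] for m in mode_objs}
    return ThicknessSweepResult(
        base_geometry=base_geometry,
        side=side,
        added_um=added,
        modes=mode_objs,
        sbr=sbr,
        retention_pct=retention,
        profiles=profiles,
        target_um=target_um,
    )
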
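"""Variance-reduced photon transport through a layered slab.

The walk follows MCML conventions: photons carry a statistical weight,
absorption deposits the fraction mu_a/mu_t of the weight at each interaction
site, scattering deflects by a Henyey-Greenstein cosine, boundaries apply
unpolarized Fresnel reflection/refraction, and low-weight photons play
Russian roulette.  The slab is laterally infinite; lateral position is
tracked so that the flux density around a pencil-beam axis can be scored.

Fluence uses a track-length estimator (weight x path length per bin volume),
which is unbiased, has lower variance than absorption scoring, and remains
defined in non-absorbing layers.  Two views are tallied:

* ``fluence_z`` — planar (depth-only) fluence, i.e. the laterally integrated
  value per depth bin, relative to the incident irradiance;
* ``fluence_rz`` — cylindrical (depth x radius) flux density around the beam
  axis, the quantity a narrow-beam "light distribution" map shows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernel
from .tissue_optics import UM_PER_CM, DepthPlanes, LayeredTissue

__all__ = [
    "Source",
    "TransportTallies",
    "FluxRatios",
    "sample_free_path",
    "sample_hg_deflection",
    "fresnel_reflectance",
    "run_transport",
    "fluence_at_planes",
    "DEFAULT_AXIS_RADIUS_UM",
]

# Radial averaging radius around the pencil-beam axis.  The near-axis flux
# of a narrow beam depends on the radius it is averaged over; 35 um is the
# package's scoring resolution, calibrated once against the one stated
# depth-decay anchor of the slab model (surface flux ~ 2x the 200-um flux in
# 520-um dermis); see docs/methods.md.
DEFAULT_AXIS_RADIUS_UM = 35.0


def sample_free_path(mu_t: float, u: float) -> float:
    """Exponential free path -ln(u)/mu_t (cm) from a uniform draw u in (0, 1]."""
    if mu_t <= 0.0:
        raise ValueError("mu_t must be > 0 (mu_t = 0 is ballistic, handled by the caller)")
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u must lie in (0, 1], got {u}")
    return -np.log(u) / mu_t


def sample_hg_deflection(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine via the inverse CDF.

    For g = 0 the isotropic branch 2u - 1 is used.  E[cos theta] = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    return float(_kernel.hg_cos_theta(g, u))


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance; returns 1 beyond the critical angle."""
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_incident <= 1.0:
        raise ValueError(f"cos_incident must lie in [0, 1], got {cos_incident}")
    return float(_kernel.fresnel_unpolarized(n1, n2, cos_incident))


@dataclass(frozen=True)
class Source:
    """Photon source: a normally incident pencil beam at one face, or an
    isotropic point emitter at a given depth (used for the signal-return step)."""

    kind: Literal["pencil_beam_normal", "isotropic_point"]
    face: Literal["top", "bottom"] = "top"
    depth_um: float | None = None

    @classmethod
    def pencil(cls, face: str = "top") -> "Source":
        if face not in ("top", "bottom"):
            raise ValueError(f"face must be 'top' or 'bottom', got {face!r}")
        return cls(kind="pencil_beam_normal", face=face)

    @classmethod
    def isotropic_point(cls, depth_um: float) -> "Source":
        return cls(kind="isotropic_point", depth_um=float(depth_um))


@dataclass(frozen=True)
class TransportTallies:
    """Normalized Monte Carlo tallies for one transport run.

    ``fluence_z[i]`` is the planar fluence in depth bin ``[i*b, (i+1)*b)``
    relative to the incident irradiance; ``fluence_rz[i, j]`` is the flux
    density (per cm^2) in the annulus ``[j*dr, (j+1)*dr)`` around the beam
    axis.  ``fluence_rz`` is None when fluence scoring was disabled.
    """

    fluence_z: np.ndarray
    fluence_rz: np.ndarray | None
    bin_width_um: float
    r_bin_width_um: float
    escaped_top: float
    escaped_bottom: float
    absorbed: float
    n_photons: int
    seed: int

    @property
    def conservation_residual(self) -> float:
        return self.escaped_top + self.escaped_bottom + self.absorbed - 1.0

    def axis_fluence(self, radius_um: float = DEFAULT_AXIS_RADIUS_UM) -> np.ndarray:
        """Mean flux density within ``radius_um`` of the beam axis, per depth bin."""
        if self.fluence_rz is None:
            raise ValueError("run_transport was called with score_fluence=False")
        n_ann = max(1, int(round(radius_um / self.r_bin_width_um)))
        n_ann = min(n_ann, self.fluence_rz.shape[1])
        dr_cm = self.r_bin_width_um / UM_PER_CM
        edges = np.arange(n_ann + 1) * dr_cm
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        dens = self.fluence_rz[:, :n_ann] * areas  # back to deposited track length
        return dens.sum(axis=1) / areas.sum()

    def to_frame(self) -> pd.DataFrame:
        z = (np.arange(len(self.fluence_z)) + 0.5) * self.bin_width_um
        return pd.DataFrame({"depth_um": z, "fluence": self.fluence_z})

    def summary(self) -> dict:
        return {
            "escaped_top": self.escaped_top,
            "escaped_bottom": self.escaped_bottom,
            "absorbed": self.absorbed,
            "n_photons": self.n_photons,
            "seed": self.seed,
        }

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass(frozen=True)
class FluxRatios:
    """Per-plane flux values normalized to the source-entry face (entry = 1)."""

    planes_um: tuple[float, ...]
    values: np.ndarray
    entry_face: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("flux ratios must be >= 0")


def run_transport(
    tissue: LayeredTissue,
    source: Source,
    n_photons: int,
    seed: int,
    fluence_bin_um: float = 10.0,
    score_fluence: bool = True,
    r_bin_um: float = 5.0,
    n_r_bins: int = 120,
) -> TransportTallies:
    """Run the hop/drop/spin walk and return normalized tallies.

    Deterministic for fixed arguments.  ``score_fluence=False`` skips the
    track-length tallies (escape fractions only), which is substantially
    faster for signal-return runs.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if fluence_bin_um <= 0 or r_bin_um <= 0:
        raise ValueError("fluence bin widths must be > 0")

    D_um = tissue.total_thickness_um
    n_bins = max(1, int(np.ceil(D_um / fluence_bin_um - 1e-9)))
    bin_w_cm = fluence_bin_um / UM_PER_CM
    dr_cm = r_bin_um / UM_PER_CM

    if source.kind == "pencil_beam_normal":
        src_iso, src_face, src_depth_cm = 0, (0 if source.face == "top" else 1), 0.0
    elif source.kind == "isotropic_point":
        if source.depth_um is None or not 0.0 <= source.depth_um <= D_um:
            raise ValueError(f"isotropic point depth {source.depth_um} outside [0, {D_um}] um")
        src_iso, src_face, src_depth_cm = 1, 0, source.depth_um / UM_PER_CM
    else:  # pragma: no cover
        raise ValueError(f"unknown source kind {source.kind!r}")

    arrs = tissue.layer_arrays()
    a_z, a_rz, esc_top, esc_bot, absorbed = _kernel.transport_kernel(
        int(n_photons),
        int(seed),
        tissue.boundaries_cm(),
        arrs["n"],
        arrs["mu_a"],
        arrs["mu_s"],
        arrs["g"],
        float(tissue.ambient_n_top),
        float(tissue.ambient_n_bottom),
        src_face,
        src_iso,
        src_depth_cm,
        bin_w_cm,
        n_bins,
        1 if score_fluence else 0,
        dr_cm,
        int(n_r_bins),
    )

    if score_fluence:
        fluence_z = a_z / (n_photons * bin_w_cm)
        r_edges = np.arange(n_r_bins + 1) * dr_cm
        areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
        fluence_rz = a_rz / (n_photons * bin_w_cm * areas[None, :])
    else:
        fluence_z = np.full(n_bins, np.nan)
        fluence_rz = None

    return TransportTallies(
        fluence_z=fluence_z,
        fluence_rz=fluence_rz,
        bin_width_um=float(fluence_bin_um),
        r_bin_width_um=float(r_bin_um),
        escaped_top=esc_top / n_photons,
        escaped_bottom=esc_bot / n_photons,
        absorbed=absorbed / n_photons,
        n_photons=int(n_photons),
        seed=int(seed),
    )


def fluence_at_planes(
    tallies: TransportTallies,
    planes: DepthPlanes,
    entry_face: str = "top",
    weighting: str = "axis",
    axis_radius_um: float = DEFAULT_AXIS_RADIUS_UM,
) -> FluxRatios:
    """Read the flux bin containing each plane, normalized to the entry face.

    ``weighting='axis'`` (default) uses the near-axis flux density of the
    pencil beam — the quantity a narrow-beam illumination map shows over
    depth; ``'planar'`` uses the laterally integrated fluence.  Boundary
    planes (depth 0 or the full thickness) map to the adjacent interior bin,
    so the entry-face plane is exactly 1 by construction.
    """
    n_bins = len(tallies.fluence_z)
    if n_bins == 0 or tallies.n_photons == 0:
        raise ValueError("empty fluence tallies")
    if entry_face not in ("top", "bottom"):
        raise ValueError(f"entry_face must be 'top' or 'bottom', got {entry_face!r}")

    if weighting == "axis":
        profile = tallies.axis_fluence(axis_radius_um)
    elif weighting == "planar":
        profile = tallies.fluence_z
    else:
        raise ValueError(f"weighting must be 'axis' or 'planar', got {weighting!r}")

    total_um = n_bins * tallies.bin_width_um

    def plane_bin(d: float) -> int:
        b = int(np.floor(d / tallies.bin_width_um))
        return min(max(b, 0), n_bins - 1)

    entry_bin = 0 if entry_face == "top" else n_bins - 1
    ref = profile[entry_bin]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("entry-face flux is zero or undefined; cannot normalize")

    if planes.depths_um[-1] > total_um + tallies.bin_width_um:
        raise ValueError("planes extend beyond the tallied depth range")
    vals = np.array([profile[plane_bin(d)] for d in planes.depths_um]) / ref
    return FluxRatios(planes_um=planes.depths_um, values=vals, entry_face=entry_face)
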
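"""Layered optical media for slab photon transport.

A medium is an ordered stack of :class:`OpticalLayer` objects (top = detector
side, depth increasing downward).  Optical coefficients are kept in cm^-1, as
conventionally tabulated for skin; thicknesses are accepted in micrometres at
the interface and converted to cm internally.

The preset geometries bundled here are the slab configurations used to compare
reflective-detected and transmissive-detected speckle imaging at 633-nm skin
optical properties: a single 520-um dermis, a stratum corneum / epidermis /
dermis skin stack, top/bottom thickening sweeps around a fixed signal layer,
and millimetre-scale homogeneous phantoms.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

UM_PER_CM = 1.0e4

__all__ = [
    "OpticalLayer",
    "LayeredTissue",
    "DepthPlanes",
    "DetectionMode",
    "DetectionGeometry",
    "make_layer",
    "preset_geometry",
    "PRESET_NAMES",
    "DERMIS",
    "EPIDERMIS",
    "STRATUM_CORNEUM",
    "tissue_to_config",
    "tissue_from_config",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous slab layer.

    Parameters
    ----------
    refractive_index : float
        Real refractive index n (>= 1).
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s : float
        Scattering coefficient, cm^-1.
    anisotropy_g : float
        Henyey-Greenstein anisotropy factor, in [-1, 1].
    thickness_um : float
        Layer thickness in micrometres (> 0).
    """

    refractive_index: float
    mu_a: float
    mu_s: float
    anisotropy_g: float
    thickness_um: float

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.refractive_index}")
        if self.mu_a < 0.0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0.0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.anisotropy_g <= 1.0:
            raise ValueError(f"anisotropy g must lie in [-1, 1], got {self.anisotropy_g}")
        if not self.thickness_um > 0.0:
            raise ValueError(f"thickness must be > 0, got {self.thickness_um}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    @property
    def thickness_cm(self) -> float:
        return self.thickness_um / UM_PER_CM


def make_layer(n: float, mu_a: float, mu_s: float, g: float, thickness_um: float) -> OpticalLayer:
    """Validated construction of an :class:`OpticalLayer` (thickness in um)."""
    return OpticalLayer(
        refractive_index=float(n),
        mu_a=float(mu_a),
        mu_s=float(mu_s),
        anisotropy_g=float(g),
        thickness_um=float(thickness_um),
    )


# 633-nm skin optical properties (n, mu_a / cm^-1, mu_s / cm^-1, g)
STRATUM_CORNEUM = (1.50, 0.15, 175.0, 0.90)
EPIDERMIS = (1.34, 2.47, 87.5, 0.80)
DERMIS = (1.40, 0.28, 80.6, 0.82)


@dataclass(frozen=True)
class LayeredTissue:
    """Ordered layer stack, top (detector side) to bottom, plus ambient media."""

    layers: tuple[OpticalLayer, ...]
    ambient_n_top: float = 1.0
    ambient_n_bottom: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("LayeredTissue needs at least one layer")
        if self.ambient_n_top < 1.0 or self.ambient_n_bottom < 1.0:
            raise ValueError("ambient refractive indices must be >= 1")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def total_thickness_cm(self) -> float:
        return self.total_thickness_um / UM_PER_CM

    def boundaries_cm(self) -> np.ndarray:
        """Cumulative layer boundaries in cm: [0, d1, d1+d2, ...]."""
        t = np.array([l.thickness_cm for l in self.layers], dtype=np.float64)
        return np.concatenate([[0.0], np.cumsum(t)])

    def layer_arrays(self) -> dict[str, np.ndarray]:
        """Per-layer property arrays for the transport kernel."""
        return {
            "n": np.array([l.refractive_index for l in self.layers], dtype=np.float64),
            "mu_a": np.array([l.mu_a for l in self.layers], dtype=np.float64),
            "mu_s": np.array([l.mu_s for l in self.layers], dtype=np.float64),
            "g": np.array([l.anisotropy_g for l in self.layers], dtype=np.float64),
        }

    def layer_index_at(self, depth_um: float) -> int:
        """Index of the layer containing ``depth_um`` (bottom face -> last layer)."""
        if not 0.0 <= depth_um <= self.total_thickness_um:
            raise ValueError(f"depth {depth_um} um outside tissue [0, {self.total_thickness_um}]")
        edges = np.cumsum([l.thickness_um for l in self.layers])
        idx = int(np.searchsorted(edges, depth_um, side="right"))
        return min(idx, len(self.layers) - 1)


@dataclass(frozen=True)
class DepthPlanes:
    """Strictly increasing signal-layer depths, um, measured from the top face."""

    depths_um: tuple[float, ...]

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.depths_um)
        if len(d) < 1:
            raise ValueError("DepthPlanes needs at least one depth")
        if any(x < 0 for x in d):
            raise ValueError("depths must be >= 0")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths_um", d)

    def __len__(self) -> int:
        return len(self.depths_um)

    def validate_within(self, tissue: LayeredTissue) -> None:
        if self.depths_um[-1] > tissue.total_thickness_um + 1e-9:
            raise ValueError(
                f"deepest plane {self.depths_um[-1]} um exceeds tissue "
                f"thickness {tissue.total_thickness_um} um"
            )


class DetectionMode(str, enum.Enum):
    """Illumination/detection arrangement; detection is always at the top face."""

    REFLECTIVE = "reflective"
    TRANSMISSIVE = "transmissive"

    @property
    def source_face(self) -> str:
        return "top" if self is DetectionMode.REFLECTIVE else "bottom"


@dataclass(frozen=True)
class DetectionGeometry:
    mode: DetectionMode
    source_face: str = field(init=False)
    detector_face: str = field(default="top", init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", DetectionMode(self.mode))
        object.__setattr__(self, "source_face", self.mode.source_face)


def _single_material_tissue(props: tuple, thickness_um: float) -> LayeredTissue:
    n, mu_a, mu_s, g = props
    return LayeredTissue(layers=(make_layer(n, mu_a, mu_s, g, thickness_um),))


def regrid_planes(total_um: float, grid_um: float) -> DepthPlanes:
    """Planes at every ``grid_um`` from the top face, plus the bottom face."""
    depths = list(np.arange(0.0, total_um, grid_um))
    if not depths or depths[-1] < total_um:
        depths.append(total_um)
    return DepthPlanes(tuple(depths))


PRESET_NAMES = (
    "single_dermis_520",
    "skin_620",
    "dermis_top_sweep",
    "dermis_bottom_sweep",
    "phantom_5mm",
    "phantom_upper_sweep",
)


def preset_geometry(name: str) -> tuple[LayeredTissue, DepthPlanes, dict]:
    """Return (tissue, planes, metadata) for a named preset configuration.

    ``dermis_top_sweep`` / ``dermis_bottom_sweep`` and ``phantom_upper_sweep``
    return the zero-added-thickness base slab; their ``meta['sweep']`` entry
    describes the thickening schedule around the fixed signal layer.
    """
    if name == "single_dermis_520":
        tissue = _single_material_tissue(DERMIS, 520.0)
        planes = DepthPlanes((0, 100, 200, 300, 400, 500, 520))
        meta = {"name": name, "grid_um": 100.0}
    elif name == "skin_620":
        tissue = LayeredTissue(
            layers=(
                make_layer(*STRATUM_CORNEUM, 20.0),
                make_layer(*EPIDERMIS, 80.0),
                make_layer(*DERMIS, 520.0),
            )
        )
        planes = DepthPlanes((0, 20, 100, 200, 300, 400, 500, 600, 620))
        meta = {"name": name, "grid_um": 100.0}
    elif name in ("dermis_top_sweep", "dermis_bottom_sweep"):
        tissue = _single_material_tissue(DERMIS, 520.0)
        planes = DepthPlanes((0, 100, 200, 300, 400, 500, 520))
        meta = {
            "name": name,
            "grid_um": 100.0,
            "sweep": {
                "side": "top" if name == "dermis_top_sweep" else "bottom",
                "material": DERMIS,
                "base_thickness_um": 520.0,
                "target_um": 200.0,
                "step_um": 100.0,
                "max_added_um": 400.0,
            },
        }
    elif name == "phantom_5mm":
        tissue = _single_material_tissue(DERMIS, 5000.0)
        planes = regrid_planes(5000.0, 500.0)
        meta = {"name": name, "grid_um": 500.0}
    elif name == "phantom_upper_sweep":
        tissue = _single_material_tissue(DERMIS, 3500.0)
        planes = regrid_planes(3500.0, 500.0)
        meta = {
            "name": name,
            "grid_um": 500.0,
            "sweep": {
                "side": "top",
                "material": DERMIS,
                "base_thickness_um": 3500.0,
                "target_um": 0.0,
                "step_um": 500.0,
                "max_added_um": 2000.0,
            },
        }
    else:
        raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    planes.validate_within(tissue)
    return tissue, planes, meta


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

def tissue_to_config(
    tissue: LayeredTissue,
    planes: DepthPlanes | None = None,
    mode: DetectionMode | str | None = None,
) -> dict:
    cfg: dict = {
        "layers": [
            {
                "n": l.refractive_index,
                "mu_a_cm": l.mu_a,
                "mu_s_cm": l.mu_s,
                "g": l.anisotropy_g,
                "thickness_um": l.thickness_um,
            }
            for l in tissue.layers
        ],
        "ambient_n_top": tissue.ambient_n_top,
        "ambient_n_bottom": tissue.ambient_n_bottom,
    }
    if planes is not None:
        cfg["planes_um"] = list(planes.depths_um)
    if mode is not None:
        cfg["mode"] = DetectionMode(mode).value
    return cfg


def tissue_from_config(cfg: dict) -> tuple[LayeredTissue, DepthPlanes | None, DetectionMode | None]:
    layers = tuple(
        make_layer(d["n"], d["mu_a_cm"], d["mu_s_cm"], d["g"], d["thickness_um"])
        for d in cfg["layers"]
    )
    tissue = LayeredTissue(
        layers=layers,
        ambient_n_top=float(cfg.get("ambient_n_top", 1.0)),
        ambient_n_bottom=float(cfg.get("ambient_n_bottom", 1.0)),
    )
    planes = DepthPlanes(tuple(cfg["planes_um"])) if "planes_um" in cfg else None
    mode = DetectionMode(cfg["mode"]) if "mode" in cfg else None
    if planes is not None:
        planes.validate_within(tissue)
    return tissue, planes, mode


def save_config(path, tissue, planes=None, mode=None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(tissue_to_config(tissue, planes, mode), fh, sort_keys=False)


def load_config(path):
    with open(path) as fh:
        return tissue_from_config(yaml.safe_load(fh))
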
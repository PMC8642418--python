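"""End-to-end experiment suites.

Ties the two halves of the package together: the Monte Carlo depth/SBR
experiments (preset geometries, both detection modes, thickness sweeps) and
the synthetic speckle experiments (velocity, static-fraction and speckle-size
sweeps through the full analysis chain).  Every stochastic stage derives its
seed from the master seed via :func:`specklemode.derive_seed`, and each suite
writes a machine-readable manifest alongside its CSV outputs, so a suite is
byte-reproducible from (config, master seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .sbr_engine import (
    DEFAULT_STEP1_PHOTONS,
    sbr_profile_pair,
    thickness_sweep,
)
from .speckle_analysis import flow_index, roi_sbr, speckle_size, temporal_contrast
from .synthetic_speckle import (
    GeneratorParams,
    make_phantom_scene,
    pupil_fraction_for_speckle_size,
    render_stack,
)
from .tissue_optics import PRESET_NAMES

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_paper_suite", "run_synthetic_suite",
           "SBR_CSV_COLUMNS", "SWEEP_CSV_COLUMNS"]

# versioned output schemas; tests pin these
SBR_CSV_COLUMNS = ["geometry", "mode", "plane_um", "flux_ratio", "escape_fraction", "sbr"]
SWEEP_CSV_COLUMNS = ["geometry", "side", "mode", "added_um", "sbr", "retention_pct"]
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one suite run; serialized into the run manifest."""

    experiment: str
    seed: int = 0
    n_photons: int = DEFAULT_STEP1_PHOTONS
    out_dir: str = "."
    extra: dict = field(default_factory=dict)


def _write_manifest(out_dir: Path, config: RunConfig, outputs: dict) -> None:
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_paper_suite(
    out_dir, n_photons: int = DEFAULT_STEP1_PHOTONS, seed: int = 0
) -> dict:
    """All six preset geometries in both modes plus the two dermis thickness
    sweeps; writes one CSV per experiment and a retention summary JSON.

    Returns the summary dictionary (retention percentages at +200/+400 um for
    both modes and both thickening sides).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = RunConfig(experiment="paper_suite", seed=seed, n_photons=n_photons,
                       out_dir=str(out))
    outputs: dict = {}

    profile_presets = [p for p in PRESET_NAMES if "sweep" not in p]
    for preset in profile_presets:
        profiles = sbr_profile_pair(preset, n_photons_step1=n_photons,
                                    seed=derive_seed(seed, "paper_suite", preset))
        df = pd.concat([p.to_frame() for p in profiles.values()],
                       ignore_index=True)[SBR_CSV_COLUMNS]
        path = out / f"sbr_{preset}.csv"
        df.to_csv(path, index=False)
        outputs[f"sbr_{preset}"] = path.name
        log.info("wrote %s", path)

    summary: dict = {"n_photons": n_photons, "seed": seed, "retention_pct": {}}
    for side in ("top", "bottom"):
        sweep = thickness_sweep(
            f"dermis_{side}_sweep",
            n_photons_step1=n_photons,
            seed=derive_seed(seed, "paper_suite", "sweep", side),
        )
        df = sweep.to_frame()[SWEEP_CSV_COLUMNS]
        path = out / f"sweep_{side}.csv"
        df.to_csv(path, index=False)
        outputs[f"sweep_{side}"] = path.name
        summary["retention_pct"][side] = {
            mode.value: {
                "+200um": sweep.retention_at(mode, 200.0),
                "+400um": sweep.retention_at(mode, 400.0),
            }
            for mode in sweep.modes
        }
        log.info("wrote %s", path)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = "summary.json"
    _write_manifest(out, config, outputs)
    return summary


# synthetic-suite study conditions: the phantom-style velocity sweep
# (0 -> 4 mm/s), a static-fraction (depth-proxy) sweep, and a speckle-size
# sweep, all at the acquisition defaults (40 frames, 20 ms exposure)
VELOCITY_SWEEP_MM_S = (0.0, 0.5, 1.0, 2.0, 4.0)
STATIC_FRACTION_SWEEP = (0.0, 0.3, 0.5, 0.7, 0.9)
SPECKLE_SIZE_SWEEP_PX = (1.5, 2.5, 4.0)
_SUITE_STATIC_FRACTION = 0.7   # capillary under ~1 mm of turbid medium
_SUITE_READ_NOISE = 0.15       # camera noise floor, fraction of mean intensity
_SUITE_SHAPE = (96, 96)


def _scene_rois(scene):
    tube = scene.tube_mask
    rows = scene.shape[0]
    band = np.zeros(scene.shape, dtype=bool)
    band[: rows // 4, :] = True      # background strip clear of the tube
    return tube, band


def _tube_flow(stack, scene) -> float:
    fmap = flow_index(temporal_contrast(stack))
    tube, _ = _scene_rois(scene)
    return float(np.nanmean(fmap.values[tube]))


def run_synthetic_suite(
    out_dir,
    seed: int = 0,
    shape: tuple[int, int] = _SUITE_SHAPE,
    velocities: tuple[float, ...] = VELOCITY_SWEEP_MM_S,
    static_fractions: tuple[float, ...] = STATIC_FRACTION_SWEEP,
    speckle_sizes_px: tuple[float, ...] = SPECKLE_SIZE_SWEEP_PX,
) -> dict:
    """Velocity, static-fraction, and speckle-size sweeps through the full
    generate -> contrast -> flow-index -> ROI chain; one CSV per sweep.

    Defaults are the reference experimental conditions (phantom velocity range 0-4 mm/s,
    40-frame 20-ms acquisitions); smaller grids can be passed for quick runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = RunConfig(experiment="synthetic_suite", seed=seed, out_dir=str(out))
    outputs: dict = {}

    rows = []
    for v in velocities:
        scene = make_phantom_scene(_SUITE_STATIC_FRACTION, v, shape=shape)
        params = GeneratorParams(read_noise=_SUITE_READ_NOISE,
                                 seed=derive_seed(seed, "synth", "velocity", v))
        stack = render_stack(scene, params)
        rows.append({"velocity_mm_s": v, "tube_mean_flow_index": _tube_flow(stack, scene)})
    df_v = pd.DataFrame(rows)
    df_v.to_csv(out / "velocity_sweep.csv", index=False)
    outputs["velocity_sweep"] = "velocity_sweep.csv"

    rows = []
    for rho in static_fractions:
        scene = make_phantom_scene(rho, 2.0, shape=shape)
        params = GeneratorParams(read_noise=_SUITE_READ_NOISE,
                                 seed=derive_seed(seed, "synth", "static", rho))
        stack = render_stack(scene, params)
        fmap = flow_index(temporal_contrast(stack))
        tube, band = _scene_rois(scene)
        rows.append({"static_fraction": rho, "tube_roi_sbr": roi_sbr(fmap, tube, band)})
    df_s = pd.DataFrame(rows)
    df_s.to_csv(out / "static_fraction_sweep.csv", index=False)
    outputs["static_fraction_sweep"] = "static_fraction_sweep.csv"

    rows = []
    for target in speckle_sizes_px:
        scene = make_phantom_scene(_SUITE_STATIC_FRACTION, 2.0, shape=shape)
        params = GeneratorParams(
            pupil_fraction=pupil_fraction_for_speckle_size(target),
            seed=derive_seed(seed, "synth", "size", target),
        )
        stack = render_stack(scene, params)
        measured = speckle_size(stack.frames[0])
        tube, _ = _scene_rois(scene)
        kmap = temporal_contrast(stack)
        rows.append(
            {
                "target_size_px": target,
                "measured_size_px": measured,
                "tube_mean_contrast": float(np.nanmean(kmap.values[tube])),
            }
        )
    df_k = pd.DataFrame(rows)
    df_k.to_csv(out / "speckle_size_sweep.csv", index=False)
    outputs["speckle_size_sweep"] = "speckle_size_sweep.csv"

    _write_manifest(out, config, outputs)
    return {
        "velocity_sweep": df_v.to_dict("records"),
        "static_fraction_sweep": df_s.to_dict("records"),
        "speckle_size_sweep": df_k.to_dict("records"),
    }
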
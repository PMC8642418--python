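"""Temporal-contrast LSCI processing.

Per pixel, the temporal speckle contrast over a stack of frames is

    K_t(x, y) = sigma(x, y) / <I(x, y)>

with sigma the sample standard deviation over the frame axis, and the flow
index 1/K_t^2 a monotone qualitative surrogate of scatterer speed.  Relative
flow change against a pre-stimulus baseline is
DeltaFlow = (I_i - I_BL) / I_BL.  The module also provides speckle sizing by
the autocovariance-peak width, ROI quantification (vessel/background ratio
and background-subtracted signal), and line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "FrameStack",
    "ContrastMap",
    "FlowIndexMap",
    "FlowTimeSeries",
    "LineProfile",
    "temporal_contrast",
    "spatial_contrast",
    "flow_index",
    "delta_flow",
    "speckle_size",
    "background_subtracted_signal",
    "roi_sbr",
    "line_profile",
    "roi_mask",
    "exposure_energy_density",
    "read_stack",
    "write_stack",
    "write_map",
]

DEFAULT_EXPOSURE_MS = 20.0
DEFAULT_N_FRAMES = 40
DEFAULT_FLOW_CEILING = 1.0e4


@dataclass(frozen=True)
class FrameStack:
    """Raw speckle frames, shape (frames, rows, cols), intensities >= 0."""

    frames: np.ndarray
    exposure_ms: float = DEFAULT_EXPOSURE_MS

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError(f"frames must be 3-D (frames, rows, cols), got shape {f.shape}")
        if np.any(f < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ContrastMap:
    """Per-pixel temporal contrast K_t; invalid (zero-mean) pixels are NaN."""

    values: np.ndarray
    n_frames: int
    ddof: int = 1


@dataclass(frozen=True)
class FlowIndexMap:
    """Per-pixel 1/K_t^2, clamped at ``ceiling``; NaN pixels propagate."""

    values: np.ndarray
    ceiling: float


@dataclass(frozen=True)
class FlowTimeSeries:
    times: np.ndarray
    values: np.ndarray
    baseline: float
    delta_flow: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "flow_index": self.values, "delta_flow": self.delta_flow}
        )


@dataclass(frozen=True)
class LineProfile:
    positions_px: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_px": self.positions_px, "value": self.values})


def temporal_contrast(stack: FrameStack, ddof: int = 1) -> ContrastMap:
    """K_t = sigma / mean over the frame axis (sample std, N-1, by default).

    Pixels whose temporal mean is zero are flagged NaN rather than raising.
    """
    if stack.n_frames < 2:
        raise ValueError("temporal statistics need at least 2 frames")
    f = stack.frames.astype(np.float64)
    mean = f.mean(axis=0)
    sigma = f.std(axis=0, ddof=ddof)
    # constant series have sigma = 0 by definition; mask float rounding
    sigma[np.ptp(f, axis=0) == 0] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(mean > 0, sigma / mean, np.nan)
    return ContrastMap(values=k, n_frames=stack.n_frames, ddof=ddof)


def spatial_contrast(frame: np.ndarray, window: int = 7) -> np.ndarray:
    """Reference sliding-window spatial contrast K_s = local sigma / local mean
    of a single frame (uniform window, edges handled by nearest extension).

    Provided for comparison only; the analysis chain in this package is
    temporal-contrast based.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("spatial_contrast expects a single 2-D frame")
    if window < 2 or window > min(img.shape):
        raise ValueError("window must be >= 2 and fit inside the frame")
    mean = ndimage.uniform_filter(img, window, mode="nearest")
    mean_sq = ndimage.uniform_filter(img * img, window, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, np.sqrt(var) / mean, np.nan)


def flow_index(contrast: ContrastMap, ceiling: float = DEFAULT_FLOW_CEILING) -> FlowIndexMap:
    """1/K_t^2 with values above ``ceiling`` clamped (K_t = 0 maps to the
    ceiling); NaN (invalid) pixels propagate."""
    k = np.asarray(contrast.values, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = 1.0 / (k * k)
    v = np.where(np.isnan(k), np.nan, np.minimum(v, ceiling))
    return FlowIndexMap(values=v, ceiling=float(ceiling))


def delta_flow(
    series: Sequence[float],
    baseline_window: slice | Sequence[int],
    times: Sequence[float] | None = None,
) -> FlowTimeSeries:
    """Relative flow change (I_i - I_BL)/I_BL against the pre-stimulus
    baseline mean over ``baseline_window``."""
    vals = np.asarray(series, dtype=np.float64)
    if isinstance(baseline_window, slice):
        base = vals[baseline_window]
    else:
        base = vals[np.asarray(baseline_window, dtype=int)]
    if base.size == 0:
        raise ValueError("baseline window is empty")
    i_bl = float(base.mean())
    if i_bl == 0:
        raise ValueError("baseline flow intensity is zero")
    t = np.arange(len(vals), dtype=float) if times is None else np.asarray(times, dtype=float)
    return FlowTimeSeries(times=t, values=vals, baseline=i_bl, delta_flow=(vals - i_bl) / i_bl)


def _fwhm_from_profile(profile: np.ndarray) -> float:
    """Full width at half maximum of a symmetric peak centered at index 0
    (positive lags only), by linear interpolation between samples."""
    half = 0.5 * profile[0]
    below = np.nonzero(profile < half)[0]
    if below.size == 0:
        raise ValueError("autocovariance never falls below half maximum")
    j = below[0]
    if j == 0:
        return 0.0
    y0, y1 = profile[j - 1], profile[j]
    frac = (y0 - half) / (y0 - y1)
    return 2.0 * ((j - 1) + frac)


def speckle_size(image: np.ndarray) -> float:
    """Speckle grain size in pixels: FWHM of the central peak of the 2-D
    normalized autocovariance of the mean-subtracted image, averaged over the
    two axes.

    Invariant to global intensity scaling and offset.  For i.i.d. pixel noise
    the autocovariance is delta-like and the estimate is ~1 pixel.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("speckle_size expects a single 2-D frame")
    img = img - img.mean()
    var = np.mean(img * img)
    if var == 0:
        raise ValueError("constant image has no speckle")
    f = np.fft.fft2(img)
    acov = np.fft.ifft2(f * np.conj(f)).real / img.size / var  # circular, normalized
    rows = acov[: img.shape[0] // 2, 0]
    cols = acov[0, : img.shape[1] // 2]
    return 0.5 * (_fwhm_from_profile(rows) + _fwhm_from_profile(cols))


def roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    """Boolean mask from either a boolean array or a (r0, c0, r1, c1)
    half-open rectangle."""
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("mask shape does not match image")
        return roi
    r0, c0, r1, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"rectangle {roi} out of bounds for image {shape}")
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def _roi_mean(values: np.ndarray, mask: np.ndarray) -> float:
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(sel.mean())


def background_subtracted_signal(flow_map: FlowIndexMap | np.ndarray, signal_roi, background_roi) -> float:
    """Mean flow index over the signal ROI minus the background ROI mean."""
    values = flow_map.values if isinstance(flow_map, FlowIndexMap) else np.asarray(flow_map)
    ms = roi_mask(values.shape, signal_roi)
    mb = roi_mask(values.shape, background_roi)
    if np.any(ms & mb):
        raise ValueError("signal and background ROIs must be disjoint")
    return _roi_mean(values, ms) - _roi_mean(values, mb)


def roi_sbr(flow_map: FlowIndexMap | np.ndarray, vessel_roi, background_roi) -> float:
    """Vessel-mean / background-mean of the flow-index map.

    This is this package's operational vessel-to-background ratio for flow
    maps; acquisition software may normalize differently.
    """
    values = flow_map.values if isinstance(flow_map, FlowIndexMap) else np.asarray(flow_map)
    mv = roi_mask(values.shape, vessel_roi)
    mb = roi_mask(values.shape, background_roi)
    if np.any(mv & mb):
        raise ValueError("vessel and background ROIs must be disjoint")
    bg = _roi_mean(values, mb)
    if bg == 0:
        raise ValueError("background mean is zero")
    return _roi_mean(values, mv) / bg


def line_profile(
    flow_map: FlowIndexMap | np.ndarray,
    start_px: tuple[float, float],
    end_px: tuple[float, float],
    n_samples: int = 100,
) -> LineProfile:
    """Bilinear-interpolated samples of a map along the segment start->end
    (pixel coordinates, (row, col))."""
    values = flow_map.values if isinstance(flow_map, FlowIndexMap) else np.asarray(flow_map)
    for p in (start_px, end_px):
        if not (0 <= p[0] <= values.shape[0] - 1 and 0 <= p[1] <= values.shape[1] - 1):
            raise ValueError(f"endpoint {p} out of bounds for map {values.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    rr = start_px[0] + t * (end_px[0] - start_px[0])
    cc = start_px[1] + t * (end_px[1] - start_px[1])
    samples = ndimage.map_coordinates(values, np.vstack([rr, cc]), order=1, mode="nearest")
    length = float(np.hypot(end_px[0] - start_px[0], end_px[1] - start_px[1]))
    return LineProfile(positions_px=t * length, values=samples)


def exposure_energy_density(power_mw_cm2: float, exposure_ms: float, n_frames: int) -> float:
    """Total delivered energy density in mJ/cm^2 for an acquisition:
    power (mW/cm^2) x exposure (ms) x frames.  1 mW*ms = 1 uJ."""
    return power_mw_cm2 * exposure_ms * n_frames / 1000.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stack(path, exposure_ms: float = DEFAULT_EXPOSURE_MS, n_frames: int | None = None) -> FrameStack:
    """Read a multi-page TIFF stack; optionally truncate to ``n_frames``."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if n_frames is not None:
        arr = arr[:n_frames]
    return FrameStack(frames=arr.astype(np.float64), exposure_ms=exposure_ms)


def write_stack(path, stack: FrameStack, dtype=np.uint16, scale: float | None = None) -> None:
    """Write frames as multi-page TIFF.  For integer dtypes the stack is
    scaled so the maximum maps near the top of the range (or by ``scale``)."""
    f = stack.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        top = np.iinfo(dtype).max
        s = scale if scale is not None else (0.95 * top / max(f.max(), 1e-12))
        f = np.clip(f * s, 0, top).astype(dtype)
    else:
        f = f.astype(dtype)
    tifffile.imwrite(path, f)


def write_map(path, map_obj) -> None:
    """Write a contrast or flow map as 32-bit float TIFF."""
    values = map_obj.values if hasattr(map_obj, "values") else np.asarray(map_obj)
    tifffile.imwrite(path, values.astype(np.float32))
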
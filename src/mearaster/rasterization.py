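"""IMFI-windowed raster-plot images.

The inter-maximum-frequency interval (IMFI) of a well is the typical
spacing between successive network bursts' peak-firing-rate times in the
pre-drug (vehicle) epoch.  Every epoch of that well is segmented into
non-overlapping windows of width 4 x IMFI — wide enough to capture the
regularity of the burst rhythm while normalizing away inter-well
differences in burst frequency — and each window is rendered as a
raster-plot image (electrodes as 16 horizontal bands, time on the x
axis, spikes as dark dots) ready for deep feature extraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from mearaster.mea_io import N_ELECTRODES, ConditionLabel, WellRecording
from mearaster.burst_analysis import NetworkBurst

__all__ = [
    "ImfiEstimate",
    "RasterWindow",
    "RenderConfig",
    "RasterImage",
    "estimate_imfi",
    "segment_windows",
    "render_raster",
    "export_png",
]


@dataclass(frozen=True)
class ImfiEstimate:
    """Per-well IMFI (seconds), estimated from the vehicle epoch.

    ``imfi_s`` is the median of successive differences of the network
    bursts' pooled-rate peak times.
    """

    well_id: str
    imfi_s: float
    n_intervals: int
    source: str = "vehicle"

    def __post_init__(self):
        if self.imfi_s <= 0:
            raise ValueError("imfi_s must be positive")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")


@dataclass(frozen=True)
class RasterWindow:
    """One 4 x IMFI slice of an epoch; spike times are offsets from t0."""

    well_id: str
    condition: ConditionLabel
    t0: float
    width: float
    spikes: tuple[tuple[int, float], ...]  # (electrode, offset in [0, width))
    window_index: int = 0

    def __post_init__(self):
        for e, off in self.spikes:
            if not 0 <= off < self.width:
                raise ValueError("spike offset outside window")
            if not 0 <= e < N_ELECTRODES:
                raise ValueError("electrode out of range")


@dataclass(frozen=True)
class RenderConfig:
    """Raster rendering knobs: image size, dot size, intensities.

    Default 227x227 matches the feature backbone's input size; black
    single-pixel dots on a white background (1 px keeps within-burst
    ink roughly proportional to spike count instead of saturating).
    """

    height: int = 227
    width: int = 227
    dot_px: int = 1
    background: int = 255
    foreground: int = 0

    def __post_init__(self):
        if self.height < N_ELECTRODES or self.width < 1 or self.dot_px < 1:
            raise ValueError("invalid render geometry")


@dataclass(frozen=True)
class RasterImage:
    """Rendered raster window: H x W uint8 pixels + provenance."""

    pixels: np.ndarray
    well_id: str
    condition: ConditionLabel
    window_index: int


def estimate_imfi(
    vehicle_rec: WellRecording, bursts: Sequence[NetworkBurst]
) -> ImfiEstimate:
    """IMFI = median spacing of successive burst peak-rate times.

    Requires at least two network bursts in the vehicle epoch; with
    fewer the window width is undefined and the well must be excluded.
    """
    if not vehicle_rec.condition.is_vehicle:
        warnings.warn(
            f"well {vehicle_rec.well_id}: IMFI estimated from a non-vehicle epoch",
            stacklevel=2,
        )
    if len(bursts) < 2:
        raise ValueError(
            f"well {vehicle_rec.well_id}: {len(bursts)} network burst(s) in the "
            "vehicle epoch; >= 2 required to define the IMFI window width"
        )
    peaks = np.array([b.peak_rate_time for b in bursts])
    diffs = np.diff(np.sort(peaks))
    return ImfiEstimate(
        well_id=vehicle_rec.well_id,
        imfi_s=float(np.median(diffs)),
        n_intervals=int(diffs.size),
    )


def segment_windows(rec: WellRecording, imfi: ImfiEstimate) -> list[RasterWindow]:
    """Tile an epoch into floor(duration / 4 IMFI) windows of width 4 IMFI.

    Windows are anchored at the epoch start; the trailing partial window
    is discarded.  Spike times become offsets from each window's t0.
    """
    if imfi.well_id != rec.well_id:
        raise ValueError(f"IMFI of well {imfi.well_id} applied to well {rec.well_id}")
    width = 4.0 * imfi.imfi_s
    n_win = int(math.floor(rec.duration_s / width))
    if n_win == 0:
        warnings.warn(
            f"well {rec.well_id}: window width {width:.3g}s exceeds epoch "
            f"duration {rec.duration_s}s; no windows",
            stacklevel=2,
        )
        return []
    windows = []
    for i in range(n_win):
        t0 = i * width
        spikes = []
        for train in rec.spike_trains:
            t = train.times
            sel = t[(t >= t0) & (t < t0 + width)]
            spikes.extend((train.electrode_index, float(x - t0)) for x in sel)
        windows.append(
            RasterWindow(
                well_id=rec.well_id,
                condition=rec.condition,
                t0=float(t0),
                width=float(width),
                spikes=tuple(spikes),
                window_index=i,
            )
        )
    return windows


def render_raster(window: RasterWindow, cfg: RenderConfig | None = None) -> RasterImage:
    """Render a window as a raster-plot image.

    Electrode e occupies horizontal band e of 16 equal bands (electrode
    0 at the top); time maps linearly to columns over [0, width); each
    spike is a ``dot_px`` x ``dot_px`` foreground square anchored at the
    band origin.  Deterministic.
    """
    cfg = cfg or RenderConfig()
    img = np.full((cfg.height, cfg.width), cfg.background, dtype=np.uint8)
    band_h = cfg.height / N_ELECTRODES
    for elec, off in window.spikes:
        row = int(elec * band_h)
        col = int(off / window.width * cfg.width)
        col = min(col, cfg.width - 1)
        img[row : row + cfg.dot_px, col : col + cfg.dot_px] = cfg.foreground
    return RasterImage(
        pixels=img,
        well_id=window.well_id,
        condition=window.condition,
        window_index=window.window_index,
    )


def export_png(image: RasterImage, out_dir) -> Path:
    """Write a raster image as PNG with a provenance-encoding filename."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    c = image.condition
    conc = "vehicle" if c.is_vehicle else f"{c.concentration:g}{c.concentration_unit}"
    name = f"{image.well_id}__{c.compound}__{conc}__{image.window_index:04d}.png"
    path = out_dir / name
    Image.fromarray(image.pixels, mode="L").save(path)
    return path
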
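"""End-to-end digitization: scanned page (or single strip) → mV/ms leads.

Per lead crop, in order: HSV segmentation of the trace, thinning,
signal removal + grid isolation + scale-factor estimation, column-wise
trace extraction, baseline alignment by the signal mode, R-peak
amplitude correction, unit conversion.  The scale factor actually used
is the mean over all crops of the page, since each crop's grid carries
different discontinuities where the trace was removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from . import grid as _grid
from . import mask as _mask
from . import reconstruct as _rec
from .image_io import CropRegion, crop_image
from .reconstruct import DigitizedLead

__all__ = ["PipelineConfig", "estimate_crop_scale", "digitize_crop", "digitize_page"]

_REFERENCE_DPI = 600.0  # resolution at which the closing/area defaults were set


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: _mask.MaskThresholds = _mask.DEFAULT_THRESHOLDS
    thin_iterations: int = 3
    gray_band: _grid.GrayBand = _grid.DEFAULT_GRAY_BAND
    close_width: int = 16
    min_area: int = 1000
    square_mm: float = _grid.SQUARE_MM
    column_reduce: str = "mean"
    peak_delta_mm: float = 1.0
    peak_count: int = 5
    min_peak_separation_ms: float = 200.0
    hr_hint_bpm: float | None = None
    dpi: float | None = None  # rescales close_width/min_area from 600 dpi defaults

    @property
    def scaled_close_width(self) -> int:
        if self.dpi is None:
            return self.close_width
        return max(1, int(round(self.close_width * self.dpi / _REFERENCE_DPI)))

    @property
    def scaled_min_area(self) -> int:
        if self.dpi is None:
            return self.min_area
        return max(1, int(round(self.min_area * (self.dpi / _REFERENCE_DPI) ** 2)))


def estimate_crop_scale(
    crop: np.ndarray, cfg: PipelineConfig = PipelineConfig()
) -> _grid.GridEstimate:
    """Scale factor of one crop: segment the trace, remove it, isolate
    and consolidate the grid, measure the 5 mm squares."""
    signal = _mask.extract_signal_mask(crop, cfg.thresholds)
    cleaned = _grid.remove_signal(crop, signal)
    gmask = _grid.grid_mask(cleaned, cfg.gray_band)
    lines = _grid.consolidate_grid(
        gmask, se_width=cfg.scaled_close_width, min_area=cfg.scaled_min_area
    )
    return _grid.estimate_scale_factor(lines, square_mm=cfg.square_mm)


def digitize_crop(
    crop: np.ndarray, sf: float, cfg: PipelineConfig = PipelineConfig()
) -> DigitizedLead:
    """Digitize one lead crop using an already-estimated scale factor."""
    signal = _mask.extract_signal_mask(crop, cfg.thresholds)
    thinned = _mask.thin_mask(signal, iterations=cfg.thin_iterations)
    trace = _rec.trace_from_mask(thinned, reduce=cfg.column_reduce)
    mm = _rec.baseline_align(trace.amplitude * sf, sf_mm_per_px=sf)
    ms_per_sample = sf / _rec.PAPER_SPEED_MM_PER_S * 1000.0
    k = cfg.peak_count
    if cfg.hr_hint_bpm is not None:
        duration_s = len(mm) * ms_per_sample / 1000.0
        k = max(1, int(round(duration_s * cfg.hr_hint_bpm / 60.0)))
    peaks = _rec.detect_r_peaks(
        mm,
        k=k,
        min_separation_ms=cfg.min_peak_separation_ms,
        ms_per_sample=ms_per_sample,
    )
    corrected = _rec.correct_peak_amplitudes(mm, peaks, delta_mm=cfg.peak_delta_mm)
    return _rec.to_physical_units(corrected, sf)


def digitize_page(
    image: np.ndarray,
    regions: Mapping[str, CropRegion],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[dict[str, DigitizedLead], dict[str, _grid.GridEstimate], float]:
    """Digitize every lead of a scanned page.

    Returns the digitized leads, the per-crop grid estimates, and the
    mean scale factor (mm/px) that was applied to all leads.
    """
    if not regions:
        raise ValueError("no crop regions supplied")
    crops = {name: crop_image(image, reg) for name, reg in regions.items()}
    estimates = {name: estimate_crop_scale(c, cfg) for name, c in crops.items()}
    sf = _grid.mean_scale_factor(list(estimates.values()))
    leads = {name: digitize_crop(c, sf, cfg) for name, c in crops.items()}
    return leads, estimates, sf
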
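"""Graph-paper grid isolation and pixel→millimeter scale calibration.

ECG paper carries a fixed grid of 5 mm coarse squares (subdivided into
1 mm fine squares), so the physical size of a pixel can be recovered
from the image itself.  The procedure, per lead crop:

1. whiten the trace pixels (``remove_signal``);
2. keep mid-gray pixels — grayscale value in a band away from both the
   near-black fine marks and the white background (``grid_mask``);
3. morphologically close the result to join dotted grid marks into
   continuous lines, and drop small connected components
   (``consolidate_grid``);
4. measure the enclosed square interiors: with mean interior area A and
   grid line width w, the square side is L = sqrt(A) + w pixels and the
   scale factor is SF = 5 / L millimeters per pixel
   (``estimate_scale_factor``).

The per-crop scale factors of one page are averaged (``mean_scale_factor``)
because signal removal leaves different discontinuities in each crop's
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.measure import label, regionprops
from skimage.morphology import closing, footprint_rectangle

__all__ = [
    "GrayBand",
    "GridEstimate",
    "remove_signal",
    "grid_mask",
    "consolidate_grid",
    "estimate_scale_factor",
    "mean_scale_factor",
    "DEFAULT_GRAY_BAND",
    "SQUARE_MM",
]

SQUARE_MM = 5.0  # coarse grid square side on standard ECG paper


class GridEstimationError(RuntimeError):
    """No usable grid squares could be found in a crop."""


@dataclass(frozen=True)
class GrayBand:
    """Inclusive grayscale band (0–255) that counts as grid ink."""

    low: int = 100
    high: int = 220

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 255):
            raise ValueError("band must satisfy 0 <= low < high <= 255")


DEFAULT_GRAY_BAND = GrayBand()


@dataclass(frozen=True)
class GridEstimate:
    """Detected square side L (px) and derived scale factor (mm/px)."""

    L: float
    n_squares: int
    line_width: float
    square_mm: float = SQUARE_MM

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("square side must be positive")
        if self.n_squares < 1:
            raise ValueError("at least one square required")

    @property
    def SF(self) -> float:
        """Scale factor: millimeters per pixel, SF = 5/L."""
        return self.square_mm / self.L


def remove_signal(crop: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Whiten the trace pixels so only background and grid remain."""
    signal = np.asarray(signal, dtype=bool)
    if signal.shape != crop.shape[:2]:
        raise ValueError(
            f"mask shape {signal.shape} does not match crop {crop.shape[:2]}"
        )
    out = crop.copy()
    out[signal] = 255
    return out


def grid_mask(crop: np.ndarray, band: GrayBand = DEFAULT_GRAY_BAND) -> np.ndarray:
    """Keep pixels whose luminance lies inside the mid-gray band.

    The band excludes both near-black marks and the white background
    (including the whitened trace), leaving the grid ink.
    """
    gray = rgb2gray(crop) * 255.0
    eps = 1e-6  # keep the inclusive bounds exact despite float luminance weights
    return (gray >= band.low - eps) & (gray <= band.high + eps)


def consolidate_grid(
    mask: np.ndarray, se_width: int = 16, min_area: int = 1000
) -> np.ndarray:
    """Close gaps in the grid and drop small connected components.

    Morphological closing with a ``se_width`` × ``se_width`` square
    joins nearby dots into continuous lines; every 8-connected component
    with area strictly below ``min_area`` pixels is then removed.  The
    defaults suit 600 dpi scans and should be scaled linearly
    (quadratically for ``min_area``) with resolution.
    """
    if se_width < 1:
        raise ValueError("structuring element width must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    closed = closing(mask, footprint_rectangle((se_width, se_width)))
    lbl = label(closed, connectivity=2)
    counts = np.bincount(lbl.ravel())
    keep = counts >= min_area
    keep[0] = False  # background
    return keep[lbl]


def estimate_scale_factor(
    gridlines: np.ndarray,
    square_mm: float = SQUARE_MM,
    line_width: float | None = None,
) -> GridEstimate:
    """Estimate the scale factor from the consolidated grid of one crop.

    Square interiors are the 8-connected background components fully
    enclosed by grid pixels; components touching the crop border are
    partial squares and are excluded, as are interiors whose area is an
    outlier (outside [0.6, 1.8] × median) — discontinuities left by
    signal removal can fuse adjacent squares or split one.  The inner side is
    sqrt(mean interior area); adding one grid-line width gives the
    square side L, and SF = square_mm / L.
    """
    gridlines = np.asarray(gridlines, dtype=bool)
    if not gridlines.any():
        raise GridEstimationError("grid mask is empty")
    lbl = label(~gridlines, connectivity=2)
    border = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    areas = np.array(
        [p.area for p in regionprops(lbl) if p.label not in set(border)],
        dtype=float,
    )
    if areas.size == 0:
        raise GridEstimationError(
            "no fully enclosed grid squares found (grid too sparse or crop too small)"
        )
    med = np.median(areas)
    areas = areas[(areas >= 0.6 * med) & (areas <= 1.8 * med)]
    if line_width is None:
        line_width = _measure_line_width(gridlines)
    inner = float(np.sqrt(areas.mean()))
    return GridEstimate(
        L=inner + line_width,
        n_squares=int(areas.size),
        line_width=float(line_width),
        square_mm=square_mm,
    )


def mean_scale_factor(estimates: list[GridEstimate]) -> float:
    """Arithmetic mean of per-crop scale factors (mm/px)."""
    if not estimates:
        raise ValueError("need at least one grid estimate")
    return float(np.mean([e.SF for e in estimates]))


def _measure_line_width(gridlines: np.ndarray, fallback: float = 1.0) -> float:
    """Median run length of grid-pixel runs crossing the grid lines.

    Scanning rows and columns of the mask, a run of foreground pixels is
    either a perpendicular crossing of a line (length ≈ line width, the
    overwhelming majority) or a stretch along a line (long).  Runs
    longer than a quarter of the crop side are discarded before taking
    the median.
    """
    h, w = gridlines.shape
    cap = max(2.0, min(h, w) / 4.0)
    runs: list[np.ndarray] = []
    for arr in (gridlines, gridlines.T):
        padded = np.pad(arr, ((0, 0), (1, 1)))
        diff = np.diff(padded.astype(np.int8), axis=1)
        starts = np.nonzero(diff == 1)
        ends = np.nonzero(diff == -1)
        runs.append(ends[1] - starts[1])
    lengths = np.concatenate(runs)
    lengths = lengths[lengths < cap]
    if lengths.size == 0:
        return fallback
    return float(np.median(lengths))
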
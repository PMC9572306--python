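"""Trace segmentation: HSV color thresholding and morphological thinning.

The ECG trace is separated from the graph-paper background by keeping
every pixel whose HSV coordinates (all channels scaled to [0, 1]) fall
inside three closed intervals, then thinned to a quasi-one-pixel curve.
The default intervals were tuned for 600 dpi scans of thermal ECG paper
with contrast/sharpness boosted during scanning:

    0.000 <= H <= 0.997,  0.000 <= S <= 0.659,  0.647 <= V <= 1.000

Hue is treated as a plain closed interval (no wraparound): the upper
bound 0.997 deliberately excludes a narrow slice of pure-red hue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import thin as _thin

__all__ = ["MaskThresholds", "extract_signal_mask", "thin_mask", "DEFAULT_THRESHOLDS"]

Interval = tuple[float, float]


@dataclass(frozen=True)
class MaskThresholds:
    """Closed HSV intervals classifying a pixel as trace ink."""

    h_range: Interval = (0.000, 0.997)
    s_range: Interval = (0.000, 0.659)
    v_range: Interval = (0.647, 1.000)

    def __post_init__(self) -> None:
        for lo, hi in (self.h_range, self.s_range, self.v_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("each interval must satisfy 0 <= lo <= hi <= 1")


DEFAULT_THRESHOLDS = MaskThresholds()


def extract_signal_mask(
    crop: np.ndarray, thresholds: MaskThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Return a boolean mask of trace pixels in an RGB crop.

    A pixel is foreground iff all three of its HSV channel values fall
    inside the corresponding closed interval.  The test is pixel-wise:
    no neighborhood information is used.
    """
    if crop.size == 0:
        raise ValueError("empty crop")
    hsv = rgb2hsv(crop)
    (hl, hh), (sl, sh), (vl, vh) = (
        thresholds.h_range,
        thresholds.s_range,
        thresholds.v_range,
    )
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return (
        (h >= hl) & (h <= hh) & (s >= sl) & (s <= sh) & (v >= vl) & (v <= vh)
    )


def thin_mask(mask: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Thin a binary mask by ``iterations`` passes of morphological thinning.

    Thinning only ever removes pixels and preserves the 8-connectivity
    of each component, so the trace stays a single curve; repeated
    application beyond convergence is a no-op.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    return _thin(np.asarray(mask, dtype=bool), max_num_iter=iterations)
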
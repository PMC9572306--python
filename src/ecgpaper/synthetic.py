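"""Synthetic ground truth: ECG waveform generator and graph-paper renderer.

``generate_ecg`` emulates a patient simulator: a PQRST-like waveform
built from parameterized Gaussian bumps, with exactly known fiducial
sample indices, configurable heart rate, R amplitude, R-R jitter and
additive noise.  At the default 60 bpm the beat template reproduces the
standard textbook intervals used as ground truth throughout the test
suite: QRS 88 ms, QT 368 ms, PQ 164 ms, P-wave 86 ms, R-R 1000 ms.

``render_paper`` emulates the print-then-scan chain: the waveform is
drawn at 25 mm/s and 10 mm/mV onto graph paper with 1 mm fine and 5 mm
coarse squares, in either of two grid dialects (a dot grid, or solid
lines), at a configurable scale (mm per pixel, i.e. scanner
resolution).  Ink colors are chosen so that the trace falls inside the
default HSV segmentation window while grid ink falls outside it but
inside the grayscale grid band — the same contrast structure that the
boosted-contrast scans the pipeline was designed for exhibit.  The
renderer returns the exact pixel column of every signal sample, so
every pipeline stage can be checked against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFilter

from .image_io import ReferenceECG
from .validate import FiducialSet

__all__ = [
    "EcgSimConfig",
    "RenderConfig",
    "RenderGroundTruth",
    "generate_ecg",
    "render_paper",
    "TRACE_INK",
    "GRID_DOT_INK",
    "GRID_LINE_INK",
    "FINE_LINE_INK",
    "BACKGROUND",
]

# Ink palette (RGB).  Chosen against the default segmentation thresholds:
# the trace is a desaturated bright blue (inside the HSV window, below the
# grayscale grid band); grid ink is too dark in V for the HSV window but
# mid-gray in luminance (inside the 100-220 grid band); the background and
# the fine 1 mm rules are light but strongly saturated (S > 0.659), so
# neither is mistaken for trace ink, and both are brighter than 220 in
# luminance, so neither is mistaken for grid.
TRACE_INK = (80, 80, 200)
GRID_DOT_INK = (110, 110, 110)
GRID_LINE_INK = (160, 110, 110)
FINE_LINE_INK = (250, 240, 60)
BACKGROUND = (255, 255, 80)

# Beat template: Gaussian bump (center ms, sigma ms, relative amplitude),
# offsets relative to QRS onset.  Fiducial offsets follow the template.
_BUMPS = {
    "P": (-121.0, 14.0, 0.17),
    "Q": (12.0, 4.0, -0.12),
    "R": (40.0, 9.0, 1.00),
    "S": (72.0, 5.0, -0.20),
    "T": (300.0, 24.0, 0.30),
}
_FIDUCIAL_OFFSETS_MS = {
    "p_onset": -164.0,
    "p_offset": -78.0,
    "qrs_onset": 0.0,
    "r": 40.0,
    "qrs_offset": 88.0,
    "t_offset": 368.0,
}
_FIRST_QRS_ONSET_MS = 200.0


@dataclass(frozen=True)
class EcgSimConfig:
    """Simulated recording conditions (one printed strip)."""

    hr_bpm: float = 60.0
    amplitude_mV: float = 1.0
    duration_s: float = 5.0
    fs_hz: float = 500.0
    rhythm: str = "sinus"  # sinus | irregular_rr | noisy
    noise_amplitude_mV: float = 0.0
    rr_jitter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20 <= self.hr_bpm <= 300):
            raise ValueError("heart rate must be in [20, 300] bpm")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs_hz < 100:
            raise ValueError("sampling frequency must be >= 100 Hz")
        if self.rhythm not in ("sinus", "irregular_rr", "noisy"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and inks of the printed/scanned strip."""

    sf_true: float = 0.05  # mm per pixel
    grid_style: str = "dots"  # dots | lines
    paper_speed: float = 25.0  # mm/s
    gain: float = 10.0  # mm/mV
    height_mm: float = 40.0
    margin_mm: float = 5.0
    baseline_mm: float = 22.5  # from top; off the 1 mm lattice on purpose
    trace_width_mm: float = 0.3
    dot_radius_mm: float = 0.1
    dot_pitch_mm: float = 0.5  # dot spacing along the 5 mm rules
    blur_sigma: float = 0.0
    max_width_px: int = 20000
    trace_color: tuple[int, int, int] = TRACE_INK
    grid_color: tuple[int, int, int] | None = None
    background_color: tuple[int, int, int] = BACKGROUND

    def __post_init__(self) -> None:
        if self.sf_true <= 0:
            raise ValueError("scale factor must be positive")
        if self.grid_style not in ("dots", "lines"):
            raise ValueError(f"unknown grid style {self.grid_style!r}")

    @classmethod
    def from_dpi(cls, dpi: float, **kwargs) -> "RenderConfig":
        return cls(sf_true=25.4 / dpi, **kwargs)


@dataclass
class RenderGroundTruth:
    """Exact geometry of a rendered strip."""

    sf_true: float
    baseline_row: float
    columns: np.ndarray  # pixel column of each signal sample
    rows: np.ndarray  # pixel row of each signal sample

    @property
    def col_start(self) -> int:
        return int(self.columns[0])

    @property
    def col_end(self) -> int:
        return int(self.columns[-1])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sf_true": self.sf_true,
                    "baseline_row": self.baseline_row,
                    "columns": self.columns.tolist(),
                    "rows": self.rows.tolist(),
                },
                fh,
            )


def generate_ecg(config: EcgSimConfig) -> tuple[ReferenceECG, FiducialSet]:
    """Simulate one lead strip with exactly known fiducials.

    Beats are placed at R-R = 60000/HR ms (optionally jittered); each
    beat is a sum of P/Q/R/S/T Gaussian bumps.  At high rates the beat
    template is compressed (shorter QT, as real hearts do) so that
    successive beats do not collide.  The waveform is normalized so the
    R peak equals ``amplitude_mV`` exactly.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    t_ms = np.arange(n) * 1000.0 / config.fs_hz
    rr_ms = 60000.0 / config.hr_bpm
    jitter = config.rr_jitter_fraction
    if config.rhythm == "irregular_rr" and jitter == 0.0:
        jitter = 0.05
    noise = config.noise_amplitude_mV
    if config.rhythm == "noisy" and noise == 0.0:
        noise = 0.05

    # compress the beat template at high rates so QT < RR
    scale = float(np.clip(rr_ms / 500.0, 0.4, 1.0))

    onsets = []
    t0 = _FIRST_QRS_ONSET_MS * scale
    duration_ms = config.duration_s * 1000.0
    while t0 + _FIDUCIAL_OFFSETS_MS["t_offset"] * scale < duration_ms:
        if t0 + _FIDUCIAL_OFFSETS_MS["p_onset"] * scale >= 0:
            onsets.append(t0)
        step = rr_ms * (1.0 + jitter * rng.uniform(-1.0, 1.0)) if jitter else rr_ms
        t0 += step

    v = np.zeros(n)
    for onset in onsets:
        for center, sigma, amp in _BUMPS.values():
            c = onset + center * scale
            v += amp * np.exp(-0.5 * ((t_ms - c) / (sigma * scale)) ** 2)
    peak = v.max()
    if peak > 0:
        v *= config.amplitude_mV / peak
    if noise:
        v = v + rng.normal(0.0, noise, size=n)

    to_idx = lambda ms: int(round(ms * config.fs_hz / 1000.0))
    fid = FiducialSet(
        **{
            name: np.array([to_idx(onset + off * scale) for onset in onsets])
            for name, off in _FIDUCIAL_OFFSETS_MS.items()
        }
    )
    return ReferenceECG(leads={"II": v}, fs_hz=config.fs_hz), fid


def render_paper(
    ecg: ReferenceECG,
    cfg: RenderConfig = RenderConfig(),
    lead: str | None = None,
) -> tuple[np.ndarray, RenderGroundTruth]:
    """Draw one lead onto graph paper; return the image and geometry.

    Horizontal advance is ``paper_speed * t / sf_true`` pixels from the
    left margin; vertical deflection is ``gain * v / sf_true`` pixels
    about the baseline row.  The trace is a hard-edged polyline so its
    ink color is exact; an optional Gaussian blur emulates scanner
    softness.
    """
    name = lead or ecg.lead_names[0]
    v = ecg.leads[name]
    t_s = np.arange(len(v)) / ecg.fs_hz
    sf = cfg.sf_true
    width_mm = 2 * cfg.margin_mm + cfg.paper_speed * t_s[-1]
    width_px = int(round(width_mm / sf)) + 1
    height_px = int(round(cfg.height_mm / sf))
    if width_px > cfg.max_width_px:
        raise ValueError(
            f"strip would be {width_px} px wide (max {cfg.max_width_px})"
        )

    im = Image.new("RGB", (width_px, height_px), cfg.background_color)
    draw = ImageDraw.Draw(im)
    if cfg.grid_style == "dots":
        _draw_dot_grid(draw, width_px, height_px, cfg)
    else:
        _draw_line_grid(draw, width_px, height_px, cfg)

    x_px = (cfg.margin_mm + cfg.paper_speed * t_s) / sf
    baseline_row = cfg.baseline_mm / sf
    y_px = baseline_row - cfg.gain * v / sf
    pts = list(zip(x_px.tolist(), y_px.tolist()))
    w = max(1, int(round(cfg.trace_width_mm / sf)))
    draw.line(pts, fill=cfg.trace_color, width=w, joint="curve")

    if cfg.blur_sigma > 0:
        im = im.filter(ImageFilter.GaussianBlur(cfg.blur_sigma))
    img = np.asarray(im, dtype=np.uint8)
    gt = RenderGroundTruth(
        sf_true=sf,
        baseline_row=float(baseline_row),
        columns=np.round(x_px).astype(int),
        rows=np.asarray(y_px),
    )
    return img, gt


def _mm_positions(extent_px: int, pitch_mm: float, sf: float) -> np.ndarray:
    return np.arange(0.0, extent_px * sf + 1e-9, pitch_mm) / sf


def _dot(draw: ImageDraw.ImageDraw, x: float, y: float, side: int, color) -> None:
    half = (side - 1) / 2.0
    draw.rectangle([round(x - half), round(y - half),
                    round(x - half) + side - 1, round(y - half) + side - 1],
                   fill=color)


def _draw_dot_grid(draw: ImageDraw.ImageDraw, w: int, h: int, cfg: RenderConfig) -> None:
    """Dot-grid dialect: dense dots trace the 5 mm rules; sparse lattice
    dots mark the 1 mm crossings.  Dots shrink with resolution so that
    the lattice stays unconnected while the rule dots stay joinable."""
    sf = cfg.sf_true
    color = cfg.grid_color or GRID_DOT_INK
    side = max(1, int(round(2 * cfg.dot_radius_mm / sf)))
    fine_side = max(1, int(round(1.6 * cfg.dot_radius_mm / sf)))
    coarse_x = _mm_positions(w, 5.0, sf)
    coarse_y = _mm_positions(h, 5.0, sf)
    along_x = _mm_positions(w, cfg.dot_pitch_mm, sf)
    along_y = _mm_positions(h, cfg.dot_pitch_mm, sf)
    for x in coarse_x:
        for y in along_y:
            _dot(draw, x, y, side, color)
    for y in coarse_y:
        for x in along_x:
            _dot(draw, x, y, side, color)
    for x in _mm_positions(w, 1.0, sf):
        for y in _mm_positions(h, 1.0, sf):
            _dot(draw, x, y, fine_side, color)


def _draw_line_grid(draw: ImageDraw.ImageDraw, w: int, h: int, cfg: RenderConfig) -> None:
    """Solid-line dialect: light 1 mm rules under heavier 5 mm rules."""
    sf = cfg.sf_true
    color = cfg.grid_color or GRID_LINE_INK
    fine_w = max(1, int(round(0.08 / sf)))
    coarse_w = max(1, int(round(0.2 / sf)))
    for x in _mm_positions(w, 1.0, sf):
        draw.line([(x, 0), (x, h)], fill=FINE_LINE_INK, width=fine_w)
    for y in _mm_positions(h, 1.0, sf):
        draw.line([(0, y), (w, y)], fill=FINE_LINE_INK, width=fine_w)
    for x in _mm_positions(w, 5.0, sf):
        draw.line([(x, 0), (x, h)], fill=color, width=coarse_w)
    for y in _mm_positions(h, 5.0, sf):
        draw.line([(0, y), (w, y)], fill=color, width=coarse_w)
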
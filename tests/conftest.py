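"""Shared fixtures: cached end-to-end digitization runs.

The closed loop (generate → render → digitize → align → compare) is the
expensive part of the suite, so it is computed once per configuration
and shared across tests through a session-scoped factory fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import ecgpaper as ep


@dataclass
class ClosedLoopResult:
    ecg: ep.ReferenceECG
    fiducials: ep.FiducialSet
    sf_true: float
    estimate: ep.GridEstimate
    lead: ep.DigitizedLead
    peaks: ep.PeakSet
    r: float
    image_shape: tuple[int, int]


def run_closed_loop(
    hr: float = 60.0,
    grid_style: str = "dots",
    sf_true: float = 0.05,
    seed: int = 1,
    duration_s: float = 5.0,
) -> ClosedLoopResult:
    """Render a clean sinus strip and digitize it end to end."""
    ecg, fid = ep.generate_ecg(
        ep.EcgSimConfig(hr_bpm=hr, duration_s=duration_s, seed=seed)
    )
    img, gt = ep.render_paper(
        ecg, ep.RenderConfig(sf_true=sf_true, grid_style=grid_style)
    )
    region = ep.CropRegion(
        gt.col_start, 0, gt.col_end - gt.col_start + 1, img.shape[0]
    )
    crop = ep.crop_image(img, region)
    cfg = ep.PipelineConfig(hr_hint_bpm=hr, dpi=25.4 / sf_true)
    estimate = ep.estimate_crop_scale(crop, cfg)
    lead = ep.digitize_crop(crop, estimate.SF, cfg)
    peaks = ep.detect_r_peaks(
        lead.voltage_mV * 10.0,
        k=fid.n_beats,
        ms_per_sample=lead.step_ms,
    )
    y, y_tilde = ep.align_and_resample(
        lead,
        ecg,
        (int(peaks.indices[0]), int(peaks.indices[-1])),
        (int(fid.r[0]), int(fid.r[-1])),
    )
    return ClosedLoopResult(
        ecg=ecg,
        fiducials=fid,
        sf_true=sf_true,
        estimate=estimate,
        lead=lead,
        peaks=peaks,
        r=ep.pearson_r(y, y_tilde),
        image_shape=img.shape[:2],
    )


@pytest.fixture(scope="session")
def closed_loop():
    """Memoized factory: closed_loop(hr=..., grid_style=..., sf_true=...)."""
    cache: dict[tuple, ClosedLoopResult] = {}

    def get(**kwargs) -> ClosedLoopResult:
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            cache[key] = run_closed_loop(**kwargs)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sim60():
    """Default 60 bpm / 1 mV / 5 s / 500 Hz simulated strip."""
    return ep.generate_ecg(ep.EcgSimConfig(seed=1))
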
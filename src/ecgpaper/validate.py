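"""Validation of digitized ECGs against a digital reference.

Covers the full validation methodology for a paper-ECG digitizer:

* anchor-based alignment and rational-ratio resampling of the digitized
  lead onto the reference's 500 Hz time base (polyphase FIR
  anti-aliasing resampler);
* whole-signal similarity via the Pearson correlation coefficient

      r = (n Σ y ỹ − Σy Σỹ) / sqrt([n Σy² − (Σy)²][n Σỹ² − (Σỹ)²]);

* the six standard ECG time parameters (QRS duration, QT, PQ, P-wave
  duration, mean R-R, heart rate = 60000/RR) from fiducial sample
  indices;
* absolute error aE = |X_experimental − X_true| and its millimeter
  equivalent at 25 mm/s paper speed (1 mm = 40 ms), since 1 mm — the
  grid resolution — is the acceptability bound for a paper digitizer;
* repeatability statistics (mean, sample SD, range) over repeated runs.

Fiducial points are inputs: in practice they come from manual
annotation.  ``delineate_clean`` is a threshold-crossing helper for
synthetic, noise-free waveforms only; it is not a clinical delineator.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import resample_poly

from .reconstruct import PAPER_SPEED_MM_PER_S, detect_r_peaks

__all__ = [
    "FiducialSet",
    "TimeParameters",
    "ValidationReport",
    "RepeatabilityStats",
    "align_and_resample",
    "pearson_r",
    "compute_time_parameters",
    "absolute_error",
    "ms_to_mm",
    "heart_rate_bpm",
    "repeatability_stats",
    "compare_parameters",
    "delineate_clean",
]


@dataclass
class FiducialSet:
    """Per-beat landmark sample indices (0-based).

    Order within each beat must be
    P_onset < P_offset <= QRS_onset < R < QRS_offset < T_offset.
    """

    p_onset: np.ndarray
    p_offset: np.ndarray
    qrs_onset: np.ndarray
    r: np.ndarray
    qrs_offset: np.ndarray
    t_offset: np.ndarray

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, np.atleast_1d(np.asarray(getattr(self, f.name), dtype=int)))
        n = {len(getattr(self, f.name)) for f in fields(self)}
        if len(n) != 1:
            raise ValueError("all fiducial arrays must have the same number of beats")
        ok = (
            (self.p_onset < self.p_offset)
            & (self.p_offset <= self.qrs_onset)
            & (self.qrs_onset < self.r)
            & (self.r < self.qrs_offset)
            & (self.qrs_offset < self.t_offset)
        )
        if not ok.all():
            raise ValueError("fiducials out of order within a beat")

    @property
    def n_beats(self) -> int:
        return len(self.r)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("beat,P_on,P_off,QRS_on,R,QRS_off,T_off\n")
            for b in range(self.n_beats):
                fh.write(
                    f"{b},{self.p_onset[b]},{self.p_offset[b]},{self.qrs_onset[b]},"
                    f"{self.r[b]},{self.qrs_offset[b]},{self.t_offset[b]}\n"
                )

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        data = np.genfromtxt(path, delimiter=",", names=True, dtype=int)
        data = np.atleast_1d(data)
        return cls(
            p_onset=data["P_on"],
            p_offset=data["P_off"],
            qrs_onset=data["QRS_on"],
            r=data["R"],
            qrs_offset=data["QRS_off"],
            t_offset=data["T_off"],
        )


@dataclass
class TimeParameters:
    """The six standard ECG time parameters."""

    qrs_ms: float
    qt_ms: float
    pq_ms: float
    p_wave_ms: float
    rr_ms: float

    @property
    def hr_bpm(self) -> float:
        return heart_rate_bpm(self.rr_ms)

    def as_dict(self) -> dict[str, float]:
        return {
            "qrs_ms": self.qrs_ms,
            "qt_ms": self.qt_ms,
            "pq_ms": self.pq_ms,
            "p_wave_ms": self.p_wave_ms,
            "rr_ms": self.rr_ms,
            "hr_bpm": self.hr_bpm,
        }


@dataclass
class ValidationReport:
    """Similarity plus per-parameter absolute errors (ms/bpm and mm)."""

    r: float
    abs_errors: dict[str, float]
    abs_errors_mm: dict[str, float]


@dataclass
class RepeatabilityStats:
    """Per-parameter mean, sample SD (n−1) and range over repeated tests."""

    mean: dict[str, float]
    sd: dict[str, float]
    range: dict[str, float]


def align_and_resample(
    digitized,
    reference,
    anchors_dig: tuple[int, int],
    anchors_ref: tuple[int, int],
    lead: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a digitized lead onto the reference time base and align.

    Two corresponding landmark samples (typically two R peaks) are
    identified in each signal.  The digitized lead is resampled by the
    rational ratio of the anchor gaps with a polyphase FIR anti-aliasing
    filter, so that afterwards the same number of samples separates the
    anchors in both signals; shifting the first anchors onto each other
    then overlaps the signals.  Returns the equal-length overlapping
    segments ``(y, y_tilde)`` — reference first — on the reference's
    sampling grid.
    """
    a1d, a2d = anchors_dig
    a1r, a2r = anchors_ref
    if a2d <= a1d or a2r <= a1r:
        raise ValueError("anchors must be strictly increasing")
    y_ref = np.asarray(
        reference.leads[lead] if lead is not None else next(iter(reference.leads.values())),
        dtype=float,
    )
    x = np.asarray(digitized.voltage_mV, dtype=float)
    ratio = Fraction(int(a2r - a1r), int(a2d - a1d))
    x_rs = resample_poly(x, ratio.numerator, ratio.denominator)
    a1_rs = int(round(a1d * ratio))
    # place resampled anchor a1_rs onto reference anchor a1r
    shift = a1r - a1_rs
    lo = max(0, shift)
    hi = min(len(y_ref), len(x_rs) + shift)
    if hi <= lo:
        raise ValueError("aligned signals do not overlap")
    return y_ref[lo:hi], x_rs[lo - shift : hi - shift]


def pearson_r(y: np.ndarray, y_tilde: np.ndarray) -> float:
    """Pearson correlation coefficient via the covariance formula.

    Computed on mean-centered vectors — algebraically identical to the
    raw-sums form of the definition but numerically stable when the
    signals carry a large offset.
    """
    y = np.asarray(y, dtype=float)
    yt = np.asarray(y_tilde, dtype=float)
    if y.shape != yt.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    dy = y - y.mean()
    dyt = yt - yt.mean()
    den2 = (dy * dy).sum() * (dyt * dyt).sum()
    if den2 <= 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((dy * dyt).sum() / np.sqrt(den2), -1.0, 1.0))


def compute_time_parameters(fiducials: FiducialSet, sampling_hz: float) -> TimeParameters:
    """Interval durations (ms) from fiducial indices, averaged over beats.

    R-R is the mean of successive R-peak differences and needs at least
    two beats; heart rate follows as 60000/RR.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling frequency must be positive")
    if fiducials.n_beats < 2:
        raise ValueError("need at least two beats for the R-R interval")
    to_ms = 1000.0 / sampling_hz
    return TimeParameters(
        qrs_ms=float(np.mean(fiducials.qrs_offset - fiducials.qrs_onset)) * to_ms,
        qt_ms=float(np.mean(fiducials.t_offset - fiducials.qrs_onset)) * to_ms,
        pq_ms=float(np.mean(fiducials.qrs_onset - fiducials.p_onset)) * to_ms,
        p_wave_ms=float(np.mean(fiducials.p_offset - fiducials.p_onset)) * to_ms,
        rr_ms=float(np.mean(np.diff(fiducials.r))) * to_ms,
    )


def absolute_error(x_experimental: float, x_true: float) -> float:
    """aE = |X_experimental − X_true|."""
    return abs(x_experimental - x_true)


def ms_to_mm(duration_ms: float, paper_speed: float = PAPER_SPEED_MM_PER_S) -> float:
    """Convert a duration to its width on paper: mm = ms · speed / 1000."""
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    return duration_ms * paper_speed / 1000.0


def heart_rate_bpm(rr_ms: float) -> float:
    """HR = 60000 / RR."""
    if rr_ms <= 0:
        raise ValueError("R-R interval must be positive")
    return 60000.0 / rr_ms


def repeatability_stats(
    runs: Sequence[TimeParameters] | Mapping[str, Sequence[float]],
) -> RepeatabilityStats:
    """Mean, sample SD (n−1 denominator) and range per parameter.

    Accepts either a list of :class:`TimeParameters` (repeated
    measurements of the same strip) or a mapping of parameter name to
    value sequence (e.g. including the scale factor).
    """
    if isinstance(runs, Mapping):
        table = {k: np.asarray(v, dtype=float) for k, v in runs.items()}
    else:
        table = {
            k: np.array([run.as_dict()[k] for run in runs])
            for k in ("qrs_ms", "qt_ms", "pq_ms", "p_wave_ms", "rr_ms", "hr_bpm")
        }
    n = {len(v) for v in table.values()}
    if len(n) != 1 or n.pop() < 2:
        raise ValueError("need at least two runs of equal length")
    return RepeatabilityStats(
        mean={k: float(v.mean()) for k, v in table.items()},
        sd={k: float(v.std(ddof=1)) for k, v in table.items()},
        range={k: float(v.max() - v.min()) for k, v in table.items()},
    )


def compare_parameters(
    experimental: TimeParameters, true: TimeParameters, r: float = np.nan
) -> ValidationReport:
    """Absolute errors per parameter, with mm equivalents for durations."""
    ae = {
        k: absolute_error(experimental.as_dict()[k], true.as_dict()[k])
        for k in experimental.as_dict()
    }
    ae_mm = {k: ms_to_mm(v) for k, v in ae.items() if k.endswith("_ms")}
    return ValidationReport(r=float(r), abs_errors=ae, abs_errors_mm=ae_mm)


def delineate_clean(
    voltage_mV: np.ndarray,
    fs_hz: float,
    n_beats: int | None = None,
    threshold_mV: float = 0.03,
    min_separation_ms: float = 200.0,
) -> FiducialSet:
    """Threshold-crossing delineation of a clean synthetic waveform.

    Intended only for validating the digitization pipeline on rendered
    test waveforms whose baseline is exactly zero between waves: wave
    onsets/offsets are the |v| crossings of ``threshold_mV`` around each
    deflection.  Not suitable for real ECGs.
    """
    v = np.asarray(voltage_mV, dtype=float)
    ms_per_sample = 1000.0 / fs_hz
    k = n_beats if n_beats is not None else max(1, int(len(v) * ms_per_sample / 1000))
    peaks = detect_r_peaks(v, k=k, min_separation_ms=min_separation_ms,
                           ms_per_sample=ms_per_sample)
    active = np.abs(v) > threshold_mV
    beats = []
    half_rr = (np.median(np.diff(peaks.indices)) / 2 if len(peaks) > 1
               else len(v))
    for r_idx in peaks.indices:
        lo = int(max(0, r_idx - half_rr))
        hi = int(min(len(v), r_idx + half_rr))
        # QRS bounds: contiguous active run containing R
        q = r_idx
        while q > lo and active[q - 1]:
            q -= 1
        s = r_idx
        while s < hi - 1 and active[s + 1]:
            s += 1
        # P wave: last active run ending before QRS onset
        p_off = q - 1
        while p_off > lo and not active[p_off]:
            p_off -= 1
        p_on = p_off
        while p_on > lo and active[p_on - 1]:
            p_on -= 1
        # T wave: last active run before the window end
        t_off = hi - 1
        while t_off > s and not active[t_off]:
            t_off -= 1
        if not (p_on < p_off <= q < r_idx < s < t_off):
            continue  # incomplete beat at a strip edge
        beats.append((p_on, p_off, q, r_idx, s, t_off))
    if not beats:
        raise ValueError("no complete beat found")
    arr = np.array(beats).T
    return FiducialSet(
        p_onset=arr[0], p_offset=arr[1], qrs_onset=arr[2],
        r=arr[3], qrs_offset=arr[4], t_offset=arr[5],
    )
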
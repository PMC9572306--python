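"""Image and reference-signal I/O.

Images are plain ``uint8`` H×W×3 numpy arrays with the origin at the
top-left corner and row indices increasing downward.  Crop regions are
0-based, half-open in both axes: ``[y0, y0+height) × [x0, x0+width)``.

Reference ECGs (the "true" digital signal an electrocardiograph exports
alongside the paper printout) use a deliberately minimal schema:

* CSV — a first comment line ``# fs_hz=<float>``, then a header row of
  lead names, then one row per sample, amplitudes in mV.
* XML — ``<ecg fs="500"><lead name="II">v1 v2 …</lead>…</ecg>``,
  amplitudes in mV.

Digitized output is written one CSV per lead (columns ``time_ms,
voltage_mV``) plus a combined file, or as plots over a pink 1 mm/5 mm
grid mimicking ECG graph paper.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from PIL import Image, UnidentifiedImageError

if TYPE_CHECKING:  # pragma: no cover
    from .reconstruct import DigitizedLead

__all__ = [
    "CropRegion",
    "ReferenceECG",
    "load_image",
    "crop_image",
    "read_reference",
    "write_digitized",
]


@dataclass(frozen=True)
class CropRegion:
    """Axis-aligned rectangle selecting one lead strip on a scanned page."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("crop origin must be non-negative")
        if self.width < 1 or self.height < 1:
            raise ValueError("crop extent must be at least 1×1")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


@dataclass
class ReferenceECG:
    """Digital reference signal: per-lead amplitude vectors in mV."""

    leads: dict[str, np.ndarray]
    fs_hz: float

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling frequency must be positive")
        if not self.leads:
            raise ValueError("at least one lead required")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged lead lengths: {sorted(lengths)}")
        self.leads = {k: np.asarray(v, dtype=float) for k, v in self.leads.items()}

    @property
    def lead_names(self) -> list[str]:
        return list(self.leads)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.fs_hz


def load_image(path: str | Path) -> np.ndarray:
    """Load a raster image (PNG/JPEG/TIFF) as an H×W×3 uint8 array.

    Grayscale sources are replicated to three channels; alpha channels
    are dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0 or arr.ndim != 3:
        raise ValueError(f"zero-size or malformed image: {path}")
    return arr


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write an H×W×3 uint8 array (or H×W bool mask) to disk as PNG."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = (arr * np.uint8(255)).astype(np.uint8)
    Image.fromarray(arr).save(path)


def crop_image(img: np.ndarray, region: CropRegion) -> np.ndarray:
    """Extract a crop; raises if the region exceeds the image bounds."""
    h, w = img.shape[:2]
    if region.y0 + region.height > h or region.x0 + region.width > w:
        raise ValueError(
            f"crop {region} out of bounds for {h}×{w} image"
        )
    return img[region.slices].copy()


def read_reference(path: str | Path, format: str | None = None) -> ReferenceECG:
    """Read a reference ECG from the minimal CSV or XML schema.

    The format is inferred from the file extension when not given.
    """
    path = Path(path)
    fmt = format or ("xml" if path.suffix.lower() == ".xml" else "csv")
    if fmt == "csv":
        return _read_reference_csv(path)
    if fmt == "xml":
        return _read_reference_xml(path)
    raise ValueError(f"unknown reference format: {fmt!r}")


def _read_reference_csv(path: Path) -> ReferenceECG:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs_hz=" not in first:
            raise ValueError(f"{path}: missing '# fs_hz=' comment line")
        fs = float(first.split("fs_hz=")[1])
        header = [c.strip() for c in fh.readline().strip().split(",")]
        rows = [line.strip().split(",") for line in fh if line.strip()]
    if any(len(r) != len(header) for r in rows):
        raise ValueError(f"{path}: ragged rows")
    data = np.asarray(rows, dtype=float)
    leads = {name: data[:, j] for j, name in enumerate(header)}
    return ReferenceECG(leads=leads, fs_hz=fs)


def _read_reference_xml(path: Path) -> ReferenceECG:
    root = ET.parse(path).getroot()
    if root.tag != "ecg" or "fs" not in root.attrib:
        raise ValueError(f"{path}: expected <ecg fs=...> root")
    fs = float(root.attrib["fs"])
    leads: dict[str, np.ndarray] = {}
    for el in root.findall("lead"):
        name = el.attrib.get("name", f"lead{len(leads)}")
        leads[name] = np.asarray((el.text or "").split(), dtype=float)
    return ReferenceECG(leads=leads, fs_hz=fs)


def write_reference(ecg: ReferenceECG, path: str | Path, format: str | None = None) -> None:
    """Write a ReferenceECG in the minimal CSV or XML schema."""
    path = Path(path)
    fmt = format or ("xml" if path.suffix.lower() == ".xml" else "csv")
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={ecg.fs_hz:g}\n")
            fh.write(",".join(ecg.lead_names) + "\n")
            mat = np.column_stack([ecg.leads[n] for n in ecg.lead_names])
            for row in mat:
                fh.write(",".join(f"{v:.9g}" for v in row) + "\n")
    elif fmt == "xml":
        root = ET.Element("ecg", fs=f"{ecg.fs_hz:g}")
        for name in ecg.lead_names:
            el = ET.SubElement(root, "lead", name=name)
            el.text = " ".join(f"{v:.9g}" for v in ecg.leads[name])
        ET.ElementTree(root).write(path)
    else:
        raise ValueError(f"unknown reference format: {fmt!r}")


def write_digitized(
    leads: Mapping[str, "DigitizedLead"],
    out_dir: str | Path,
    format: str = "csv",
    stem: str = "digitized",
) -> list[Path]:
    """Write digitized leads: one file per lead plus a combined file.

    ``format`` is ``csv`` (``time_ms,voltage_mV`` columns), ``xml``
    (the minimal reference schema, using the lead's constant sampling
    step), or ``plot`` (PNG over a pink millimeter grid).  Returns the
    paths written; the combined file is last.
    """
    if not leads:
        raise ValueError("no leads to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "csv":
        for name, lead in leads.items():
            p = out_dir / f"{stem}_{_safe(name)}.csv"
            _write_lead_csv(lead, p)
            written.append(p)
        p = out_dir / f"{stem}_all.csv"
        with open(p, "w") as fh:
            fh.write("lead,time_ms,voltage_mV\n")
            for name, lead in leads.items():
                for t, v in zip(lead.time_ms, lead.voltage_mV):
                    fh.write(f"{name},{t:.9g},{v:.9g}\n")
        written.append(p)
    elif format == "xml":
        for name, lead in leads.items():
            p = out_dir / f"{stem}_{_safe(name)}.xml"
            write_reference(_as_reference({name: lead}), p, format="xml")
            written.append(p)
        p = out_dir / f"{stem}_all.xml"
        write_reference(_as_reference(dict(leads)), p, format="xml")
        written.append(p)
    elif format == "plot":
        for name, lead in leads.items():
            p = out_dir / f"{stem}_{_safe(name)}.png"
            _plot_lead({name: lead}, p)
            written.append(p)
        p = out_dir / f"{stem}_all.png"
        _plot_lead(dict(leads), p)
        written.append(p)
    else:
        raise ValueError(f"unknown output format: {format!r}")
    return written


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def _write_lead_csv(lead: "DigitizedLead", path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ms,voltage_mV\n")
        for t, v in zip(lead.time_ms, lead.voltage_mV):
            fh.write(f"{t:.9g},{v:.9g}\n")


def _as_reference(leads: Mapping[str, "DigitizedLead"]) -> ReferenceECG:
    first = next(iter(leads.values()))
    step_ms = first.time_ms[1] - first.time_ms[0] if len(first.time_ms) > 1 else 2.0
    n = min(len(l.voltage_mV) for l in leads.values())
    return ReferenceECG(
        leads={k: np.asarray(l.voltage_mV[:n]) for k, l in leads.items()},
        fs_hz=1000.0 / step_ms,
    )


def _plot_lead(leads: Mapping[str, "DigitizedLead"], path: Path) -> None:
    # pink graph-paper background: fine 1 mm rules, heavy 5 mm rules.
    # 1 mm = 40 ms horizontally and 0.1 mV vertically at standard calibration.
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(leads)
    fig, axes = plt.subplots(n, 1, figsize=(10, 2.2 * n), squeeze=False)
    for ax, (name, lead) in zip(axes.ravel(), leads.items()):
        t, v = np.asarray(lead.time_ms), np.asarray(lead.voltage_mV)
        for x in np.arange(0, t[-1] + 40, 40):
            ax.axvline(x, color="#ffd9e0", lw=0.4, zorder=0)
        for x in np.arange(0, t[-1] + 200, 200):
            ax.axvline(x, color="#ff9fb5", lw=0.8, zorder=0)
        lo, hi = np.floor(v.min() * 10) / 10 - 0.2, np.ceil(v.max() * 10) / 10 + 0.2
        for y in np.arange(lo, hi, 0.1):
            ax.axhline(y, color="#ffd9e0", lw=0.4, zorder=0)
        for y in np.arange(np.floor(lo * 2) / 2, hi, 0.5):
            ax.axhline(y, color="#ff9fb5", lw=0.8, zorder=0)
        ax.plot(t, v, color="k", lw=0.9, zorder=2)
        ax.set_xlim(t[0], t[-1])
        ax.set_ylim(lo, hi)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel(f"{name} (mV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
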
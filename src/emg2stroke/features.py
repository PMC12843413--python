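"""Feature-image datasets derived from contraction segments.

Four 2-D image representations are produced per segment, each rendered to
a fixed 451 x 451 x 3 RGB geometry:

* ``spectrogram`` — the full Gaussian-window TFR as a dB colormap image;
* ``yellow_roi`` — only the high-power normalized-frequency band 0.9-1.0
  (the "yellow line" region), re-rendered to full height;
* ``amplitude_spectrum`` — the DFT magnitude of the segment plotted as a
  line over frequency (white background, no axes);
* ``peak_strength`` — amplitudes of detected local maxima of the
  rectified-signal envelope plotted as stems over time.

The amplitude-spectrum and peak-strength renders are axis-free single-color
plots so that the datasets are deterministic pixel-for-pixel.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import signal as sps

from .errors import ConfigurationError
from .preprocessing import ContractionSegment
from .tfr import (
    DB_RANGE_DEFAULT,
    SpectrogramImage,
    TFRMatrix,
    render_spectrogram_image,
    tfr_fast,
)

KINDS = ("spectrogram", "yellow_roi", "amplitude_spectrum", "peak_strength")
LABEL_TO_INDEX = {"control": 0, "stroke": 1}
YELLOW_BAND = (0.9, 1.0)

_LINE_COLOR = np.array([31, 119, 180], dtype=np.uint8)   # spectrum line
_STEM_COLOR = np.array([214, 39, 40], dtype=np.uint8)    # peak stems
_BACKGROUND = 255


@dataclass
class FeatureImage:
    """One labeled RGB feature image."""

    pixels: np.ndarray   # uint8, (H, W, 3)
    kind: str
    label: str           # control | stroke
    label_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        if self.label not in LABEL_TO_INDEX:
            raise ConfigurationError(f"unknown class label {self.label!r}")


@dataclass
class LabeledDataset:
    """A homogeneous collection of feature images of one kind."""

    images: list[FeatureImage]
    kind: str
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(img.kind != self.kind for img in self.images):
            raise ConfigurationError("all images in a dataset must share the kind")
        self.class_counts = dict(Counter(img.label for img in self.images))

    def __len__(self) -> int:
        return len(self.images)

    def labels(self) -> np.ndarray:
        """Integer class labels (control=0, stroke=1; positive class = stroke)."""
        return np.array([LABEL_TO_INDEX[img.label] for img in self.images])

    def pixel_array(self) -> np.ndarray:
        """(n, H, W, 3) uint8 stack."""
        return np.stack([img.pixels for img in self.images])

    def resized(self, size: int) -> "LabeledDataset":
        """Bilinear-resized copy (used to feed reduced-grid model inputs)."""
        out = []
        for img in self.images:
            pil = Image.fromarray(img.pixels, mode="RGB")
            small = np.asarray(pil.resize((size, size), Image.Resampling.BILINEAR))
            out.append(FeatureImage(small, img.kind, img.label, img.label_id))
        return LabeledDataset(out, self.kind)


def _to_feature_image(spec_img: SpectrogramImage, kind: str, segment) -> FeatureImage:
    return FeatureImage(spec_img.pixels, kind, segment.group, segment.label_id)


# ---------------------------------------------------------------------------
# kind-specific builders
# ---------------------------------------------------------------------------

def crop_yellow_roi(
    tfr: TFRMatrix,
    band: tuple[float, float] = YELLOW_BAND,
    size: int = 451,
    colormap: str = "viridis",
    db_range: tuple[float, float] = DB_RANGE_DEFAULT,
) -> SpectrogramImage:
    """Extract the normalized-frequency rows in ``band`` and re-render.

    The retained band is stretched to the full image height (no padding).
    """
    mask = (tfr.freq_axis >= band[0]) & (tfr.freq_axis <= band[1])
    if not np.any(mask):
        raise ConfigurationError(f"no frequency bins inside band {band}")
    sub = TFRMatrix(
        tfr.values[mask, :],
        tfr.time_axis_s,
        tfr.freq_axis[mask],
        tfr.sampling_rate_hz,
        tfr.source_label,
    )
    return render_spectrogram_image(
        sub, colormap=colormap, size=size, db_range=db_range, kind="spectrogram"
    )


def amplitude_spectrum(segment) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude of the mean-subtracted segment.

    Returns (frequencies in Hz over [0, Nyquist], |X_k|).
    """
    x = np.asarray(segment.samples, dtype=float)
    if len(x) == 0:
        raise ConfigurationError("empty segment")
    mags = np.abs(np.fft.rfft(x - np.mean(x)))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / segment.sampling_rate_hz)
    return freqs, mags


def _blank_canvas(size: int) -> np.ndarray:
    return np.full((size, size, 3), _BACKGROUND, dtype=np.uint8)


def _render_curve(y01: np.ndarray, size: int, color: np.ndarray) -> np.ndarray:
    """Rasterize a [0, 1] curve as a connected polyline on a white canvas."""
    canvas = _blank_canvas(size)
    xs = np.linspace(0, len(y01) - 1, size)
    y = np.interp(xs, np.arange(len(y01)), y01)
    rows = (size - 1) - np.round(np.clip(y, 0.0, 1.0) * (size - 1)).astype(int)
    for c in range(size):
        r0 = rows[c]
        r1 = rows[min(c + 1, size - 1)]
        lo, hi = min(r0, r1), max(r0, r1)
        canvas[lo : hi + 1, c] = color
    return canvas


def amplitude_spectrum_image(segment, size: int = 451) -> FeatureImage:
    """Line rendering of the DFT magnitude over [0, Nyquist]."""
    _, mags = amplitude_spectrum(segment)
    peak = mags.max()
    y = mags / peak if peak > 0 else np.zeros_like(mags)
    canvas = _render_curve(y, size, _LINE_COLOR)
    return FeatureImage(canvas, "amplitude_spectrum", segment.group, segment.label_id)


def detect_envelope_peaks(
    segment,
    smooth_window_s: float = 0.05,
    prominence_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima of the signal's amplitude envelope.

    The envelope is the magnitude of the analytic (Hilbert) signal of the
    mean-subtracted segment, smoothed with a 50 ms moving average.  A plain
    rectify-and-average envelope beats at fs - 2*f for carriers near
    Nyquist (the EMG band here is 115-120 Hz at fs 250), whereas the
    analytic magnitude tracks the true modulation envelope.

    Returns (peak times in s, peak envelope amplitudes, the envelope).
    Peaks must have prominence >= ``prominence_frac`` of the envelope max.
    """
    x = np.asarray(segment.samples, dtype=float)
    if len(x) == 0:
        raise ConfigurationError("empty segment")
    fs = segment.sampling_rate_hz
    env = np.abs(sps.hilbert(x - np.mean(x)))
    w = max(round(smooth_window_s * fs), 1)
    env = np.convolve(env, np.ones(w) / w, mode="same")
    if env.max() <= 0:
        return np.array([]), np.array([]), env
    peaks, _ = sps.find_peaks(env, prominence=prominence_frac * env.max())
    return peaks / fs, env[peaks], env


def peak_strength_image(
    segment,
    size: int = 451,
    smooth_window_s: float = 0.05,
    prominence_frac: float = 0.1,
) -> FeatureImage:
    """Stem plot of detected envelope-peak amplitudes over time."""
    times, heights, env = detect_envelope_peaks(segment, smooth_window_s, prominence_frac)
    canvas = _blank_canvas(size)
    duration = len(segment.samples) / segment.sampling_rate_hz
    scale = env.max() if env.size and env.max() > 0 else 1.0
    for t_peak, h in zip(times, heights):
        col = round(t_peak / duration * (size - 1))
        top = (size - 1) - round(np.clip(h / scale, 0.0, 1.0) * (size - 1))
        canvas[top:, col] = _STEM_COLOR
        # marker dot at the stem head
        r0, r1 = max(top - 2, 0), min(top + 3, size)
        c0, c1 = max(col - 2, 0), min(col + 3, size)
        canvas[r0:r1, c0:c1] = _STEM_COLOR
    return FeatureImage(canvas, "peak_strength", segment.group, segment.label_id)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(
    segments: Sequence[ContractionSegment],
    kind: str,
    size: int = 451,
    n_freq_bins: int = 451,
    n_time_bins: int = 451,
    colormap: str = "viridis",
    band: tuple[float, float] = YELLOW_BAND,
) -> LabeledDataset:
    """One feature image per segment of the requested kind."""
    if kind not in KINDS:
        raise ConfigurationError(f"unknown feature kind {kind!r}")
    images: list[FeatureImage] = []
    for seg in segments:
        if kind in ("spectrogram", "yellow_roi"):
            tfr = tfr_fast(
                seg, n_freq_bins=n_freq_bins, n_time_bins=n_time_bins,
                source_label=seg.label_id,
            )
            if kind == "spectrogram":
                spec_img = render_spectrogram_image(tfr, colormap=colormap, size=size)
            else:
                spec_img = crop_yellow_roi(tfr, band=band, size=size, colormap=colormap)
            images.append(_to_feature_image(spec_img, kind, seg))
        elif kind == "amplitude_spectrum":
            images.append(amplitude_spectrum_image(seg, size=size))
        else:
            images.append(peak_strength_image(seg, size=size))
    return LabeledDataset(images, kind)


def build_all_datasets(
    segments: Sequence[ContractionSegment],
    kinds: Sequence[str] = KINDS,
    **kwargs,
) -> dict[str, LabeledDataset]:
    return {kind: build_dataset(segments, kind, **kwargs) for kind in kinds}


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    images: list[FeatureImage] = []
    kind = None
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(root / row["file"]).convert("RGB"))
            images.append(FeatureImage(pixels, row["kind"], row["label"], row["label_id"]))
            kind = row["kind"]
    if kind is None:
        raise ConfigurationError(f"empty dataset manifest {manifest_path}")
    return LabeledDataset(images, kind)


def save_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """PNG per image plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "dataset_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "kind", "label", "label_id"])
        for img in dataset.images:
            fname = f"{img.label_id or id(img)}_{img.kind}.png"
            Image.fromarray(img.pixels, mode="RGB").save(out_dir / fname, format="PNG")
            writer.writerow([fname, img.kind, img.label, img.label_id])
    return manifest
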
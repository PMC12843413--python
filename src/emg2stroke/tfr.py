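"""Gaussian-window time-frequency representation (Stockwell-transform family).

The transform of a signal b(t) at analysis time tau and frequency f is

    S(tau, f) = (|f| / sqrt(2*pi)) * Integral b(t) exp(-(tau - t)^2 f^2 / 2)
                                             * exp(-j 2 pi f t) dt

i.e. a short-time Fourier analysis whose Gaussian window narrows in
proportion to the analysis frequency (window std = 1/f seconds).  The
|f|/sqrt(2*pi) prefactor makes the window unit-area, so a unit-amplitude
complex tone at frequency f0 yields |S(tau, f0)| = 1.  At f = 0 the
transform degenerates; the conventional value, the signal mean, is used.

Two evaluators are provided:

* :func:`tfr_brute_force` — direct Riemann-sum evaluation at every
  (tau, f) pair.  O(n_freq * n_time * n_samples); the correctness oracle.
* :func:`tfr_fast` — per-frequency evaluation in the spectral domain via
  zero-padded FFT convolution of the modulated signal with the sampled
  Gaussian window.  Exact (machine-precision) linear convolution, so it
  agrees with the oracle to roundoff.

Frequencies are exposed on a normalized axis where 1.0 = Nyquist
(consistent with dB/(rad/sample) spectrogram axis units); physical
frequency in Hz is nu * fs / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy import fft as sfft

from .errors import ConfigurationError

DB_RANGE_DEFAULT = (-120.0, 0.0)
DB_EPS = 1e-12


@dataclass
class TFRMatrix:
    """Complex time-frequency matrix indexed [frequency_bin, time_bin]."""

    values: np.ndarray           # complex, shape (n_freq, n_time)
    time_axis_s: np.ndarray      # tau grid, seconds
    freq_axis: np.ndarray        # normalized frequency, 1.0 = Nyquist
    sampling_rate_hz: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freq_axis), len(self.time_axis_s)):
            raise ConfigurationError("TFR shape does not match its axes")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def _coerce_signal(segment, sampling_rate_hz: float | None):
    """Accept a ContractionSegment-like object or a plain array."""
    if hasattr(segment, "samples") and hasattr(segment, "sampling_rate_hz"):
        return np.asarray(segment.samples, dtype=float), float(segment.sampling_rate_hz)
    x = np.asarray(segment)
    x = x if np.iscomplexobj(x) else x.astype(float)
    if sampling_rate_hz is None:
        raise ConfigurationError("sampling_rate_hz required for a bare array")
    return x, float(sampling_rate_hz)


def tfr_brute_force(
    segment,
    sampling_rate_hz: float | None = None,
    freq_axis: np.ndarray | None = None,
    time_axis_s: np.ndarray | None = None,
    source_label: str = "",
) -> TFRMatrix:
    """Direct Riemann-sum evaluation of the transform (the oracle).

    ``freq_axis`` is normalized (1.0 = Nyquist).  Rows with frequency 0
    hold the signal mean.
    """
    x, fs = _coerce_signal(segment, sampling_rate_hz)
    if len(x) == 0:
        raise ConfigurationError("empty segment")
    n = len(x)
    t = np.arange(n) / fs
    dt = 1.0 / fs
    if freq_axis is None:
        freq_axis = np.linspace(0.0, 1.0, 64)
    if time_axis_s is None:
        time_axis_s = t.copy()
    freq_axis = np.asarray(freq_axis, dtype=float)
    time_axis_s = np.asarray(time_axis_s, dtype=float)

    out = np.zeros((len(freq_axis), len(time_axis_s)), dtype=complex)
    for i, nu in enumerate(freq_axis):
        f = nu * fs / 2.0
        if f == 0.0:
            out[i, :] = np.mean(x)
            continue
        gauss = np.exp(-((time_axis_s[:, None] - t[None, :]) ** 2) * f**2 / 2.0)
        modulated = x * np.exp(-2j * np.pi * f * t)
        out[i, :] = (abs(f) / np.sqrt(2.0 * np.pi)) * (gauss @ modulated) * dt
    return TFRMatrix(out, time_axis_s, freq_axis, fs, source_label)


def tfr_fast(
    segment,
    sampling_rate_hz: float | None = None,
    n_freq_bins: int = 451,
    n_time_bins: int = 451,
    freq_axis: np.ndarray | None = None,
    source_label: str = "",
) -> TFRMatrix:
    """Fast spectral-domain evaluation (exact linear convolution per frequency).

    For each analysis frequency the modulated signal b(t) exp(-j 2 pi f t)
    is convolved with the sampled Gaussian window through zero-padded FFTs,
    then the tau grid is subsampled to ``n_time_bins`` sample instants.
    Matches :func:`tfr_brute_force` to machine precision on the same grid.
    """
    x, fs = _coerce_signal(segment, sampling_rate_hz)
    n = len(x)
    if n < 8:
        raise ConfigurationError("segment too short (need >= 8 samples)")
    t = np.arange(n) / fs
    dt = 1.0 / fs
    if freq_axis is None:
        freq_axis = np.linspace(0.0, 1.0, n_freq_bins)
    freq_axis = np.asarray(freq_axis, dtype=float)
    time_idx = np.unique(np.round(np.linspace(0, n - 1, min(n_time_bins, n))).astype(int))
    time_axis_s = t[time_idx]

    f_hz = freq_axis * fs / 2.0
    nonzero = f_hz != 0.0
    fnz = f_hz[nonzero]

    # modulated signals, one row per analysis frequency
    mod = x[None, :] * np.exp(-2j * np.pi * fnz[:, None] * t[None, :])
    mod *= (np.abs(fnz)[:, None] / np.sqrt(2.0 * np.pi)) * dt

    # sampled Gaussian window on lags -(n-1)..(n-1)
    lags = np.arange(-(n - 1), n) * dt
    win = np.exp(-(lags[None, :] ** 2) * fnz[:, None] ** 2 / 2.0)

    L = sfft.next_fast_len(3 * n - 2)
    S = sfft.ifft(
        sfft.fft(mod, n=L, axis=1) * sfft.fft(win, n=L, axis=1), axis=1
    )[:, n - 1 : 2 * n - 1]

    out = np.zeros((len(freq_axis), len(time_axis_s)), dtype=complex)
    out[nonzero, :] = S[:, time_idx]
    out[~nonzero, :] = np.mean(x)
    return TFRMatrix(out, time_axis_s, freq_axis, fs, source_label)


def to_decibels(
    tfr: TFRMatrix | np.ndarray,
    db_range: tuple[float, float] = DB_RANGE_DEFAULT,
    eps: float = DB_EPS,
) -> np.ndarray:
    """Power in dB: 10 log10(|S|^2 + eps), clipped to ``db_range``."""
    mag = tfr.magnitude if isinstance(tfr, TFRMatrix) else np.abs(np.asarray(tfr))
    db = 10.0 * np.log10(mag**2 + eps)
    return np.clip(db, db_range[0], db_range[1])


def get_colormap_lut(name: str = "viridis") -> np.ndarray:
    """256 x 3 uint8 lookup table for a perceptually ordered colormap."""
    cmap = colormaps[name]
    lut = np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3]
    return np.round(lut * 255.0).astype(np.uint8)


@dataclass
class SpectrogramImage:
    """Rendered RGB spectrogram (frequency up, time right, no axes)."""

    pixels: np.ndarray           # uint8, (size, size, 3)
    db_range: tuple[float, float]
    colormap_name: str
    kind: str = "spectrogram"
    label: str = ""
    label_id: str = ""


def resize_scalar(matrix: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Deterministic bilinear resize of a float matrix to (height, width)."""
    img = Image.fromarray(np.ascontiguousarray(matrix, dtype=np.float32), mode="F")
    resized = img.resize((size[1], size[0]), Image.Resampling.BILINEAR)
    return np.asarray(resized, dtype=np.float64)


def render_spectrogram_image(
    tfr: TFRMatrix,
    colormap: str = "viridis",
    size: int = 451,
    db_range: tuple[float, float] = DB_RANGE_DEFAULT,
    kind: str = "spectrogram",
    label: str = "",
    label_id: str = "",
) -> SpectrogramImage:
    """Render a TFR as a size x size x 3 RGB image.

    The dB matrix is min-max scaled over its own (clipped) range, so two
    TFRs differing only by a uniform power factor render identically;
    an all-equal matrix maps to the colormap's lowest color.  Frequency
    increases upward, time rightward; no axes, ticks or margins.
    """
    if tfr.values.size == 0:
        raise ConfigurationError("empty TFR")
    db = to_decibels(tfr, db_range=db_range)
    lo, hi = float(db.min()), float(db.max())
    norm = (db - lo) / (hi - lo) if hi > lo else np.zeros_like(db)
    norm = np.flipud(norm)  # row 0 of the image is the highest frequency
    scaled = np.clip(resize_scalar(norm, (size, size)), 0.0, 1.0)
    idx = np.round(scaled * 255.0).astype(np.uint8)
    lut = get_colormap_lut(colormap)
    return SpectrogramImage(
        pixels=lut[idx],
        db_range=db_range,
        colormap_name=colormap,
        kind=kind,
        label=label,
        label_id=label_id,
    )


def save_image_png(image: SpectrogramImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    return path


def save_tfr_npz(tfr: TFRMatrix, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        values=tfr.values,
        time_axis_s=tfr.time_axis_s,
        freq_axis=tfr.freq_axis,
        sampling_rate_hz=tfr.sampling_rate_hz,
    )
    return path
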
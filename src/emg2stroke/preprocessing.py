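"""Cleaning, normalization and contraction segmentation.

Fixed pipeline order: 50 Hz notch -> 115-120 Hz 4th-order Butterworth
band-pass -> min-max normalization to [0, 1] -> disjoint-window
segmentation into one fixed-length window per grasp cycle.  All filters
are applied forward-backward (zero phase) so contraction timing is not
shifted relative to the protocol schedule.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DegenerateSignalError
from .synthetic import EmgRecording

SCHEDULE = "schedule"
THRESHOLD = "threshold"


@dataclass(frozen=True)
class FilterSpec:
    """Notch + band-pass design parameters.

    The band-pass is a Butterworth of total order ``bp_order`` (an order-4
    band-pass has two pole pairs per skirt, i.e. ``scipy.signal.butter``
    with N = bp_order // 2 and btype='bandpass').
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    bp_low_hz: float = 115.0
    bp_high_hz: float = 120.0
    bp_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise ConfigurationError("band must satisfy 0 < low < high")
        if self.bp_order <= 0 or self.bp_order % 2 != 0:
            raise ConfigurationError("bp_order must be a positive even integer")
        if self.notch_q <= 0:
            raise ConfigurationError("notch_q must be positive")

    def validate_against(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.notch_hz >= nyq:
            raise ConfigurationError(f"notch {self.notch_hz} Hz >= Nyquist {nyq} Hz")
        if self.bp_high_hz >= nyq:
            raise ConfigurationError(f"band edge {self.bp_high_hz} Hz >= Nyquist {nyq} Hz")


def _notch_ba(spec: FilterSpec, fs: float):
    return signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)


def _bandpass_sos(spec: FilterSpec, fs: float):
    return signal.butter(
        spec.bp_order // 2,
        [spec.bp_low_hz, spec.bp_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def notch_response_db(spec: FilterSpec, fs: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Single-pass magnitude response of the designed notch, in dB."""
    b, a = _notch_ba(spec, fs)
    _, h = signal.freqz(b, a, worN=np.asarray(freqs_hz, dtype=float), fs=fs)
    return 20.0 * np.log10(np.abs(h))


def bandpass_response_db(spec: FilterSpec, fs: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Single-pass magnitude response of the designed band-pass, in dB."""
    sos = _bandpass_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=fs)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def notch_filter(recording: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Zero-phase 50 Hz notch; output has the same length as the input."""
    spec = spec or FilterSpec()
    spec.validate_against(recording.sampling_rate_hz)
    b, a = _notch_ba(spec, recording.sampling_rate_hz)
    filtered = signal.filtfilt(b, a, recording.samples)
    return replace(recording, samples=filtered)


def bandpass_filter(recording: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Zero-phase Butterworth band-pass (default 115-120 Hz, order 4)."""
    spec = spec or FilterSpec()
    spec.validate_against(recording.sampling_rate_hz)
    sos = _bandpass_sos(spec, recording.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return replace(recording, samples=filtered)


def normalize_minmax(recording: EmgRecording) -> EmgRecording:
    """Affine rescale of the whole recording to [0, 1].

    Raises DegenerateSignalError on a constant signal instead of silently
    returning zeros.
    """
    x = recording.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateSignalError("constant signal cannot be min-max normalized")
    return replace(recording, samples=(x - lo) / (hi - lo))


@dataclass
class ContractionSegment:
    """One fixed-length grasp window cut from a normalized recording."""

    samples: np.ndarray
    sampling_rate_hz: float
    window_s: float
    label_id: str        # e.g. H001_01 / P003_05
    group: str
    source_subject: str
    start_s: float

    def __len__(self) -> int:
        return len(self.samples)


def _threshold_onsets(
    recording: EmgRecording, window_s: float, rms_window_s: float = 0.2
) -> list[float]:
    """Detect burst onsets from a moving-RMS envelope crossing 20 % of its max."""
    fs = recording.sampling_rate_hz
    x = recording.samples - np.mean(recording.samples)
    w = max(round(rms_window_s * fs), 1)
    env = np.sqrt(np.convolve(x**2, np.ones(w) / w, mode="same"))
    above = env > 0.2 * env.max()
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.insert(edges, 0, 0)
    # merge rises closer than one window (fragmented bursts within a grasp)
    onsets: list[float] = []
    min_gap = window_s * fs * 0.8
    for e in edges:
        if not onsets or e - onsets[-1] * fs >= min_gap:
            onsets.append(e / fs)
    return onsets


def segment_contractions(
    recording: EmgRecording,
    window_s: float = 6.0,
    mode: str = SCHEDULE,
) -> list[ContractionSegment]:
    """Cut one disjoint window per grasp cycle and label it ``<ID>_NN``.

    ``schedule`` mode (default) places windows at the recorded protocol
    onsets; ``threshold`` mode detects bursts from an RMS envelope and
    falls back to the schedule (with a warning) when the detected count
    does not match the protocol's cycle count.
    """
    fs = recording.sampling_rate_hz
    n_win = round(window_s * fs)
    if n_win > len(recording.samples):
        raise ConfigurationError("recording shorter than one segmentation window")
    if mode not in (SCHEDULE, THRESHOLD):
        raise ConfigurationError(f"unknown segmentation mode {mode!r}")

    onsets = list(recording.onsets_s)
    if mode == THRESHOLD:
        detected = _threshold_onsets(recording, window_s)
        if len(detected) == recording.protocol.n_cycles:
            onsets = detected
        else:
            warnings.warn(
                f"threshold mode found {len(detected)} bursts, expected "
                f"{recording.protocol.n_cycles}; falling back to schedule",
                stacklevel=2,
            )
    if not onsets:
        raise ConfigurationError("recording carries no grasp onsets to segment at")

    segments: list[ContractionSegment] = []
    for k, onset in enumerate(onsets, start=1):
        i0 = min(round(onset * fs), len(recording.samples) - n_win)
        seg = recording.samples[i0 : i0 + n_win]
        segments.append(
            ContractionSegment(
                samples=seg.copy(),
                sampling_rate_hz=fs,
                window_s=window_s,
                label_id=f"{recording.subject_id}_{k:02d}",
                group=recording.group,
                source_subject=recording.subject_id,
                start_s=i0 / fs,
            )
        )
    return segments


def preprocess_recording(
    recording: EmgRecording,
    filter_spec: FilterSpec | None = None,
    window_s: float = 6.0,
    mode: str = SCHEDULE,
) -> list[ContractionSegment]:
    """Full pipeline: notch -> band-pass -> min-max normalize -> segment."""
    spec = filter_spec or FilterSpec()
    rec = notch_filter(recording, spec)
    rec = bandpass_filter(rec, spec)
    rec = normalize_minmax(rec)
    return segment_contractions(rec, window_s=window_s, mode=mode)


def read_segments(
    manifest_path: str | Path, sampling_rate_hz: float = 250.0
) -> list[ContractionSegment]:
    """Load segments previously written by :func:`write_segments`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    segments: list[ContractionSegment] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.loadtxt(root / row["file"], delimiter=",", skiprows=1)
            samples = data[:, 1]
            segments.append(
                ContractionSegment(
                    samples=samples,
                    sampling_rate_hz=sampling_rate_hz,
                    window_s=len(samples) / sampling_rate_hz,
                    label_id=row["label_id"],
                    group=row["group"],
                    source_subject=row["label_id"].rsplit("_", 1)[0],
                    start_s=float(data[0, 0]),
                )
            )
    return segments


def write_segments(
    segments: Sequence[ContractionSegment], out_dir: str | Path
) -> Path:
    """One CSV per segment plus a labels manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "segments_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label_id", "group", "file"])
        for seg in segments:
            fname = f"{seg.label_id}.csv"
            t = np.arange(len(seg.samples)) / seg.sampling_rate_hz
            np.savetxt(
                out_dir / fname,
                np.column_stack([t, seg.samples]),
                delimiter=",",
                header="time_s,amplitude",
                comments="",
                fmt="%.9g",
            )
            writer.writerow([seg.label_id, seg.group, fname])
    return manifest
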
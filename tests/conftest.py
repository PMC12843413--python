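"""Shared fixtures: small seeded cohorts and segment sets."""

from __future__ import annotations

import numpy as np
import pytest

from emg2stroke.preprocessing import preprocess_recording
from emg2stroke.synthetic import ProtocolSpec, SubjectProfile, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def control_recording(protocol):
    return generate_recording(SubjectProfile.control(seed=11), protocol)


@pytest.fixture(scope="session")
def stroke_recording(protocol):
    return generate_recording(SubjectProfile.stroke(seed=12), protocol)


@pytest.fixture(scope="session")
def small_cohort(protocol):
    """2 controls + 2 stroke subjects."""
    return generate_cohort(2, 2, protocol, master_seed=7)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    segments = []
    for rec in small_cohort:
        segments.extend(preprocess_recording(rec))
    return segments


@pytest.fixture(scope="session")
def tone_segment():
    """A 6 s pure 118 Hz tone shifted into [0, 1], shaped like a segment."""
    from emg2stroke.preprocessing import ContractionSegment

    fs = 250.0
    t = np.arange(int(6 * fs)) / fs
    x = 0.5 + 0.5 * np.sin(2 * np.pi * 118.0 * t)
    return ContractionSegment(
        samples=x, sampling_rate_hz=fs, window_s=6.0,
        label_id="H001_01", group="control", source_subject="H001", start_s=0.0,
    )
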
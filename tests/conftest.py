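"""Shared fixtures and helpers for the nvckit test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nvckit.synthdata import GroundTruth
from nvckit.trials import TrialTrace

# Deterministic hypothesis runs: fixed example budget, no wall-clock deadline.
settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None
)
settings.load_profile("ci")


def make_trace(
    value: np.ndarray,
    rate: float = 10.0,
    stim_onset: float | None = None,
    stim_duration: float = 1.0,
    baseline_start: float = 0.0,
    modality: str = "diameter",
) -> TrialTrace:
    """A TrialTrace around a plain value array, with sane default timing."""
    value = np.asarray(value, dtype=float)
    time = np.arange(value.size) / rate
    if stim_onset is None:
        stim_onset = float(time[-1]) * 0.8
    return TrialTrace(
        time=time,
        value=value,
        stim_onset=stim_onset,
        stim_duration=stim_duration,
        baseline_window=(baseline_start, stim_onset),
        modality=modality,
    )


@pytest.fixture
def clean_truth() -> GroundTruth:
    """Ground truth without noise or vasomotion (deterministic waveforms)."""
    return GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
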
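"""Shared fixtures: small probes, recordings and waveform builders."""

import numpy as np
import pytest

from htsort.detect import Snippet
from htsort.io_probe import ProbeGeometry, Recording


@pytest.fixture
def probe4() -> ProbeGeometry:
    """Four-channel linear probe, 30 um pitch (adjacent channels neighbors)."""
    pos = np.column_stack([np.zeros(4), np.arange(4) * 30.0])
    return ProbeGeometry((0, 1, 2, 3), pos, thres_nb=40.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def biphasic(n: int = 42, trough_at: int = 21, width: float = 3.0) -> np.ndarray:
    """Deterministic test spike: sharp negative trough, slower positive lobe."""
    t = np.arange(n, dtype=float) - trough_at
    return -np.exp(-0.5 * (t / width) ** 2) + 0.4 * np.exp(
        -0.5 * ((t - 3 * width) / (2 * width)) ** 2
    )


def make_snippet(waveform: np.ndarray, channel: int = 0, peak_index: int = 100,
                 amplitude: float | None = None) -> Snippet:
    if amplitude is not None:
        waveform = waveform / np.max(np.abs(waveform)) * amplitude
    return Snippet(
        waveform=np.asarray(waveform, float),
        channel=channel,
        peak_index=peak_index,
        peak_amplitude=float(np.max(np.abs(waveform))),
    )


@pytest.fixture
def noise_recording(probe4, rng) -> Recording:
    """One second of pure Gaussian noise on four channels at 14 kHz."""
    traces = rng.normal(0.0, 1.0, size=(4, 14000))
    return Recording(traces, 14000.0, probe4)
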
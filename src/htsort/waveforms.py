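"""Subsample waveform alignment utilities.

Threshold detection anchors each snippet on the sample that won the
argmax.  When a spike's true extremum falls between two samples, noise
assigns different spikes of the same unit to anchors one sample apart;
downstream stages that compare waveforms sample-by-sample then see two
phase cohorts where there is one unit.  The bandpassed signal is
band-limited well below Nyquist, so the continuous extremum is recovered
accurately by sinc (polyphase) interpolation, and waveforms can be
re-anchored on a common subsample phase before averaging or clustering.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly

__all__ = ["UPSAMPLE", "peak_position", "align_peak", "align_peak_matrix",
           "peak_normalize"]

#: interpolation factor for subsample peak localisation
UPSAMPLE = 16


def peak_position(waveform: np.ndarray) -> float:
    """Subsample position of the absolute peak via upsampled argmax."""
    fine = resample_poly(waveform, UPSAMPLE, 1)
    return int(np.argmax(np.abs(fine))) / UPSAMPLE


def _shift_fine(fine: np.ndarray, delta: int) -> np.ndarray:
    """Integer shift on the upsampled grid, edge-padding with end values."""
    out = np.empty_like(fine)
    if delta > 0:
        out[delta:] = fine[:fine.size - delta]
        out[:delta] = fine[0]
    elif delta < 0:
        out[:delta] = fine[-delta:]
        out[delta:] = fine[-1]
    else:
        out[:] = fine
    return out


def align_peak(waveform: np.ndarray, at: float) -> np.ndarray:
    """Shift one waveform so its interpolated absolute peak sits at ``at``."""
    fine = resample_poly(waveform, UPSAMPLE, 1)
    delta = int(round(at * UPSAMPLE)) - int(np.argmax(np.abs(fine)))
    if delta == 0:
        return waveform.copy()
    return _shift_fine(fine, delta)[::UPSAMPLE]


def align_peak_matrix(X: np.ndarray, at: float) -> np.ndarray:
    """Row-wise :func:`align_peak` on an (n_waveforms, n_samples) matrix."""
    fine = resample_poly(X, UPSAMPLE, 1, axis=1)
    target = int(round(at * UPSAMPLE))
    deltas = target - np.argmax(np.abs(fine), axis=1)
    out = np.empty_like(fine)
    for i, d in enumerate(deltas):
        out[i] = _shift_fine(fine[i], int(d))
    return out[:, ::UPSAMPLE]


def align_to_reference(waveform: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Shift ``waveform`` to its best cross-correlation lag against ``reference``.

    Anchoring a waveform on its own absolute peak fails when two features
    compete for the peak (a biphasic spike whose positive lobe rivals the
    trough): noise then anchors different cohorts of one unit on
    different features, and their averaged waveforms disagree by a large
    shift that no per-waveform rule can see.  Aligning everything to one
    common reference by full-waveform cross-correlation (on the upsampled
    grid) recovers the relative shift regardless of which feature won.
    """
    fa = resample_poly(reference, UPSAMPLE, 1)
    fb = resample_poly(waveform, UPSAMPLE, 1)
    corr = np.correlate(fa, fb, mode="full")
    delta = int(np.argmax(corr)) - (fb.size - 1)
    return _shift_fine(fb, delta)[::UPSAMPLE]


def peak_normalize(waveform: np.ndarray) -> np.ndarray:
    """Divide by the peak absolute amplitude; an all-zero waveform is returned as is."""
    peak = np.max(np.abs(waveform))
    if peak == 0:
        return waveform.copy()
    return waveform / peak
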
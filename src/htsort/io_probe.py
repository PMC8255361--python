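"""Recording and probe-geometry I/O plus signal preprocessing.

A recording is a channels x samples voltage matrix with a sampling rate and
a probe geometry attached.  The probe geometry carries the 2-D electrode
coordinates (micrometres) and the distance threshold ``thres_nb`` that
defines which electrodes count as neighbors; the neighbor relation drives
duplicate suppression (grouping) and template merging downstream.

Preprocessing is a zero-phase 300-3000 Hz bandpass followed by optional
resampling to a common working rate (14 kHz by default).  Zero-phase
filtering is used because spike-peak alignment is phase sensitive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ProbeGeometry",
    "Recording",
    "read_probe",
    "read_prb",
    "read_recording",
    "write_recording",
    "bandpass",
    "resample",
]

#: recommended range for the neighbor threshold, micrometres
_THRES_NB_RANGE = (20.0, 50.0)

_DTYPES = {"int16": np.int16, "float32": np.float32}


@dataclass(frozen=True)
class ProbeGeometry:
    """Electrode layout: per-channel 2-D positions in micrometres.

    Two distinct channels are *neighbors* iff their Euclidean distance is
    strictly below ``thres_nb``.  The relation is symmetric and irreflexive.
    """

    channel_ids: tuple[int, ...]
    positions: np.ndarray  # (n_channels, 2) float, micrometres
    thres_nb: float = 40.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n_channels, 2) array")
        if pos.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{len(self.channel_ids)} channel ids but {pos.shape[0]} positions"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("probe positions must be finite")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if self.thres_nb <= 0:
            raise ValueError("thres_nb must be positive")
        lo, hi = _THRES_NB_RANGE
        if not lo <= self.thres_nb <= hi:
            warnings.warn(
                f"thres_nb={self.thres_nb} um is outside the recommended "
                f"[{lo}, {hi}] um range",
                UserWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_ids", tuple(int(c) for c in self.channel_ids))

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between electrodes, micrometres."""
        return squareform(pdist(self.positions))

    def neighbor_matrix(self) -> np.ndarray:
        """Boolean adjacency: ``[i, j]`` True iff channels i and j are neighbors."""
        d = self.distance_matrix()
        adj = d < self.thres_nb
        np.fill_diagonal(adj, False)
        return adj

    def are_neighbors(self, a: int, b: int) -> bool:
        """Neighbor test by channel id (not index)."""
        ia, ib = self.channel_ids.index(a), self.channel_ids.index(b)
        if ia == ib:
            return False
        return bool(np.linalg.norm(self.positions[ia] - self.positions[ib]) < self.thres_nb)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "channel_ids": list(self.channel_ids),
            "positions_um": self.positions.tolist(),
            "thres_nb": self.thres_nb,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


@dataclass
class Recording:
    """Multi-channel voltage trace tied to a probe.

    ``traces`` is channels x samples, in the units of the source file (the
    pipeline is amplitude-scale invariant, so no calibration is applied).
    """

    traces: np.ndarray
    sampling_rate: float
    probe: ProbeGeometry

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces)
        if tr.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")
        if tr.shape[0] != self.probe.n_channels:
            raise ValueError(
                f"{tr.shape[0]} trace rows but probe has {self.probe.n_channels} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(tr)):
            raise ValueError("traces contain non-finite samples")
        self.traces = tr

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def read_probe(path: str | Path) -> ProbeGeometry:
    """Read the native JSON probe document ``{channel_ids, positions_um, thres_nb}``."""
    doc = json.loads(Path(path).read_text())
    try:
        ids = doc["channel_ids"]
        pos = doc["positions_um"]
    except KeyError as exc:
        raise ValueError(f"probe file {path} is missing key {exc}") from exc
    return ProbeGeometry(tuple(ids), np.asarray(pos, float), float(doc.get("thres_nb", 40.0)))


def read_prb(path: str | Path, thres_nb: float = 40.0) -> ProbeGeometry:
    """Convenience reader for PRB-style geometry files.

    A PRB file is a Python-literal document defining ``channel_groups``,
    each with a ``geometry`` mapping channel id -> (x, y).  All groups are
    concatenated; channels are ordered by id.
    """
    import ast

    text = Path(path).read_text()
    # strip the "channel_groups =" prefix if present, leaving a dict literal
    if "=" in text.split("{", 1)[0]:
        text = text.split("=", 1)[1]
    groups = ast.literal_eval(text.strip())
    geometry: dict[int, tuple[float, float]] = {}
    for grp in groups.values():
        geometry.update({int(k): tuple(v) for k, v in grp["geometry"].items()})
    ids = sorted(geometry)
    pos = np.array([geometry[i] for i in ids], dtype=float)
    return ProbeGeometry(tuple(ids), pos, thres_nb)


def read_recording(
    path: str | Path,
    layout: str,
    dtype: str,
    sampling_rate: float,
    probe: ProbeGeometry | str | Path,
) -> Recording:
    """Read a flat binary voltage file.

    ``layout`` is ``"interleaved"`` (sample-major: c0s0 c1s0 c2s0 ...) or
    ``"channel-major"`` (c0s0 c0s1 ... c1s0 ...).  No amplitude scaling is
    applied; traces are promoted to float64 for downstream filtering.
    """
    if dtype not in _DTYPES:
        raise ValueError(f"unknown dtype {dtype!r}; expected one of {sorted(_DTYPES)}")
    if layout not in ("interleaved", "channel-major"):
        raise ValueError(f"unknown layout {layout!r}")
    if not isinstance(probe, ProbeGeometry):
        probe = read_probe(probe)
    raw = np.fromfile(str(path), dtype=_DTYPES[dtype])
    n_ch = probe.n_channels
    if raw.size % n_ch:
        raise ValueError(
            f"file {path} holds {raw.size} values, not divisible by "
            f"{n_ch} channels (expected a whole number of frames)"
        )
    n_samp = raw.size // n_ch
    if layout == "interleaved":
        traces = raw.reshape(n_samp, n_ch).T
    else:
        traces = raw.reshape(n_ch, n_samp)
    return Recording(traces.astype(np.float64), float(sampling_rate), probe)


def write_recording(rec: Recording, path: str | Path, layout: str = "interleaved",
                    dtype: str = "float32") -> None:
    """Write traces as flat binary, the inverse of :func:`read_recording`."""
    if dtype not in _DTYPES:
        raise ValueError(f"unknown dtype {dtype!r}")
    arr = rec.traces.T if layout == "interleaved" else rec.traces
    np.ascontiguousarray(arr, dtype=_DTYPES[dtype]).tofile(str(path))


def bandpass(rec: Recording, low: float = 300.0, high: float = 3000.0,
             order: int = 3) -> Recording:
    """Zero-phase Butterworth bandpass, default 300-3000 Hz.

    Applied forward-backward (``sosfiltfilt``) so spike peaks are not
    shifted in time by the filter's phase response.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must lie below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.traces, axis=1)
    return Recording(filtered, rec.sampling_rate, rec.probe)


def resample(rec: Recording, target_rate: float = 14000.0) -> Recording:
    """Polyphase resampling with anti-aliasing (scipy ``resample_poly``).

    The rate ratio is reduced to a rational up/down pair; 30 kHz -> 14 kHz
    becomes up=7, down=15.  Identity when the rates already match.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return Recording(rec.traces.copy(), rec.sampling_rate, rec.probe)
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(rec.traces, frac.numerator, frac.denominator, axis=1)
    return Recording(out, float(target_rate), rec.probe)
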
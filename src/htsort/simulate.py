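"""Synthetic ground-truth MEA recordings at desk scale.

The generator produces exactly the statistical structure the sorting
pipeline assumes: each unit has a biphasic spike waveform (sharp negative
trough followed by a slower positive lobe) whose per-channel amplitude
decays exponentially with electrode distance, fires as a Poisson process
with an absolute refractory period, and sits in additive white Gaussian
background noise.  A controllable fraction of spikes is re-timed to
collide (land within half a spike width) with another unit's spike, which
is what exercises the outlier-resolution stage.

Everything is a deterministic function of the seed.  What this generator
does *not* emulate — electrode drift, bursting amplitude attenuation,
correlated noise — is documented in the methods note; results on this
data bound what the pipeline can do, not what real tissue will do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_probe import ProbeGeometry, Recording

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_probe",
    "place_units",
    "make_unit_templates",
    "make_spike_trains",
    "render_recording",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic recording.

    Defaults mirror a small dense-probe experiment: 25 um pitch,
    spikes visible on 2-4 channels (30 um spatial decay), 25 Hz Poisson
    firing with a 2 ms absolute refractory period (about 750 spikes per
    unit in a 30 s recording, the density typical of benchmark
    ground-truth recordings), and peak signal-to-noise of 10 on each
    unit's best channel.
    """

    n_channels: int = 32
    n_units: int = 10
    duration_s: float = 30.0
    sampling_rate_hz: float = 14000.0
    probe_pitch_um: float = 25.0
    probe_layout: str = "two-column"
    noise_sigma: float = 1.0
    snr: float = 10.0
    firing_rate_hz: float = 25.0
    refractory_ms: float = 2.0
    collision_fraction: float = 0.0
    decay_constant_um: float = 30.0
    spike_ms: float = 2.0
    min_unit_separation_um: float = 25.0
    thres_nb: float = 40.0
    seed: int = 0
    unit_positions: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_units", "duration_s", "sampling_rate_hz",
                     "probe_pitch_um", "snr", "firing_rate_hz",
                     "refractory_ms", "decay_constant_um", "spike_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.collision_fraction < 1.0:
            raise ValueError("collision_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """The generator's answer key.

    ``spike_times`` are best-channel trough sample indices (the quantity
    detection aligns to), sorted ascending; ``spike_units`` the firing
    unit of each; ``collision_mask`` flags spikes that participate in an
    injected collision pair (both the re-timed spike and its partner).
    """

    spike_times: np.ndarray
    spike_units: np.ndarray
    unit_positions: np.ndarray          # (n_units, 2) um
    unit_templates: np.ndarray          # (n_units, n_channels, template_len)
    collision_mask: np.ndarray
    spec: SimulationSpec

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def best_channel(self, unit: int) -> int:
        """Channel index with the largest absolute template amplitude."""
        return int(np.argmax(np.max(np.abs(self.unit_templates[unit]), axis=1)))


def make_probe(n_channels: int, pitch_um: float, layout: str = "linear",
               thres_nb: float = 40.0) -> ProbeGeometry:
    """Deterministic probe coordinates.

    ``linear``: one column at x=0, y = i * pitch.  ``two-column``: a
    staggered double column (x in {0, pitch}, second column offset by half
    a pitch vertically), the dense-probe arrangement; all pairwise
    distances are >= pitch in both layouts.
    """
    if layout == "linear":
        pos = np.column_stack([np.zeros(n_channels),
                               np.arange(n_channels) * pitch_um])
    elif layout == "two-column":
        col = np.arange(n_channels) % 2
        row = np.arange(n_channels) // 2
        pos = np.column_stack([col * pitch_um,
                               row * pitch_um + col * pitch_um / 2.0])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return ProbeGeometry(tuple(range(n_channels)), pos, thres_nb)


def place_units(spec: SimulationSpec, probe: ProbeGeometry,
                rng: np.random.Generator) -> np.ndarray:
    """Random unit positions over the probe footprint.

    Rejection-sampled so no two units sit closer than
    ``min_unit_separation_um`` — units inside one pitch of each other are
    genuinely unresolvable and would only measure the generator, not the
    sorter.
    """
    if spec.unit_positions is not None:
        pos = np.asarray(spec.unit_positions, dtype=float)
        if pos.shape != (spec.n_units, 2):
            raise ValueError("unit_positions must be (n_units, 2)")
        return pos
    lo = probe.positions.min(axis=0) - 5.0
    hi = probe.positions.max(axis=0) + 5.0
    for _restart in range(200):
        placed: list[np.ndarray] = []
        for _unit in range(spec.n_units):
            for _attempt in range(2000):
                cand = rng.uniform(lo, hi)
                if all(np.linalg.norm(cand - p) >= spec.min_unit_separation_um
                       for p in placed):
                    placed.append(cand)
                    break
            else:
                break
        if len(placed) == spec.n_units:
            return np.array(placed)
    raise RuntimeError("could not place units with the requested separation")


def _biphasic_waveform(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One unit's canonical spike shape, peak-normalized to -1 at the trough.

    Sum of alpha functions: an optional small positive pre-lobe (many
    real extracellular waveforms are triphasic), a fast negative trough
    (tau ~ 0.15-0.45 ms), and a slower, smaller positive lobe
    (tau ~ 0.4-0.7 ms).  Widths, lobe ratios and delays are randomized
    per unit so units differ in shape as well as location, with the
    diversity concentrated inside the 300-3000 Hz analysis band so that
    bandpass filtering preserves it.
    """
    t = np.arange(n) / rate * 1000.0  # ms
    tau_n = rng.uniform(0.15, 0.45)
    tau_p = rng.uniform(0.40, 0.70)
    ratio = rng.uniform(0.20, 0.65)
    delay = rng.uniform(0.10, 0.50)
    pre = rng.uniform(0.0, 0.30)       # triphasic pre-lobe, absent for some cells
    tau_pre = rng.uniform(0.15, 0.35)
    alpha = lambda tt, tau: np.where(tt > 0, (tt / tau) * np.exp(1 - tt / tau), 0.0)
    # the pre-lobe peaks before the trough: the trough component is delayed
    # by roughly the pre-lobe's width
    d0 = tau_pre * 1.2
    w = (pre * alpha(t, tau_pre) - alpha(t - d0, tau_n)
         + ratio * alpha(t - d0 - delay, tau_p))
    # somatic extracellular spikes are strongly trough-dominant, and the
    # 300-3000 Hz analysis band attenuates a sharp trough more than the
    # slower positive lobes; cap the positive excursion so the *filtered*
    # waveform keeps its trough at least 1/0.6 times any positive peak
    from scipy import signal as _sig

    sos = _sig.butter(3, [300.0, 3000.0], btype="bandpass", fs=rate, output="sos")
    for _ in range(4):
        padded = np.concatenate([np.zeros(4 * n), w, np.zeros(4 * n)])
        wf = _sig.sosfiltfilt(sos, padded)[4 * n:5 * n]
        r = np.max(wf) / -np.min(wf)
        if r <= 0.6:
            break
        w = np.where(w > 0, w * 0.85 * 0.6 / r, w)
    # half-Hann taper over the last 30% so the waveform decays to zero
    # inside its window instead of truncating mid-lobe
    k = max(int(0.3 * n), 2)
    w[-k:] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, k)))
    # ratio < 1 guarantees the trough dominates, so this normalizes it to -1
    return w / np.max(np.abs(w))


def make_unit_templates(spec: SimulationSpec, probe: ProbeGeometry,
                        positions: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-unit, per-channel waveforms, (n_units, n_channels, template_len).

    Channel c of unit u carries the unit's canonical waveform scaled by
    ``A_u * exp(-d(u, c) / decay_constant_um)``; ``A_u`` is set so the
    *best* channel's peak equals ``snr * noise_sigma`` (or ``snr`` voltage
    units in the noise-free case).
    """
    n = int(round(spec.spike_ms * spec.sampling_rate_hz / 1000.0))
    scale = spec.noise_sigma if spec.noise_sigma > 0 else 1.0
    out = np.zeros((spec.n_units, probe.n_channels, n))
    for u in range(spec.n_units):
        shape = _biphasic_waveform(n, spec.sampling_rate_hz, rng)
        d = np.linalg.norm(probe.positions - positions[u], axis=1)
        decay = np.exp(-d / spec.decay_constant_um)
        amp = spec.snr * scale / decay.max()
        out[u] = amp * decay[:, None] * shape[None, :]
    return out


def _poisson_train(rate_hz: float, refractory_s: float, duration_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Poisson spike times (seconds) thinned by an absolute refractory period."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if times:
            t = max(t, times[-1] + refractory_s)
        if t >= duration_s:
            return np.array(times)
        times.append(t)


def make_spike_trains(spec: SimulationSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike times (samples), unit ids, and the collision mask.

    Each unit fires as an independent Poisson process with dead time.
    Then ``collision_fraction`` of all spikes are re-timed to land within
    half a spike width of a randomly chosen spike of a *different* unit;
    a re-timing is skipped when it would violate the victim unit's own
    refractory period.  Both partners of each engineered pair are flagged
    in the mask.
    """
    rate = spec.sampling_rate_hz
    refr = spec.refractory_ms / 1000.0
    trains = [_poisson_train(spec.firing_rate_hz, refr, spec.duration_s, rng)
              for _ in range(spec.n_units)]
    times = np.concatenate([np.round(tr * rate).astype(int) for tr in trains])
    units = np.concatenate([np.full(tr.size, u, dtype=int)
                            for u, tr in enumerate(trains)])

    collision = np.zeros(times.size, dtype=bool)
    n_collide = int(round(spec.collision_fraction * times.size))
    if n_collide and times.size > 1:
        half_width = spec.spike_ms / 2.0 / 1000.0 * rate  # samples
        refr_samp = refr * rate
        movable = rng.permutation(times.size)
        moved = 0
        for idx in movable:
            if moved >= n_collide or collision[idx]:
                continue
            others = np.nonzero((units != units[idx]) & ~collision)[0]
            if others.size == 0:
                break
            partner = int(rng.choice(others))
            lag = rng.uniform(-half_width, half_width)
            new_t = int(round(times[partner] + lag))
            if new_t < 0:
                continue
            own = times[(units == units[idx])]
            own = own[own != times[idx]]
            if own.size and np.min(np.abs(own - new_t)) < refr_samp:
                continue
            times[idx] = new_t
            collision[idx] = collision[partner] = True
            moved += 1

    order = np.argsort(times, kind="stable")
    return times[order], units[order], collision[order]


def render_recording(spec: SimulationSpec) -> tuple[Recording, GroundTruth]:
    """Superpose unit templates at their spike times and add Gaussian noise.

    Ground-truth spike times refer to each unit's best-channel trough, so
    they align with what threshold detection reports.  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    probe = make_probe(spec.n_channels, spec.probe_pitch_um, spec.probe_layout,
                       spec.thres_nb)
    positions = place_units(spec, probe, rng)
    templates = make_unit_templates(spec, probe, positions, rng)
    times, units, collision = make_spike_trains(spec, rng)

    n_samples = int(round(spec.duration_s * spec.sampling_rate_hz))
    tmpl_len = templates.shape[2]
    trough = np.array([int(np.argmax(np.max(np.abs(templates[u]), axis=0)))
                       for u in range(spec.n_units)])

    traces = rng.normal(0.0, spec.noise_sigma, size=(probe.n_channels, n_samples)) \
        if spec.noise_sigma > 0 else np.zeros((probe.n_channels, n_samples))

    keep = np.ones(times.size, dtype=bool)
    for i, (t, u) in enumerate(zip(times, units)):
        start = t - trough[u]
        if start < 0 or start + tmpl_len > n_samples:
            keep[i] = False
            continue
        traces[:, start:start + tmpl_len] += templates[u]

    gt = GroundTruth(
        spike_times=times[keep],
        spike_units=units[keep],
        unit_positions=positions,
        unit_templates=templates,
        collision_mask=collision[keep],
        spec=spec,
    )
    rec = Recording(traces, spec.sampling_rate_hz, probe)
    return rec, gt
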
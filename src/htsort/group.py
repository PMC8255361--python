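"""Divide-and-conquer grouping: duplicate suppression and per-electrode groups.

On a dense probe one spike is picked up by several adjacent electrodes, so
threshold detection yields redundant snippets.  Snippets whose peaks fall
within a short coincidence window of one another *and* whose channels are
probe neighbors are coalesced (transitively) into one spike-event
candidate; only the member with the largest peak amplitude — the best
channel — is kept.  Retained snippets are then grouped by electrode, which
acts as a spatial pre-clustering: units at different locations land in
different groups before any waveform clustering happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Snippet
from .io_probe import ProbeGeometry
from .waveforms import align_peak, peak_normalize

__all__ = [
    "SpikeEventCandidate",
    "SnippetGroup",
    "coalesce_events",
    "select_best_channel",
    "build_groups",
]


@dataclass
class SpikeEventCandidate:
    """One putative spike seen on one or more neighboring channels."""

    member_snippets: list[Snippet]
    event_time: int  # peak index of the strongest member

    def __len__(self) -> int:
        return len(self.member_snippets)


@dataclass
class SnippetGroup:
    """All best-channel snippets retained for one electrode."""

    channel: int
    snippets: list[Snippet] = field(default_factory=list)

    def waveform_matrix(self) -> np.ndarray:
        """Stack waveforms into an (n_snippets, n_samples) array."""
        return np.stack([s.waveform for s in self.snippets])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def coalesce_events(
    per_channel_snippets: dict[int, list[Snippet]],
    probe: ProbeGeometry,
    delta_t_ms: float,
    sampling_rate: float,
    min_shape_similarity: float | None = 0.8,
    similarity_amp_ratio: float = 0.8,
) -> list[SpikeEventCandidate]:
    """Partition snippets into spike events.

    Candidate same-event pairs are snippets whose peaks lie within
    ``delta_t_ms`` of each other and whose channels are probe neighbors.
    Pairs of comparable amplitude (weaker above ``similarity_amp_ratio``
    times the stronger) must additionally pass a shape gate: their
    peak-aligned, peak-normalized waveforms must correlate at least
    ``min_shape_similarity``.  The gate encodes what "the same spike on
    two electrodes" means — spatial decay scales the amplitude but
    preserves the waveform — so a comparable-amplitude coincident pair
    with genuinely different shapes is two units firing together, and
    suppressing one of them would silently delete a real spike; a
    clearly decayed pair, by contrast, is claimed on amplitude alone,
    since near-threshold copies are too noisy for a reliable shape test.

    Events are grown by watershed claiming, strongest snippet first:
    each event spreads from its amplitude peak to claimable snippets of
    non-increasing amplitude, transitively, so an event can chain across
    channels but never across an amplitude valley — two units firing
    together on nearby channels remain two events.  Every snippet ends
    up in exactly one event; events are returned sorted by event time,
    then by strongest-member channel id.
    """
    snippets: list[Snippet] = [s for ch in sorted(per_channel_snippets)
                               for s in per_channel_snippets[ch]]
    if not snippets:
        return []
    delta = delta_t_ms * sampling_rate / 1000.0
    order = np.argsort([s.peak_index for s in snippets], kind="stable")
    snippets = [snippets[i] for i in order]
    times = np.array([s.peak_index for s in snippets])
    amps = np.array([s.peak_amplitude for s in snippets])

    id_to_idx = {cid: i for i, cid in enumerate(probe.channel_ids)}
    adj = probe.neighbor_matrix()

    normalized: list[np.ndarray | None] = [None] * len(snippets)

    def unit_shape(i: int) -> np.ndarray:
        if normalized[i] is None:
            w = align_peak(peak_normalize(snippets[i].waveform),
                           snippets[i].waveform.size // 2)
            n = np.linalg.norm(w)
            normalized[i] = w / n if n > 0 else w
        return normalized[i]

    def claimable(u: int, v: int) -> bool:
        cu, cv = id_to_idx[snippets[u].channel], id_to_idx[snippets[v].channel]
        if not adj[cu, cv]:
            return False
        decayed = amps[v] <= similarity_amp_ratio * amps[u]
        # a near-threshold copy's apparent peak can be displaced by noise
        # well beyond a strong snippet's, so strongly decayed copies (at
        # most half the claimer) are claimed over twice the window
        wide = amps[v] <= 0.5 * amps[u]
        if abs(int(times[v]) - int(times[u])) > (2 * delta if wide else delta):
            return False
        # a clearly decayed copy is claimed on amplitude alone; the shape
        # gate only arbitrates comparable-amplitude pairs, where "unit
        # midway between two electrodes" (same shape) must be told apart
        # from "two units firing together" (different shapes) and both
        # snippets are strong enough for the correlation to be reliable
        if decayed:
            return True
        if min_shape_similarity is not None and \
                float(unit_shape(u) @ unit_shape(v)) < min_shape_similarity:
            return False
        return True

    # watershed claiming, strongest snippet first: an event spreads from its
    # amplitude peak outward, claiming coincident neighboring snippets only
    # downhill in amplitude, so two amplitude local maxima (two units firing
    # together on nearby channels) yield two events instead of one
    claimed = np.zeros(len(snippets), dtype=bool)
    events: list[SpikeEventCandidate] = []
    for seed in sorted(range(len(snippets)),
                       key=lambda i: (-amps[i], snippets[i].channel, times[i])):
        if claimed[seed]:
            continue
        claimed[seed] = True
        members = [seed]
        stack = [seed]
        while stack:
            u = stack.pop()
            lo = int(np.searchsorted(times, times[u] - 2 * delta, side="left"))
            hi = int(np.searchsorted(times, times[u] + 2 * delta, side="right"))
            for v in range(lo, hi):
                if not claimed[v] and amps[v] <= amps[u] and claimable(u, v):
                    claimed[v] = True
                    members.append(v)
                    stack.append(v)
        events.append(SpikeEventCandidate([snippets[i] for i in sorted(members)],
                                          event_time=int(times[seed])))
    events.sort(key=lambda e: (e.event_time, e.member_snippets[0].channel))
    return events


def select_best_channel(event: SpikeEventCandidate) -> Snippet:
    """Best-channel selection: the member with the largest peak amplitude.

    Exact amplitude ties are broken toward the lowest channel id, keeping
    the choice deterministic.
    """
    if not event.member_snippets:
        raise ValueError("event has no member snippets")
    return min(event.member_snippets, key=lambda s: (-s.peak_amplitude, s.channel))


def build_groups(events: list[SpikeEventCandidate]) -> list[SnippetGroup]:
    """Group best-channel snippets by electrode.

    One group per channel that owns at least one retained snippet; the
    total snippet count over groups equals the number of events.  Groups
    are ordered by channel id, snippets by peak index.
    """
    by_channel: dict[int, list[Snippet]] = {}
    for ev in events:
        best = select_best_channel(ev)
        by_channel.setdefault(best.channel, []).append(best)
    groups = []
    for ch in sorted(by_channel):
        snips = sorted(by_channel[ch], key=lambda s: s.peak_index)
        groups.append(SnippetGroup(channel=ch, snippets=snips))
    return groups
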
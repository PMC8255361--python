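import numpy as np
import pytest

from htsort.group import build_groups, coalesce_events, select_best_channel
from htsort.io_probe import bandpass
from htsort.detect import DetectionParams, channel_thresholds, detect_snippets
from htsort.simulate import SimulationSpec, render_recording

from .conftest import biphasic, make_snippet

RATE = 14000.0


def _per_channel(snippets):
    out = {}
    for s in snippets:
        out.setdefault(s.channel, []).append(s)
    for ch in out:
        out[ch].sort(key=lambda s: s.peak_index)
    return out


class TestCoalesce:
    def test_single_snippet_single_event(self, probe4):
        snip = make_snippet(biphasic(), channel=1, peak_index=500)
        events = coalesce_events(_per_channel([snip]), probe4, 0.5, RATE)
        assert len(events) == 1 and len(events[0]) == 1

    def test_same_spike_on_three_neighbors_one_event(self, probe4):
        w = biphasic()
        snips = [
            make_snippet(w, channel=0, peak_index=500, amplitude=4.0),
            make_snippet(w, channel=1, peak_index=501, amplitude=10.0),
            make_snippet(w, channel=2, peak_index=502, amplitude=5.0),
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert len(events) == 1 and len(events[0]) == 3

    def test_spikes_5ms_apart_two_events(self, probe4):
        w = biphasic()
        snips = [
            make_snippet(w, channel=0, peak_index=500, amplitude=10.0),
            make_snippet(w, channel=1, peak_index=570, amplitude=10.0),  # 5 ms
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert len(events) == 2

    def test_coincident_non_neighbors_stay_separate(self, probe4):
        w = biphasic()
        snips = [
            make_snippet(w, channel=0, peak_index=500, amplitude=10.0),
            make_snippet(w, channel=3, peak_index=501, amplitude=9.0),
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert len(events) == 2

    def test_comparable_amplitude_different_shapes_stay_separate(self, probe4):
        """Two units firing together on neighboring channels: the shape
        gate must keep both spikes."""
        a = biphasic(width=2.0)
        b = -biphasic(width=2.0)  # opposite polarity: maximally different
        snips = [
            make_snippet(a, channel=0, peak_index=500, amplitude=10.0),
            make_snippet(b, channel=1, peak_index=502, amplitude=9.0),
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert len(events) == 2

    def test_clearly_decayed_copy_claimed_regardless_of_shape(self, probe4):
        a = biphasic(width=2.0)
        noisy = biphasic(width=2.0) + np.random.default_rng(0).normal(0, 0.5, 42)
        snips = [
            make_snippet(a, channel=0, peak_index=500, amplitude=10.0),
            make_snippet(noisy, channel=1, peak_index=501, amplitude=3.0),
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert len(events) == 1

    def test_two_amplitude_peaks_make_two_events(self, probe4):
        """Watershed: a valley in amplitude across channels separates two
        coincident spikes even when all shapes agree."""
        w = biphasic()
        snips = [
            make_snippet(w, channel=0, peak_index=500, amplitude=10.0),
            make_snippet(w, channel=1, peak_index=500, amplitude=3.0),
            make_snippet(w, channel=2, peak_index=501, amplitude=9.0),
        ]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        amps = sorted(max(s.peak_amplitude for s in e.member_snippets)
                      for e in events)
        assert len(events) == 2
        assert amps == [9.0, 10.0]

    def test_partition_is_total(self, probe4, rng):
        snips = [make_snippet(biphasic(), channel=int(rng.integers(4)),
                              peak_index=int(t), amplitude=float(rng.uniform(3, 10)))
                 for t in np.sort(rng.integers(100, 50000, size=60))]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert sum(len(e) for e in events) == len(snips)

    def test_deterministic(self, probe4, rng):
        snips = [make_snippet(biphasic(), channel=int(rng.integers(4)),
                              peak_index=int(t), amplitude=float(rng.uniform(3, 10)))
                 for t in np.sort(rng.integers(100, 20000, size=40))]
        a = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        b = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert [(e.event_time, len(e)) for e in a] == \
            [(e.event_time, len(e)) for e in b]


class TestBestChannel:
    def test_single_member_identity(self, probe4):
        snip = make_snippet(biphasic(), channel=2, peak_index=100)
        events = coalesce_events(_per_channel([snip]), probe4, 0.5, RATE)
        assert select_best_channel(events[0]) is events[0].member_snippets[0]

    def test_largest_amplitude_wins(self, probe4):
        w = biphasic()
        snips = [make_snippet(w, channel=c, peak_index=500 + c, amplitude=a)
                 for c, a in [(0, 12.1), (1, 7.3), (2, 4.0)]]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert select_best_channel(events[0]).peak_amplitude == pytest.approx(12.1)

    def test_tie_breaks_to_lowest_channel(self, probe4):
        w = biphasic()
        snips = [make_snippet(w, channel=c, peak_index=500, amplitude=8.0)
                 for c in (2, 1)]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        assert select_best_channel(events[0]).channel == 1


class TestBuildGroups:
    def test_conservation(self, probe4, rng):
        snips = [make_snippet(biphasic(), channel=int(rng.integers(4)),
                              peak_index=int(t), amplitude=float(rng.uniform(3, 10)))
                 for t in np.sort(rng.integers(100, 50000, size=80))]
        events = coalesce_events(_per_channel(snips), probe4, 0.5, RATE)
        groups = build_groups(events)
        assert sum(len(g.snippets) for g in groups) == len(events)
        for g in groups:
            assert all(s.channel == g.channel for s in g.snippets)

    def test_all_best_on_one_channel(self, probe4):
        w = biphasic()
        snips = [make_snippet(w, channel=0, peak_index=t, amplitude=10.0)
                 for t in (500, 1500, 2500)]
        groups = build_groups(coalesce_events(_per_channel(snips), probe4,
                                              0.5, RATE))
        assert len(groups) == 1 and groups[0].channel == 0

    def test_distinct_channels_distinct_groups(self, probe4):
        w = biphasic()
        snips = [make_snippet(w, channel=c, peak_index=500 + 1000 * c,
                              amplitude=10.0) for c in range(4)]
        groups = build_groups(coalesce_events(_per_channel(snips), probe4,
                                              0.5, RATE))
        assert [g.channel for g in groups] == [0, 1, 2, 3]
        assert all(len(g.snippets) == 1 for g in groups)


class TestOnSyntheticRecording:
    def test_noise_free_well_separated_units_conserved(self):
        """With units farther apart than twice the neighbor radius and no
        collisions, each true spike yields exactly one retained snippet."""
        spec = SimulationSpec(
            n_channels=8, n_units=3, duration_s=8.0, probe_layout="linear",
            probe_pitch_um=30.0, snr=10.0, firing_rate_hz=8.0,
            refractory_ms=3.5, seed=7,
            unit_positions=((4.0, 8.0), (4.0, 98.0), (4.0, 188.0)),
        )
        rec, gt = render_recording(spec)
        filtered = bandpass(rec)
        params = DetectionParams(k=5.0)
        thresholds = channel_thresholds(filtered, params)
        per_channel = {
            ch: detect_snippets(filtered.traces[i], params, RATE, channel=ch,
                                threshold=thresholds[ch])
            for i, ch in enumerate(filtered.probe.channel_ids)
        }
        events = coalesce_events(per_channel, filtered.probe, 0.5, RATE)
        interior = (gt.spike_times > 21) & (gt.spike_times < rec.n_samples - 21)
        assert len(events) == int(interior.sum())
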
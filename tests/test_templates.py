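import numpy as np
import pytest

from htsort.io_probe import ProbeGeometry
from htsort.templates import (
    Template,
    TemplateLibrary,
    build_shared_space,
    estimate_template,
    merge_templates,
)

from .conftest import biphasic, make_snippet

L = 42


def _template(waveform, channels=(0,), n=100, times=None):
    return Template(
        waveform=np.asarray(waveform, float),
        home_channels=frozenset(channels),
        n_member_spikes=n,
        member_times=None if times is None else np.sort(np.asarray(times)),
    )


def _library(templates, sigma=0.05):
    build_shared_space(templates)
    return TemplateLibrary(templates=list(templates), merge_sigma=sigma)


@pytest.fixture
def linear_probe():
    pos = np.column_stack([np.zeros(6), np.arange(6) * 30.0])
    return ProbeGeometry(tuple(range(6)), pos, thres_nb=40.0)


class TestEstimateTemplate:
    def test_single_snippet_identity(self):
        w = biphasic()
        tmpl = estimate_template([make_snippet(w, channel=3)])
        np.testing.assert_allclose(tmpl.waveform, w)
        assert tmpl.home_channels == frozenset({3})
        assert tmpl.n_member_spikes == 1

    def test_opposite_waveforms_cancel(self):
        w = biphasic()
        tmpl = estimate_template([make_snippet(w), make_snippet(-w)])
        np.testing.assert_allclose(tmpl.waveform, 0.0, atol=1e-12)

    def test_noisy_copies_recover_truth(self, rng):
        truth = biphasic() * 5.0
        snips = [make_snippet(truth + rng.normal(0, 1.0, L)) for _ in range(50)]
        tmpl = estimate_template(snips)
        corr = np.corrcoef(tmpl.waveform, truth)[0, 1]
        assert corr > 0.99

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            estimate_template([])


class TestSharedSpace:
    def test_identical_waveforms_distance_zero(self):
        temps = [_template(biphasic(), (0,)), _template(biphasic(), (1,))]
        coords = build_shared_space(temps)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.0, abs=1e-10)

    def test_scaled_copy_distance_zero(self):
        w = biphasic()
        temps = [_template(w), _template(2.0 * w)]
        coords = build_shared_space(temps)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.0, abs=1e-10)

    def test_dissimilar_shapes_exceed_sigma(self):
        """Shapes with cosine similarity ~0.5 sit far beyond the merge
        threshold in the shared space."""
        a = biphasic(width=2.0)
        b = np.roll(biphasic(width=8.0), 6)
        na, nb = a / np.linalg.norm(a), b / np.linalg.norm(b)
        assert abs(na @ nb) < 0.75  # genuinely different shapes
        temps = [_template(a), _template(b)]
        coords = build_shared_space(temps)
        assert np.linalg.norm(coords[0] - coords[1]) > 0.05

    def test_feature_vectors_stored(self):
        temps = [_template(biphasic())]
        build_shared_space(temps)
        assert temps[0].feature_vector is not None


def _perturbed_pair(distance):
    """Two templates whose shared-space distance is approximately the
    requested per-sample RMS value (independent construction: add a unit
    perturbation vector away from the peak and scale analytically)."""
    w = biphasic()  # peak magnitude 1 at index 21
    u = np.zeros(L)
    u[5] = 0.6
    u[34] = -0.8  # unit norm, zero at the peak sample
    eps = distance * np.sqrt(L)
    return _template(w, (0,)), _template(w + eps * u, (1,))


class TestMerge:
    def test_identical_on_neighbors_merge(self, linear_probe):
        lib = _library([_template(biphasic(), (0,)), _template(biphasic(), (1,))])
        merged = merge_templates(lib, linear_probe)
        assert len(merged) == 1

    def test_identical_on_non_neighbors_stay(self, linear_probe):
        lib = _library([_template(biphasic(), (0,)), _template(biphasic(), (4,))])
        merged = merge_templates(lib, linear_probe)
        assert len(merged) == 2

    def test_threshold_separates_004_from_006(self, linear_probe):
        near = _library(list(_perturbed_pair(0.04)))
        far = _library(list(_perturbed_pair(0.06)))
        assert len(merge_templates(near, linear_probe)) == 1
        assert len(merge_templates(far, linear_probe)) == 2

    def test_idempotent(self, linear_probe, rng):
        temps = [
            _template(biphasic(width=2.0) + rng.normal(0, 0.01, L), (0,)),
            _template(biphasic(width=2.0) + rng.normal(0, 0.01, L), (1,)),
            _template(np.roll(biphasic(width=7.0), 5), (3,)),
        ]
        merged = merge_templates(_library(temps), linear_probe)
        again = merge_templates(merged, linear_probe)
        assert len(again) == len(merged)

    def test_order_independent(self, linear_probe, rng):
        def build():
            return [
                _template(biphasic(width=2.0), (0,), n=300),
                _template(biphasic(width=2.0) * 1.5, (1,), n=200),
                _template(np.roll(biphasic(width=7.0), 5), (3,), n=250),
                _template(np.roll(biphasic(width=7.0), 5) * 0.8, (4,), n=150),
            ]
        a = merge_templates(_library(build()), linear_probe)
        temps = build()
        perm = [2, 0, 3, 1]
        b = merge_templates(_library([temps[i] for i in perm]), linear_probe)
        sizes_a = sorted(t.n_member_spikes for t in a.templates)
        sizes_b = sorted(t.n_member_spikes for t in b.templates)
        assert sizes_a == sizes_b == [400, 500]

    def test_weighted_mean_favors_large_cluster(self, linear_probe):
        w = biphasic()
        big = _template(w * 10.0, (0,), n=500)
        spur = _template(w * 10.0 + 0.2, (1,), n=5)
        merged = merge_templates(_library([big, spur]), linear_probe)
        assert len(merged) == 1
        # the 5-spike spur barely moves the 500-spike template
        np.testing.assert_allclose(merged.templates[0].waveform, big.waveform,
                                   atol=0.02)
        unweighted = merge_templates(_library([big, spur]), linear_probe,
                                     weighted=False)
        offset = np.mean(unweighted.templates[0].waveform - big.waveform)
        assert offset == pytest.approx(0.1, abs=0.03)

    def test_home_channels_and_counts_union(self, linear_probe):
        lib = _library([_template(biphasic(), (0,), n=120),
                        _template(biphasic(), (1,), n=80)])
        merged = merge_templates(lib, linear_probe)
        assert merged.templates[0].home_channels == frozenset({0, 1})
        assert merged.templates[0].n_member_spikes == 200

    def test_provenance_total_and_surjective(self, linear_probe):
        temps = [_template(biphasic(), (0,)), _template(biphasic(), (1,)),
                 _template(np.roll(biphasic(width=7.0), 5), (3,))]
        build_shared_space(temps)
        lib = TemplateLibrary(templates=temps, merge_sigma=0.05,
                              provenance={(0, 0): 0, (1, 0): 1, (3, 0): 2})
        merged = merge_templates(lib, linear_probe)
        assert set(merged.provenance) == {(0, 0), (1, 0), (3, 0)}
        assert set(merged.provenance.values()) == set(range(len(merged)))

    def test_refractory_conflict_blocks_lookalikes(self, linear_probe, rng):
        """Near-identical waveforms on neighboring electrodes must not merge
        when their spike trains interleave within a refractory period."""
        w = biphasic()
        rate = 14000.0
        # strictly alternating trains 0.7 ms apart: blatant co-activity
        ta = np.arange(100) * 1400 + 1000
        tb = ta + 10
        a = _template(w, (0,), n=100, times=ta)
        b = _template(w, (1,), n=100, times=tb)
        merged = merge_templates(_library([a, b]), linear_probe,
                                 sampling_rate=rate)
        assert len(merged) == 2
        # complementary trains (no co-activity) do merge
        a2 = _template(w, (0,), n=100, times=ta)
        b2 = _template(w, (1,), n=100, times=ta + 700)  # 50 ms away
        merged2 = merge_templates(_library([a2, b2]), linear_probe,
                                  sampling_rate=rate)
        assert len(merged2) == 1

    def test_empty_library_rejected(self, linear_probe):
        with pytest.raises(ValueError):
            merge_templates(TemplateLibrary(templates=[]), linear_probe)
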
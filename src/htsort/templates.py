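"""Template estimation and geometry-aware template merging.

Each cluster's template is the pointwise mean of its member waveforms.
Because the best channel of a unit sitting between two electrodes flaps
between them, the same unit can produce one cluster per electrode
(overclustering); merging collapses these.  Two templates merge iff

1. they are closer than ``merge_sigma`` (default 0.05) in a shared,
   scale-free comparison space, and
2. their home electrodes are the same or probe neighbors
   (distance < ``thres_nb``).

The shared space is built by peak-normalizing every template waveform
(dividing by its peak absolute amplitude) and fitting a PCA across the
normalized waveforms; per-group clustering spaces are mutually
incomparable, so cross-group distances must be measured in one common
basis.  Pairs satisfying both criteria are closed transitively
(union-find), which makes the merge order-independent and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

from .cluster import ClusterLabeling
from .detect import Snippet
from .group import SnippetGroup
from .io_probe import ProbeGeometry
from .waveforms import (
    align_peak,
    align_peak_matrix,
    align_to_reference,
    peak_normalize,
)

__all__ = [
    "Template",
    "TemplateLibrary",
    "estimate_template",
    "build_templates",
    "build_shared_space",
    "merge_templates",
]

#: dimensionality of the shared comparison space
SHARED_SPACE_COMPONENTS = 3


@dataclass
class Template:
    """Mean waveform of one cluster (or of several merged clusters)."""

    waveform: np.ndarray
    home_channels: frozenset[int]
    n_member_spikes: int
    feature_vector: np.ndarray | None = None  # set by build_shared_space
    member_times: np.ndarray | None = None    # peak sample times of members

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(np.abs(self.waveform)))


@dataclass
class TemplateLibrary:
    """The merged template library plus cluster -> template provenance.

    ``provenance`` maps each original ``(group_channel, cluster_label)``
    to the index of the merged template that represents it; it is total
    and surjective onto the template list.
    """

    templates: list[Template]
    merge_sigma: float = 0.05
    provenance: dict[tuple[int, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.templates)


def estimate_template(snippets: list[Snippet], align_at: int | None = None) -> Template:
    """Pointwise mean of the cluster's waveforms.

    The mean (rather than the median) keeps this stage consistent with
    merging, which also averages.  When ``align_at`` is given, every
    member waveform is first re-anchored so its interpolated absolute
    peak sits at that index (see :mod:`htsort.waveforms`): averaging
    snippets whose discrete anchors straddle the true extremum would
    otherwise smear the template.  The pipeline passes the detection
    alignment offset.
    """
    if not snippets:
        raise ValueError("cannot estimate a template from an empty cluster")
    waveforms = np.stack([s.waveform for s in snippets])
    if align_at is not None:
        waveforms = align_peak_matrix(waveforms, float(align_at))
    return Template(
        waveform=waveforms.mean(axis=0),
        home_channels=frozenset({s.channel for s in snippets}),
        n_member_spikes=len(snippets),
        member_times=np.sort(np.array([s.peak_index for s in snippets])),
    )


def build_templates(
    clustered: list[tuple[SnippetGroup, object, ClusterLabeling]],
    align_at: int | None = None,
) -> tuple[list[Template], list[tuple[int, int]]]:
    """One template per (group, cluster); returns templates and their keys.

    Keys are ``(group_channel, cluster_label)`` pairs, ordered by channel
    then label, and feed the library's provenance map.  ``align_at`` is
    forwarded to :func:`estimate_template`.
    """
    templates: list[Template] = []
    keys: list[tuple[int, int]] = []
    for grp, _feats, labeling in clustered:
        for lab in range(labeling.n_clusters):
            members = [s for s, l in zip(grp.snippets, labeling.labels) if l == lab]
            templates.append(estimate_template(members, align_at=align_at))
            keys.append((grp.channel, lab))
    return templates, keys


def build_shared_space(
    templates: list[Template], n_components: int = SHARED_SPACE_COMPONENTS
) -> np.ndarray:
    """Assign each template a feature vector in the shared comparison space.

    Waveforms are peak-normalized (making the merge threshold a
    dimensionless, amplitude-free quantity), aligned to a common
    reference template by full-waveform cross-correlation (so neither
    alignment jitter nor a flipped peak anchor can masquerade as a shape
    difference; see :func:`htsort.waveforms.align_to_reference`), scaled by
    ``1/sqrt(L)`` so that a distance reads as the RMS per-sample
    deviation relative to a unit-peak waveform — a scale on which the
    default merge threshold of 0.05 means "5 % average disagreement" and
    is independent of window length and sampling rate — and projected
    onto a PCA basis fit on the normalized waveforms themselves.
    Euclidean distance in this space is the merge metric.  Returns the
    (n_templates, n_components) coordinate matrix and stores each vector
    on its template.
    """
    if not templates:
        raise ValueError("no templates to embed")
    L = templates[0].waveform.size
    ref = _reference_index(templates)
    ref_wave = align_peak(peak_normalize(templates[ref].waveform), L // 2)
    X = np.stack([
        align_to_reference(peak_normalize(t.waveform), ref_wave)
        for t in templates
    ]) / np.sqrt(L)
    n_comp = min(n_components, X.shape[0], X.shape[1])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    if n_comp < n_components:  # pad so distances stay comparable across runs
        coords = np.pad(coords, ((0, 0), (0, n_components - n_comp)))
    for t, v in zip(templates, coords):
        t.feature_vector = v
    return coords


def _reference_index(templates: list[Template]) -> int:
    """Deterministic, order-insensitive choice of the alignment reference.

    The best-populated template is the cleanest anchor; ties fall back to
    peak amplitude and finally to the waveform bytes themselves so the
    choice does not depend on list order.
    """
    return min(
        range(len(templates)),
        key=lambda i: (
            -templates[i].n_member_spikes,
            -templates[i].peak_amplitude,
            templates[i].waveform.tobytes(),
        ),
    )


def _channels_compatible(a: Template, b: Template, probe: ProbeGeometry) -> bool:
    """Merge criterion 2: some pair of home electrodes identical or neighbors."""
    for ca in a.home_channels:
        for cb in b.home_channels:
            if ca == cb or probe.are_neighbors(ca, cb):
                return True
    return False


def _refractory_conflict(
    ta: np.ndarray | None, tb: np.ndarray | None, sampling_rate: float,
    window_ms: tuple[float, float], max_fraction: float,
) -> bool:
    """True when two spike trains look like independent units.

    If two clusters are duplicates of one unit, the union of their spike
    trains still respects the neuron's absolute refractory period, so
    cross-cluster spike pairs closer than ~1 ms should be essentially
    absent.  Two independent units firing at rate r instead produce such
    pairs for a fraction ~2*r*window of their spikes (less after duplicate
    suppression, which eats many coincidences, so the threshold sits well
    below the naive expectation).  Pairs closer than the lower window
    edge are excluded: those are double detections of one physical spike
    (which the merge is meant to fix, not veto).  A single stray pair is
    never taken as evidence.
    """
    if ta is None or tb is None:
        return False
    lo = window_ms[0] / 1000.0 * sampling_rate
    hi = window_ms[1] / 1000.0 * sampling_rate
    idx = np.searchsorted(tb, ta)
    count = 0
    for t, i in zip(ta, idx):
        for j in (i - 1, i):
            if 0 <= j < tb.size and lo <= abs(t - tb[j]) <= hi:
                count += 1
                break
    return count >= 2 and count / min(ta.size, tb.size) > max_fraction


def _cross_amplitude_ok(
    a: Template, b: Template, recording, min_ratio: float,
) -> bool:
    """Merge criterion 3: each cluster's spikes must be full-size on the
    other cluster's home channel.

    Trigger-averaging the other channel's trace at this cluster's spike
    times recovers this unit's mean waveform there.  If the two clusters
    are one unit whose best channel flaps between two electrodes, that
    waveform has essentially the other template's amplitude; if they are
    two different units, each sees only the spatially decayed copy of the
    other — a factor that an electrode pitch of tens of micrometres makes
    small.  This evidence survives duplicate suppression and outlier
    triage, which silently delete the coincident spikes that a
    refractory-based test would need.
    """
    if a.member_times is None or b.member_times is None or recording is None:
        return True
    row_of = {cid: i for i, cid in enumerate(recording.probe.channel_ids)}

    def best_home(t: Template) -> int:
        return min(t.home_channels)

    def triggered_peak(times: np.ndarray, channel: int, L: int) -> float:
        trace = recording.traces[row_of[channel]]
        half = L // 2
        wins = [trace[t - half:t + L - half] for t in times[:400]
                if t - half >= 0 and t + L - half <= trace.size]
        if not wins:
            return 0.0
        return float(np.max(np.abs(np.mean(wins, axis=0))))

    L = a.waveform.size
    cha, chb = best_home(a), best_home(b)
    if cha == chb:
        return True
    amp_a_on_b = triggered_peak(a.member_times, chb, L)
    amp_b_on_a = triggered_peak(b.member_times, cha, L)
    ratio_a = amp_a_on_b / b.peak_amplitude if b.peak_amplitude > 0 else 0.0
    ratio_b = amp_b_on_a / a.peak_amplitude if a.peak_amplitude > 0 else 0.0
    return min(ratio_a, ratio_b) >= min_ratio


def merge_templates(
    library: TemplateLibrary,
    probe: ProbeGeometry,
    weighted: bool = True,
    sampling_rate: float | None = None,
    refractory_window_ms: tuple[float, float] = (0.3, 1.0),
    refractory_max_fraction: float = 0.004,
    recording=None,
    cross_amplitude_min_ratio: float = 0.5,
) -> TemplateLibrary:
    """Collapse redundant templates by the two-criterion rule.

    All pairs satisfying both the distance and the neighborhood criterion
    are unioned; each union is replaced by the mean of its members'
    waveforms — weighted by member-spike count by default, so a small spur
    cluster cannot drag a well-populated template (``weighted=False``
    gives the plain unweighted mean).  When ``sampling_rate`` is given and
    the templates carry member spike times, a union is vetoed if the two
    components' aggregate spike trains violate a common refractory period
    (see :func:`_refractory_conflict`) — two units can have near-identical
    waveforms on neighboring electrodes, and firing within a millisecond
    of each other is the one thing duplicates of a single neuron cannot
    do.  Candidate pairs are processed closest-first so that a small
    ambiguous cluster cannot bridge two units that the veto keeps apart.
    Passes repeat until no pair merges — averaging denoises templates, so
    duplicates that start just outside the threshold can become mergeable
    — making the result a true fixed point.  Provenance is composed so
    original clusters still resolve to their merged template.
    """
    if not library.templates:
        raise ValueError("cannot merge an empty library")
    for _pass in range(16):
        merged = _merge_once(library, probe, weighted, sampling_rate,
                             refractory_window_ms, refractory_max_fraction,
                             recording, cross_amplitude_min_ratio)
        if len(merged) == len(library):
            return merged
        library = merged
    return library


def _merge_once(
    library: TemplateLibrary,
    probe: ProbeGeometry,
    weighted: bool,
    sampling_rate: float | None,
    refractory_window_ms: tuple[float, float],
    refractory_max_fraction: float,
    recording=None,
    cross_amplitude_min_ratio: float = 0.5,
) -> TemplateLibrary:
    """One union-find pass of :func:`merge_templates`."""
    templates = library.templates
    if any(t.feature_vector is None for t in templates):
        build_shared_space(templates)

    n = len(templates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    coords = np.stack([t.feature_vector for t in templates])
    candidates = sorted(
        (float(np.linalg.norm(coords[i] - coords[j])), i, j)
        for i in range(n) for j in range(i + 1, n)
        if np.linalg.norm(coords[i] - coords[j]) < library.merge_sigma
        and _channels_compatible(templates[i], templates[j], probe)
        and _cross_amplitude_ok(templates[i], templates[j], recording,
                                cross_amplitude_min_ratio)
    )
    comp_times: dict[int, np.ndarray | None] = {
        i: templates[i].member_times for i in range(n)
    }
    for _dist, i, j in candidates:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if sampling_rate is not None and _refractory_conflict(
                comp_times[ri], comp_times[rj], sampling_rate,
                refractory_window_ms, refractory_max_fraction):
            continue
        root, other = min(ri, rj), max(ri, rj)
        parent[other] = root
        if comp_times[root] is not None and comp_times[other] is not None:
            comp_times[root] = np.sort(
                np.concatenate([comp_times[root], comp_times[other]]))
        else:
            comp_times[root] = None

    root_order: dict[int, int] = {}
    groups: dict[int, list[int]] = {}
    for i in range(n):
        r = find(i)
        if r not in root_order:
            root_order[r] = len(root_order)
        groups.setdefault(r, []).append(i)

    merged: list[Template] = []
    index_map: dict[int, int] = {}
    for r, new_idx in root_order.items():
        members = [templates[i] for i in groups[r]]
        w = np.array([t.n_member_spikes for t in members], dtype=float) if weighted \
            else np.ones(len(members))
        w /= w.sum()
        # members can disagree by a sub-sample shift or a flipped peak
        # anchor; averaging without re-registration would smear the spike
        anchor = members[_reference_index(members)].waveform
        waveform = np.sum([
            wi * (t.waveform if t.waveform is anchor
                  else align_to_reference(t.waveform, anchor))
            for wi, t in zip(w, members)
        ], axis=0)
        times = None
        if all(t.member_times is not None for t in members):
            times = np.sort(np.concatenate([t.member_times for t in members]))
        merged.append(
            Template(
                waveform=waveform,
                home_channels=frozenset().union(*(t.home_channels for t in members)),
                n_member_spikes=sum(t.n_member_spikes for t in members),
                member_times=times,
            )
        )
        for i in groups[r]:
            index_map[i] = new_idx

    build_shared_space(merged)
    provenance = (
        {key: index_map[old] for key, old in library.provenance.items()}
        if library.provenance
        else {(-1, i): index_map[i] for i in range(n)}
    )
    return TemplateLibrary(
        templates=merged, merge_sigma=library.merge_sigma, provenance=provenance
    )
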
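"""End-to-end sorting pipeline: preprocess, detect, group, cluster, merge, match.

``run_pipeline`` executes the full flow on a Recording and returns the
sorted spike table, the merged template library, and a run report whose
counts reconcile: every detected snippet is either suppressed as a
duplicate, assigned by clustering, recovered by pursuit, or discarded as
an unmatched outlier.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import detect as _detect
from . import group as _group
from . import io_probe as _io
from . import match as _match
from . import templates as _templates

__all__ = ["PipelineConfig", "SortResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter in one validated document.

    Defaults are the working values of each stage: detection k=4 on a
    3 ms window with centre alignment, 0.5 ms coincidence window,
    2-component per-group PCA, HDBSCAN min_cluster_size=10 /
    min_samples=5, merge sigma 0.05, pursuit acceptance 0.8 with at most
    5 subtractions, and a 1 ms evaluation tolerance.
    """

    # preprocessing
    bandpass_low: float = 300.0
    bandpass_high: float = 3000.0
    target_rate_hz: float | None = 14000.0
    # detection
    k: float = 4.0
    wnd_ms: float = 3.0
    p: float = 0.5
    # grouping
    delta_t_ms: float = 0.5
    # minimum waveform correlation for two coincident neighboring snippets
    # to count as copies of one spike (None disables the shape gate)
    coincidence_min_similarity: float | None = 0.8
    # clustering
    n_components: int = 2
    min_cluster_size: int = 10
    min_samples: int = 5
    # a cluster must also hold at least this fraction of its group: in a
    # busy group, pockets of a few dozen collision-distorted waveforms are
    # artifacts that belong in pursuit, not units of their own
    min_cluster_fraction: float = 0.025
    # width of the centred sub-window (ms) that clustering features are
    # computed on; the full snippet window is longer than a spike, and its
    # flanks can carry tails of neighboring spikes
    feature_ms: float = 1.5
    # template merging
    merge_sigma: float = 0.05
    merge_weighted: bool = True
    # cluster curation: a cluster whose template peak does not clear the
    # channel threshold by this factor is treated as an aligned-noise
    # artifact; its members are demoted to outliers for pursuit to triage
    min_template_amplitude_ratio: float = 1.2
    # unit curation: a merged unit most of whose spikes coincide (within
    # shadow_tol_ms) with spikes of larger units is a collision echo, not
    # a neuron — two neurons fire independently, so at most a modest
    # share of a real unit's spikes can coincide with anything else
    shadow_max_fraction: float = 0.5
    shadow_tol_ms: float = 1.0
    # pursuit
    accept_threshold: float = 0.8
    max_pursuit: int = 5
    metric: str = "ncc"
    scale_subtraction: bool = True
    # least-squares amplitude window for a pursuit match to be reported:
    # templates carry absolute amplitude, so a genuine occurrence fits
    # near 1; far-off scales are echoes of spikes claimed elsewhere
    pursuit_amplitude_range: tuple[float, float] | None = (0.6, 1.6)
    # evaluation
    tol_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_t_ms >= self.wnd_ms / 2.0:
            warnings.warn(
                f"delta_t_ms={self.delta_t_ms} is not below half the window "
                f"({self.wnd_ms / 2.0} ms); coincident peaks may be ambiguous",
                UserWarning,
                stacklevel=2,
            )
        if self.metric not in ("ncc", "sqdiff"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if not 0.0 < self.accept_threshold < 1.0:
            raise ValueError("accept_threshold must lie in (0, 1)")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load TOML or JSON depending on extension."""
        import json
        from pathlib import Path

        p = Path(path)
        if p.suffix == ".toml":
            import tomllib

            doc = tomllib.loads(p.read_text())
        else:
            doc = json.loads(p.read_text())
        return cls.from_dict(doc)


def _drop_shadow_units(
    spikes: pd.DataFrame,
    library: _templates.TemplateLibrary,
    max_fraction: float,
    tol: int,
) -> tuple[pd.DataFrame, int]:
    """Drop units whose spikes mostly coincide with larger units' spikes.

    Walks units largest-first; a smaller unit whose spike times lie within
    ``tol`` samples of retained units' spikes for more than
    ``max_fraction`` of its spikes is a collision echo and is removed.
    The library is renumbered in place to match the returned table.
    """
    if spikes.empty:
        return spikes, 0
    sizes = spikes.groupby("unit").size()
    order = sorted(sizes.index, key=lambda u: (-sizes[u], u))
    times = {u: np.sort(spikes.loc[spikes.unit == u, "time"].to_numpy())
             for u in order}
    kept_times: np.ndarray | None = None
    dropped: set[int] = set()
    for u in order:
        t = times[u]
        if kept_times is not None and t.size:
            idx = np.searchsorted(kept_times, t)
            hits = 0
            for x, k in zip(t, idx):
                for j in (k - 1, k):
                    if 0 <= j < kept_times.size and \
                            abs(int(x) - int(kept_times[j])) <= tol:
                        hits += 1
                        break
            if hits / t.size > max_fraction:
                dropped.add(int(u))
                continue
        kept_times = t if kept_times is None else \
            np.sort(np.concatenate([kept_times, t]))
    if not dropped:
        return spikes, 0
    remap: dict[int, int] = {}
    kept_templates: list[_templates.Template] = []
    for i, tmpl in enumerate(library.templates):
        if i not in dropped:
            remap[i] = len(kept_templates)
            kept_templates.append(tmpl)
    library.templates = kept_templates
    library.provenance = {k: remap[v] for k, v in library.provenance.items()
                          if v in remap}
    spikes = spikes[~spikes["unit"].isin(dropped)].copy()
    spikes["unit"] = spikes["unit"].map(remap)
    return spikes.reset_index(drop=True), len(dropped)


@dataclass
class SortResult:
    """Pipeline output bundle."""

    spikes: pd.DataFrame  # columns: time, unit, score, source
    library: _templates.TemplateLibrary
    report: dict
    sampling_rate: float


def run_pipeline(rec: _io.Recording, config: PipelineConfig | None = None) -> SortResult:
    """Run the whole sorting flow on one recording.

    Stages: zero-phase bandpass -> optional resample -> per-channel
    threshold detection -> divide-and-conquer duplicate suppression and
    grouping -> per-group PCA + HDBSCAN -> template estimation and
    merging -> pursuit on the outliers.  Deterministic for a fixed input
    and config.
    """
    cfg = config or PipelineConfig()

    filtered = _io.bandpass(rec, cfg.bandpass_low, cfg.bandpass_high)
    if cfg.target_rate_hz and cfg.target_rate_hz != filtered.sampling_rate:
        filtered = _io.resample(filtered, cfg.target_rate_hz)
    rate = filtered.sampling_rate

    params = _detect.DetectionParams(k=cfg.k, wnd_ms=cfg.wnd_ms, p=cfg.p)
    thresholds = _detect.channel_thresholds(filtered, params)
    per_channel = {
        ch: _detect.detect_snippets(filtered.traces[row], params, rate,
                                    channel=ch, threshold=thresholds[ch])
        for row, ch in enumerate(filtered.probe.channel_ids)
    }
    n_detected = sum(len(v) for v in per_channel.values())

    events = _group.coalesce_events(
        per_channel, filtered.probe, cfg.delta_t_ms, rate,
        min_shape_similarity=cfg.coincidence_min_similarity,
    )
    groups = _group.build_groups(events)

    L = _detect.snippet_length(cfg.wnd_ms, rate)
    off = _detect.align_offset(cfg.wnd_ms, cfg.p, rate)
    half_feat = int(round(cfg.feature_ms / 2.0 / 1000.0 * rate))
    feature_slice = slice(max(off - half_feat, 0), min(off + half_feat, L))
    clustered = []
    for grp in groups:
        mcs = max(cfg.min_cluster_size,
                  int(np.ceil(cfg.min_cluster_fraction * len(grp.snippets))))
        feats = _cluster.fit_features(grp, n_components=cfg.n_components,
                                      feature_slice=feature_slice,
                                      align_at=float(off))
        labeling = _cluster.cluster_group(feats, min_cluster_size=mcs,
                                          min_samples=cfg.min_samples)
        clustered.append((grp, feats, labeling))

    # demote noise-like clusters: snippets cut from threshold-grazing noise
    # cluster together (they are all aligned noise bumps), but their mean
    # waveform barely clears the threshold, unlike any real unit's template
    n_demoted = 0
    for grp, _feats, labeling in clustered:
        floor = cfg.min_template_amplitude_ratio * thresholds[grp.channel]
        keep: dict[int, int] = {}
        for lab in range(labeling.n_clusters):
            members = [s for s, l in zip(grp.snippets, labeling.labels) if l == lab]
            tmpl = _templates.estimate_template(members)
            if tmpl.peak_amplitude >= floor:
                keep[lab] = len(keep)
        if len(keep) < labeling.n_clusters:
            n_demoted += int(sum(1 for l in labeling.labels
                                 if l >= 0 and l not in keep))
            labeling.labels = np.array([keep.get(l, -1) for l in labeling.labels])
            labeling.n_clusters = len(keep)
    n_clusters = sum(lab.n_clusters for _, _, lab in clustered)

    align_at = off
    rows: list[tuple[int, int, float, str]] = []
    outliers: list[_detect.Snippet] = []
    raw_templates, keys = _templates.build_templates(clustered, align_at=align_at)
    if raw_templates:
        _templates.build_shared_space(raw_templates)
        library = _templates.TemplateLibrary(
            templates=raw_templates,
            merge_sigma=cfg.merge_sigma,
            provenance={key: i for i, key in enumerate(keys)},
        )
        pre_merge = len(library)
        library = _templates.merge_templates(library, filtered.probe,
                                             weighted=cfg.merge_weighted,
                                             sampling_rate=rate,
                                             recording=filtered)

        # shadow-unit curation: walk units largest-first; a unit whose
        # spikes mostly coincide with already-retained units' spikes is a
        # collision echo — dissolve it and let pursuit re-triage its spikes
        dissolved: set[int] = set()
        tol = int(round(cfg.shadow_tol_ms / 1000.0 * rate))
        retained_times: np.ndarray | None = None
        for i in sorted(range(len(library.templates)),
                        key=lambda i: (-library.templates[i].n_member_spikes, i)):
            times = library.templates[i].member_times
            if times is None:
                continue
            if retained_times is not None and times.size:
                idx = np.searchsorted(retained_times, times)
                hits = 0
                for x, k in zip(times, idx):
                    for j in (k - 1, k):
                        if 0 <= j < retained_times.size and \
                                abs(int(x) - int(retained_times[j])) <= tol:
                            hits += 1
                            break
                if hits / times.size > cfg.shadow_max_fraction:
                    dissolved.add(i)
                    continue
            retained_times = times if retained_times is None else \
                np.sort(np.concatenate([retained_times, times]))

        provenance_full = dict(library.provenance)
        if dissolved:
            keep_map: dict[int, int] = {}
            kept: list[_templates.Template] = []
            for i, t in enumerate(library.templates):
                if i not in dissolved:
                    keep_map[i] = len(kept)
                    kept.append(t)
            library = _templates.TemplateLibrary(
                templates=kept, merge_sigma=cfg.merge_sigma,
                provenance={k: keep_map[v] for k, v in provenance_full.items()
                            if v in keep_map},
            )
            provenance_full = {k: keep_map.get(v, -1)
                               for k, v in provenance_full.items()}

        for grp, _feats, labeling in clustered:
            for snip, lab in zip(grp.snippets, labeling.labels):
                unit = -1 if lab < 0 else provenance_full[(grp.channel, lab)]
                if unit < 0:
                    outliers.append(snip)
                else:
                    rows.append((snip.peak_index, unit, np.nan, "cluster"))
        n_shadow = len(dissolved)
        pursued, n_matched_outliers = _match.resolve_outliers(
            outliers, library, filtered, thresholds,
            accept_threshold=cfg.accept_threshold,
            max_iterations=cfg.max_pursuit, metric=cfg.metric,
            scale_subtraction=cfg.scale_subtraction,
            amplitude_range=cfg.pursuit_amplitude_range,
        )
    else:
        library = _templates.TemplateLibrary(templates=[],
                                             merge_sigma=cfg.merge_sigma)
        pre_merge = 0
        outliers = [s for grp, _f, lab in clustered
                    for s, l in zip(grp.snippets, lab.labels) if l < 0]
        pursued, n_matched_outliers = [], 0
        n_shadow = 0

    # deduplicate pursuit output against spikes already claimed by clustering
    # (and against itself): same unit within half a detection window
    dedup_tol = int(round(cfg.wnd_ms / 2.0 / 1000.0 * rate))
    claimed: dict[int, list[int]] = {}
    for t, u, _s, _src in rows:
        claimed.setdefault(u, []).append(t)
    n_dup = 0
    for t, u, score in sorted(pursued):
        near = claimed.get(u, [])
        if any(abs(t - x) <= dedup_tol for x in near):
            n_dup += 1
            continue
        claimed.setdefault(u, []).append(t)
        rows.append((t, u, score, "pursuit"))

    spikes = pd.DataFrame(rows, columns=["time", "unit", "score", "source"])
    spikes = spikes.sort_values(["time", "unit"], kind="stable",
                                ignore_index=True)

    # second shadow pass on the final table: an echo unit whose partners
    # were recovered by pursuit is invisible to the pre-pursuit pass
    pre_drop_cluster = int((spikes["source"] == "cluster").sum())
    pre_drop_pursuit = int((spikes["source"] == "pursuit").sum())
    spikes, n_late_shadow = _drop_shadow_units(
        spikes, library, cfg.shadow_max_fraction,
        int(round(cfg.shadow_tol_ms / 1000.0 * rate)))
    n_shadow += n_late_shadow
    late_cluster_dropped = pre_drop_cluster - int(
        (spikes["source"] == "cluster").sum())
    late_pursuit_dropped = pre_drop_pursuit - int(
        (spikes["source"] == "pursuit").sum())

    n_pursuit = int((spikes["source"] == "pursuit").sum())
    report = {
        "sampling_rate_hz": rate,
        "snippets_detected": n_detected,
        "events_coalesced": len(events),
        "duplicates_suppressed": n_detected - len(events),
        "clustered_spikes": int((spikes["source"] == "cluster").sum()),
        "outliers": len(outliers),
        "clusters_found": n_clusters,
        "cluster_spikes_demoted": n_demoted,
        "templates_pre_merge": pre_merge,
        "templates_post_merge": len(library),
        "shadow_units_dissolved": n_shadow,
        "late_shadow_cluster_spikes_dropped": late_cluster_dropped,
        "late_shadow_pursuit_spikes_dropped": late_pursuit_dropped,
        "pursuit_accepted": n_pursuit,
        "pursuit_duplicates_dropped": n_dup,
        "outliers_resolved": n_matched_outliers,
        "outliers_discarded": len(outliers) - n_matched_outliers,
        "sorted_spikes": len(spikes),
        "config": asdict(cfg),
    }
    return SortResult(spikes=spikes, library=library, report=report,
                      sampling_rate=rate)
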
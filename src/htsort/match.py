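"""Greedy template-matching pursuit for overlapping-spike resolution.

Snippets that the clusterer labeled as outliers are either background
noise or collisions (superimposed spikes).  Pursuit distinguishes them:
repeatedly find the library template with the highest normalized
cross-correlation against the residual segment over all admissible lags;
accept it only if the score exceeds 0.8; subtract the least-squares
amplitude-scaled template at the matched lag; stop when the residual peak
drops below ``dtc_th`` (set to the channel's detection threshold — below
it, nothing left resembles a spike), when the best candidate is rejected,
or at the iteration cap.  Unmatched outliers are discarded as noise, which
is what makes a lenient detection threshold harmless.

The match score is the normalized cross-correlation
``sum(T*I) / sqrt(sum(T^2) * sum(I^2))`` — dimensionless, scale-invariant,
maximal (1) at a perfect shape match.  A normalized squared-difference
score is available as an alternative metric for comparison; with it a
candidate is accepted when ``1 - R > 0.8``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .templates import TemplateLibrary

__all__ = [
    "MatchResult",
    "AcceptedSpike",
    "similarity",
    "best_match",
    "pursue",
    "resolve_outliers",
]


@dataclass(frozen=True)
class AcceptedSpike:
    """One spike recovered from a segment by pursuit."""

    template_id: int
    lag: int          # template start offset within the segment, samples
    score: float
    amplitude: float  # least-squares scale applied at subtraction


@dataclass
class MatchResult:
    """Outcome of pursuing one outlier segment."""

    accepted_spikes: list[AcceptedSpike]
    residual: np.ndarray
    n_iterations: int
    truncated: bool = False
    residual_energies: list[float] = field(default_factory=list)


def similarity(segment: np.ndarray, template: np.ndarray, lag: int,
               metric: str = "ncc") -> float:
    """Match score between ``template`` and ``segment[lag : lag+len(template)]``.

    ``metric="ncc"`` (default) is the normalized cross-correlation in
    [-1, 1]; ``metric="sqdiff"`` is the normalized squared difference
    ``sum((T-I)^2) / sqrt(sum(T^2) * sum(I^2))`` (0 at a perfect match).
    An all-zero template or window scores 0 — no evidence either way.
    """
    T = np.asarray(template, dtype=float)
    if lag < 0 or lag + T.size > len(segment):
        raise ValueError("template window at this lag overhangs the segment")
    I = np.asarray(segment[lag:lag + T.size], dtype=float)
    et, ei = float(T @ T), float(I @ I)
    if et == 0.0 or ei == 0.0:
        return 0.0
    if metric == "ncc":
        return float(T @ I) / np.sqrt(et * ei)
    if metric == "sqdiff":
        d = T - I
        return float(d @ d) / np.sqrt(et * ei)
    raise ValueError(f"unknown metric {metric!r}")


def _score_all_lags(segment: np.ndarray, template: np.ndarray,
                    metric: str) -> np.ndarray:
    """Vectorized :func:`similarity` over every admissible lag."""
    T = np.asarray(template, float)
    seg = np.asarray(segment, float)
    n_lags = len(seg) - T.size + 1
    if n_lags <= 0:
        return np.empty(0)
    cross = np.correlate(seg, T, mode="valid")           # sum(T*I) per lag
    win_e = np.convolve(seg ** 2, np.ones(T.size), mode="valid")
    et = float(T @ T)
    denom = np.sqrt(et * win_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        if metric == "ncc":
            scores = np.where(denom > 0, cross / denom, 0.0)
        else:
            sq = et + win_e - 2 * cross                   # sum((T-I)^2) per lag
            scores = np.where(denom > 0, sq / denom, 0.0)
    return scores


def best_match(segment: np.ndarray, library: TemplateLibrary,
               metric: str = "ncc") -> tuple[int, int, float]:
    """Best (template, lag) over the whole library.

    For the NCC metric "best" maximizes the score; for the squared
    difference it maximizes ``1 - score``.  Ties break toward the lower
    template id, then the earlier lag.
    """
    if not library.templates:
        raise ValueError("template library is empty")
    best: tuple[int, int, float] | None = None
    for tid, tmpl in enumerate(library.templates):
        scores = _score_all_lags(segment, tmpl.waveform, metric)
        if scores.size == 0:
            continue
        goodness = scores if metric == "ncc" else 1.0 - scores
        lag = int(np.argmax(goodness))  # first occurrence = earliest lag
        if best is None or goodness[lag] > best_goodness:
            best = (tid, lag, float(scores[lag]))
            best_goodness = goodness[lag]
    if best is None:
        raise ValueError("no admissible lag: segment shorter than every template")
    return best


def pursue(
    segment: np.ndarray,
    library: TemplateLibrary,
    dtc_th: float,
    accept_threshold: float = 0.8,
    max_iterations: int = 5,
    metric: str = "ncc",
    scale_subtraction: bool = True,
    amplitude_range: tuple[float, float] | None = (0.6, 1.6),
) -> MatchResult:
    """Greedy matching pursuit on one segment.

    Iterates best-match / accept / subtract.  A candidate is accepted when
    its score clears ``accept_threshold`` (NCC > threshold, or
    ``1 - sqdiff`` > threshold).  Subtraction removes ``beta * template``
    with ``beta`` the least-squares amplitude at the matched lag
    (``scale_subtraction=False`` subtracts the raw template).

    Because templates carry absolute amplitude, a genuine occurrence of a
    unit on its own channel fits at ``beta`` near 1; a shape-similar
    component at a very different scale is typically the attenuated echo
    of a spike already claimed on a neighboring channel.  When
    ``amplitude_range`` is set, such components are still subtracted — so
    the pursuit can proceed past them — but are not reported as spikes.

    Termination: residual peak below ``dtc_th``, candidate rejected, or
    the iteration cap (then ``truncated`` is flagged, not raised).
    """
    if dtc_th <= 0:
        raise ValueError("dtc_th must be positive")
    residual = np.asarray(segment, dtype=float).copy()
    accepted: list[AcceptedSpike] = []
    energies = [float(residual @ residual)]
    n_iter = 0
    truncated = False
    # the stop-on-small-residual test applies after a subtraction, so the
    # first candidate is always examined (and rejected on its score alone
    # for a segment that never held a spike)
    while True:
        if n_iter >= max_iterations:
            truncated = True
            break
        n_iter += 1
        tid, lag, score = best_match(residual, library, metric=metric)
        goodness = score if metric == "ncc" else 1.0 - score
        if goodness <= accept_threshold:
            break
        tmpl = library.templates[tid].waveform
        window = slice(lag, lag + tmpl.size)
        et = float(tmpl @ tmpl)
        beta = float(tmpl @ residual[window]) / et if (scale_subtraction and et > 0) \
            else 1.0
        residual[window] -= beta * tmpl
        if amplitude_range is None or \
                amplitude_range[0] <= beta <= amplitude_range[1]:
            accepted.append(AcceptedSpike(tid, lag, score, beta))
        energies.append(float(residual @ residual))
        if np.max(np.abs(residual)) < dtc_th:
            break
    return MatchResult(
        accepted_spikes=accepted,
        residual=residual,
        n_iterations=n_iter,
        truncated=truncated,
        residual_energies=energies,
    )


def resolve_outliers(
    outlier_snippets,
    library: TemplateLibrary,
    recording,
    thresholds: dict[int, float],
    accept_threshold: float = 0.8,
    max_iterations: int = 5,
    metric: str = "ncc",
    scale_subtraction: bool = True,
    amplitude_range: tuple[float, float] | None = (0.6, 1.6),
    context_factor: int = 1,
) -> tuple[list[tuple[int, int, float]], int]:
    """Pursue every outlier snippet against the recording.

    For each outlier a segment of the band-passed trace around the
    snippet's peak is extracted — one extra window length of context on
    each side (``context_factor``) so that lags spanning the full snippet
    window are admissible.  ``dtc_th`` is the detection threshold of the
    snippet's channel.  Returns recovered spikes as
    ``(peak_sample_index, template_id, score)`` tuples plus the number of
    outliers that yielded at least one spike; unmatched outliers
    contribute nothing (discarded as noise).
    """
    row_of = {cid: i for i, cid in enumerate(recording.probe.channel_ids)}
    spikes: list[tuple[int, int, float]] = []
    n_matched = 0
    if not library.templates:
        return spikes, n_matched
    L = library.templates[0].waveform.size
    peak_offsets = [int(np.argmax(np.abs(t.waveform))) for t in library.templates]

    # an outlier on channel c can only contain spikes of units that are
    # visible on c, so each channel is matched against the templates homed
    # on it or on a neighboring electrode; this also keeps two units with
    # coincidentally similar waveforms at opposite ends of the probe from
    # stealing each other's spikes
    probe = recording.probe
    local_lib: dict[int, tuple[TemplateLibrary, list[int]]] = {}
    for cid in probe.channel_ids:
        ids = [tid for tid, t in enumerate(library.templates)
               if any(h == cid or probe.are_neighbors(h, cid)
                      for h in t.home_channels)]
        sub = TemplateLibrary(
            templates=[library.templates[tid] for tid in ids],
            merge_sigma=library.merge_sigma,
        )
        local_lib[cid] = (sub, ids)

    for snip in outlier_snippets:
        sub, ids = local_lib[snip.channel]
        if not sub.templates:
            continue
        trace = recording.traces[row_of[snip.channel]]
        start = snip.peak_index - (L // 2) - context_factor * L
        stop = snip.peak_index + (L - L // 2) + context_factor * L
        lo, hi = max(start, 0), min(stop, trace.size)
        segment = trace[lo:hi]
        if segment.size < L:
            continue
        result = pursue(
            segment, sub, dtc_th=thresholds[snip.channel],
            accept_threshold=accept_threshold, max_iterations=max_iterations,
            metric=metric, scale_subtraction=scale_subtraction,
            amplitude_range=amplitude_range,
        )
        matched_here = 0
        for acc in result.accepted_spikes:
            acc = AcceptedSpike(ids[acc.template_id], acc.lag, acc.score,
                                acc.amplitude)
            peak = lo + acc.lag + peak_offsets[acc.template_id]
            # context may contain neighboring spikes already claimed by
            # clustering; only spikes inside the outlier's own window are
            # attributable to this event
            if abs(peak - snip.peak_index) <= L // 2:
                spikes.append((int(peak), acc.template_id, acc.score))
                matched_here += 1
        n_matched += matched_here > 0
    return spikes, n_matched
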
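"""Ground-truth scoring: spike pairing and accuracy / precision / recall.

For every (ground-truth unit, sorter unit) pair, spikes are paired
greedily one-to-one within a time tolerance (two-pointer sweep over the
sorted time lists).  Each ground-truth unit is then assigned the sorter
unit that maximizes the pair's accuracy ``tp / (tp + fp + fn)``,
injectively, in descending accuracy order, so no sorter unit is credited
twice.  Per-unit metrics:

    accuracy  = tp / (tp + fp + fn)
    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)

with tp + fn equal to the unit's ground-truth spike count and fp the
assigned sorter unit's unpaired spikes.  A zero denominator scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GroundTruth

__all__ = [
    "MatchTable",
    "greedy_pair_count",
    "match_spikes",
    "accuracy",
    "precision",
    "recall",
    "report",
]


@dataclass
class MatchTable:
    """Per ground-truth unit pairing outcome.

    ``rows`` columns: gt_unit, sorter_unit (-1 if none assigned), tp, fp,
    fn.  ``tol_ms`` is the pairing tolerance used.
    """

    rows: pd.DataFrame
    tol_ms: float
    n_sorter_units: int


def greedy_pair_count(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    """Number of one-to-one pairs between sorted time lists within ``tol``.

    Two-pointer sweep: advance whichever unmatched head is earlier; a pair
    is made whenever the heads are within tolerance.
    """
    i = j = matched = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched


def match_spikes(
    gt: GroundTruth | tuple[np.ndarray, np.ndarray],
    sorted_spikes: pd.DataFrame,
    tol_ms: float = 1.0,
    sampling_rate: float | None = None,
) -> MatchTable:
    """Pair sorter output with ground truth and count tp / fp / fn.

    ``sorted_spikes`` needs columns ``time`` (sample index) and ``unit``.
    ``gt`` is a GroundTruth (sampling rate taken from its spec unless
    overridden) or a raw ``(times, units)`` tuple with ``sampling_rate``
    given explicitly.
    """
    if isinstance(gt, GroundTruth):
        gt_times, gt_units = gt.spike_times, gt.spike_units
        rate = sampling_rate or gt.spec.sampling_rate_hz
    else:
        gt_times, gt_units = gt
        if sampling_rate is None:
            raise ValueError("sampling_rate required with raw ground-truth arrays")
        rate = sampling_rate
    tol = tol_ms / 1000.0 * rate

    gt_ids = np.unique(gt_units)
    sorter_ids = (np.unique(sorted_spikes["unit"].to_numpy())
                  if len(sorted_spikes) else np.array([], dtype=int))
    gt_by = {g: np.sort(gt_times[gt_units == g]) for g in gt_ids}
    srt_by = {s: np.sort(sorted_spikes.loc[sorted_spikes["unit"] == s, "time"]
                         .to_numpy()) for s in sorter_ids}

    # candidate (gt, sorter) accuracies
    cand = []
    for g in gt_ids:
        for s in sorter_ids:
            tp = greedy_pair_count(gt_by[g], srt_by[s], tol)
            acc = accuracy(tp, len(srt_by[s]) - tp, len(gt_by[g]) - tp)
            if tp > 0:
                cand.append((acc, g, s, tp))
    cand.sort(key=lambda r: (-r[0], r[1], r[2]))

    assigned_gt: dict[int, tuple[int, int]] = {}
    used_sorters: set[int] = set()
    for acc, g, s, tp in cand:
        if g in assigned_gt or s in used_sorters:
            continue
        assigned_gt[g] = (s, tp)
        used_sorters.add(s)

    rows = []
    for g in gt_ids:
        n_gt = len(gt_by[g])
        if g in assigned_gt:
            s, tp = assigned_gt[g]
            rows.append((g, s, tp, len(srt_by[s]) - tp, n_gt - tp))
        else:
            rows.append((g, -1, 0, 0, n_gt))
    frame = pd.DataFrame(rows, columns=["gt_unit", "sorter_unit", "tp", "fp", "fn"])
    return MatchTable(rows=frame, tol_ms=tol_ms, n_sorter_units=len(sorter_ids))


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def accuracy(tp: int, fp: int, fn: int) -> float:
    """``tp / (tp + fp + fn)``; 0 when the denominator vanishes."""
    return _safe_ratio(tp, tp + fp + fn)


def precision(tp: int, fp: int) -> float:
    """``tp / (tp + fp)``; 0 when the denominator vanishes."""
    return _safe_ratio(tp, tp + fp)


def recall(tp: int, fn: int) -> float:
    """``tp / (tp + fn)``; 0 when the denominator vanishes."""
    return _safe_ratio(tp, tp + fn)


def report(table: MatchTable) -> pd.DataFrame:
    """Per-unit metrics plus an unweighted mean row (gt_unit = -1).

    The mean row averages accuracy, precision and recall over ground-truth
    units and carries the detected-unit count in ``sorter_unit``.
    """
    rows = table.rows.copy()
    rows["accuracy"] = [accuracy(t, f, n) for t, f, n in
                        zip(rows["tp"], rows["fp"], rows["fn"])]
    rows["precision"] = [precision(t, f) for t, f in zip(rows["tp"], rows["fp"])]
    rows["recall"] = [recall(t, n) for t, n in zip(rows["tp"], rows["fn"])]
    mean = pd.DataFrame(
        [{
            "gt_unit": -1,
            "sorter_unit": table.n_sorter_units,
            "tp": rows["tp"].sum(),
            "fp": rows["fp"].sum(),
            "fn": rows["fn"].sum(),
            "accuracy": rows["accuracy"].mean(),
            "precision": rows["precision"].mean(),
            "recall": rows["recall"].mean(),
        }]
    )
    return pd.concat([rows, mean], ignore_index=True)
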
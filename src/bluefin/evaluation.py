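"""Matching automated detections to manual annotations and scoring detectors.

A detection matches an annotation if their time intervals overlap at all.
Matching is greedy in ascending trigger order: the first detection to overlap
an annotation claims it; later detections overlapping only already-claimed
annotations are *duplicates*, counted neither as true nor false positives.

Because the refractory period prevents detections from overlapping, a
recording of duration ``T`` offers ``floor(T / delta)`` non-overlapping
detection opportunities, where ``delta`` is the detector's effective
detection period (defaulting to the mean annotation duration ``d_bar``:
13 s for pooled blue whale song, 2.5 s for pooled fin 20 Hz pulses).  The
number of *negative* opportunities subtracts the slots occupied by
annotations, and the false positive rate is false positives per negative
opportunity.  At ``delta = 2.5`` s a 1% false positive rate is ~14.4 false
positives per hour; at 13 s, ~2.8 per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations import Annotation
from .detectors import DetectionEvent

TP, FP, DUPLICATE = "TP", "FP", "duplicate"


@dataclass
class MatchResult:
    """Outcome of matching one detection list against one annotation list.

    ``statuses[i]`` is TP/FP/duplicate for the i-th detection (in ascending
    trigger order); ``matched[j]`` flags whether annotation j was claimed;
    ``matched_by[j]`` is the index (into the sorted detections) of the
    claiming detection, or -1.
    """

    statuses: list[str]
    matched: list[bool]
    matched_by: list[int]

    @property
    def n_tp(self) -> int:
        return self.statuses.count(TP)

    @property
    def n_fp(self) -> int:
        return self.statuses.count(FP)

    @property
    def n_duplicate(self) -> int:
        return self.statuses.count(DUPLICATE)


def match_events(
    detections: Sequence[DetectionEvent],
    annotations: Sequence[Annotation],
) -> MatchResult:
    """Greedy ascending-time matching of detections to annotations.

    Each annotation contributes at most one true positive.  A detection
    overlapping at least one unclaimed annotation is a TP and claims the
    earliest such annotation; one overlapping only claimed annotations is a
    duplicate; one overlapping none is a FP.
    """
    order = sorted(range(len(detections)), key=lambda i: detections[i].trigger)
    anns = sorted(range(len(annotations)), key=lambda j: annotations[j].begin)
    matched = [False] * len(annotations)
    matched_by = [-1] * len(annotations)
    statuses: list[str] = []
    for rank, i in enumerate(order):
        det = detections[i]
        overlapping = [
            j for j in anns if annotations[j].overlaps(det.begin, det.end)
        ]
        if not overlapping:
            statuses.append(FP)
            continue
        unclaimed = [j for j in overlapping if not matched[j]]
        if unclaimed:
            j = unclaimed[0]
            matched[j] = True
            matched_by[j] = rank
            statuses.append(TP)
        else:
            statuses.append(DUPLICATE)
    return MatchResult(statuses=statuses, matched=matched, matched_by=matched_by)


def possible_detections(recording_duration_s: float, delta_s: float) -> int:
    """Number of non-overlapping detection opportunities in a recording.

    ``floor(duration / delta)``; 0 for non-positive durations.
    """
    if delta_s <= 0:
        raise ValueError("effective detection period must be positive")
    if recording_duration_s <= 0:
        return 0
    return int(math.floor(recording_duration_s / delta_s))


def false_alarms_per_hour(
    fpr: float, delta_s: float, recording_duration_s: float = 3600.0
) -> float:
    """Convert a false positive rate into false positives per hour.

    Uses the slot arithmetic: ``fpr * floor(T / delta)`` false positives in
    ``T`` seconds, expressed per hour.
    """
    n_slots = possible_detections(recording_duration_s, delta_s)
    return fpr * n_slots / (recording_duration_s / 3600.0)


@dataclass(frozen=True)
class ConfusionTable:
    """Confusion counts and rates for one detector threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_neg: int
    tpr: float
    fpr: float
    precision: float
    recall: float
    fp_per_hour: float
    threshold: float | None = None

    @property
    def precision_defined(self) -> bool:
        return not math.isnan(self.precision)


def tabulate(
    match: MatchResult,
    annotations: Sequence[Annotation],
    recording_duration_s: float,
    delta_s: float,
    threshold: float | None = None,
) -> ConfusionTable:
    """Confusion table from a match result.

    Negative opportunities ``N_neg`` are total slots minus
    ``ceil(total annotated duration / delta)``; ``FPR = FP / N_neg``;
    ``TPR = recall = TP / n_annotations``; ``TN = N_neg - FP``.  Precision is
    NaN (flagged undefined) when there are no TP+FP detections; recall is NaN
    when there are no annotations.

    Raises
    ------
    ValueError
        If annotations saturate the recording (``N_neg <= 0``).
    """
    n_ann = len(annotations)
    tp, fp = match.n_tp, match.n_fp
    total_slots = possible_detections(recording_duration_s, delta_s)
    occupied = int(math.ceil(sum(a.duration for a in annotations) / delta_s))
    n_neg = total_slots - occupied
    if n_neg <= 0:
        raise ValueError(
            f"recording saturated with annotations: {occupied} occupied slots "
            f">= {total_slots} total"
        )
    fn = n_ann - tp
    tpr = recall = tp / n_ann if n_ann > 0 else float("nan")
    fpr = fp / n_neg
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return ConfusionTable(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=n_neg - fp,
        n_neg=n_neg,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=recall,
        fp_per_hour=3600.0 * fp / recording_duration_s,
        threshold=threshold,
    )


@dataclass(frozen=True)
class CurvePoint:
    """One ROC / precision-recall point at a given threshold."""

    threshold: float
    fpr: float
    tpr: float
    precision: float
    recall: float


def sweep_curves(
    detections_by_threshold: Mapping[float, Sequence[DetectionEvent]],
    annotations: Sequence[Annotation],
    recording_duration_s: float,
    delta_s: float,
) -> list[CurvePoint]:
    """ROC / PR points over a threshold sweep, ascending in threshold.

    Each threshold's detections are matched and tabulated independently; on a
    fixed score series, raising the threshold moves ROC points towards the
    origin (both coordinates non-increasing).
    """
    points = []
    for th in sorted(detections_by_threshold):
        match = match_events(detections_by_threshold[th], annotations)
        table = tabulate(
            match, annotations, recording_duration_s, delta_s, threshold=th
        )
        points.append(
            CurvePoint(
                threshold=float(th),
                fpr=table.fpr,
                tpr=table.tpr,
                precision=table.precision,
                recall=table.recall,
            )
        )
    return points
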
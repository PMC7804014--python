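"""Detection/annotation matching, confusion arithmetic, ROC/PR sweeps."""

import numpy as np
import pytest

from bluefin.annotations import Annotation
from bluefin.detectors import DetectionEvent
from bluefin.evaluation import (
    false_alarms_per_hour,
    match_events,
    possible_detections,
    sweep_curves,
    tabulate,
)


def det(begin, end, threshold=1.0, score=10.0):
    trigger = (begin + end) / 2.0
    return DetectionEvent(trigger, begin, end, score, threshold)


def ann(begin, end, label="Bm-Ant-Z"):
    return Annotation(begin, end, 17.0, 29.0, label)


class TestMatchEvents:
    def test_any_overlap_is_a_match(self):
        result = match_events([det(10, 15)], [ann(14, 20)])
        assert result.statuses == ["TP"]
        assert result.matched == [True]

    def test_disjoint_intervals_are_false_positives(self):
        result = match_events([det(10, 15)], [ann(15.5, 20)])
        assert result.statuses == ["FP"]
        assert result.matched == [False]

    def test_second_overlapping_detection_is_duplicate(self):
        result = match_events([det(10, 15), det(12, 17)], [ann(11, 16)])
        assert result.statuses == ["TP", "duplicate"]
        assert result.n_tp == 1 and result.n_fp == 0 and result.n_duplicate == 1

    def test_each_annotation_claimed_at_most_once(self):
        detections = [det(0, 5), det(3, 8), det(6, 11)]
        annotations = [ann(2, 4), ann(7, 9)]
        result = match_events(detections, annotations)
        assert result.statuses.count("TP") == 2
        assert sum(result.matched) == 2

    def test_status_partition_is_exhaustive(self, rng):
        """TP + FP + duplicates account for every detection."""
        for _ in range(20):
            n_d, n_a = rng.integers(0, 30), rng.integers(0, 20)
            starts = np.sort(rng.uniform(0, 500, n_d))
            detections = [det(s, s + 13.0) for s in starts]
            annotations = [ann(s, s + rng.uniform(2, 15)) for s in np.sort(rng.uniform(0, 500, n_a))]
            result = match_events(detections, annotations)
            assert len(result.statuses) == n_d
            assert result.n_tp + result.n_fp + result.n_duplicate == n_d
            assert result.n_tp == sum(result.matched)

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """Greedy ascending-time matching equals an independent enumeration
        over the full overlap matrix on small instances."""
        for trial in range(15):
            n_d, n_a = int(rng.integers(1, 50)), int(rng.integers(1, 30))
            detections = [det(s, s + 5.0) for s in rng.uniform(0, 300, n_d)]
            annotations = [ann(s, s + 4.0) for s in np.sort(rng.uniform(0, 300, n_a))]
            result = match_events(detections, annotations)

            # oracle: explicit overlap matrix + greedy claim in trigger order
            order = sorted(range(n_d), key=lambda i: detections[i].trigger)
            overlap = [
                [
                    detections[i].begin < annotations[j].end
                    and annotations[j].begin < detections[i].end
                    for j in range(n_a)
                ]
                for i in range(n_d)
            ]
            claimed = [False] * n_a
            statuses = []
            for i in order:
                js = [j for j in range(n_a) if overlap[i][j]]
                if not js:
                    statuses.append("FP")
                elif any(not claimed[j] for j in js):
                    j = min(
                        (j for j in js if not claimed[j]),
                        key=lambda j: annotations[j].begin,
                    )
                    claimed[j] = True
                    statuses.append("TP")
                else:
                    statuses.append("duplicate")
            assert result.statuses == statuses


class TestSlotArithmetic:
    def test_possible_detections_floor(self):
        assert possible_detections(3600.0, 13.0) == 276
        assert possible_detections(3600.0, 2.5) == 1440
        assert possible_detections(0.0, 13.0) == 0
        assert possible_detections(-5.0, 13.0) == 0

    def test_one_percent_fpr_conversions(self):
        assert round(false_alarms_per_hour(0.01, 13.0), 1) == 2.8
        assert round(false_alarms_per_hour(0.01, 2.5), 1) == 14.4


class TestTabulate:
    def _scenario(self):
        annotations = [ann(i * 100.0, i * 100.0 + 10.0) for i in range(10)]
        detections = []
        for i in range(6):  # six TPs
            detections.append(det(i * 100.0 + 2, i * 100.0 + 8))
        detections.append(det(2.0 + 0.5, 9.5))  # duplicate of annotation 0
        detections.append(det(50.0, 56.0))  # FP
        detections.append(det(150.0, 156.0))  # FP
        return detections, annotations

    def test_counts_precision_recall(self):
        detections, annotations = self._scenario()
        match = match_events(detections, annotations)
        assert (match.n_tp, match.n_fp, match.n_duplicate) == (6, 2, 1)
        table = tabulate(match, annotations, 3600.0, 2.5)
        assert table.precision == pytest.approx(0.75)
        assert table.recall == pytest.approx(0.6)
        assert table.tp + table.fn == len(annotations)
        assert table.tn + table.fp == table.n_neg
        # N_neg = 1440 slots - ceil(100 s annotated / 2.5 s)
        assert table.n_neg == 1440 - 40
        assert table.fp_per_hour == pytest.approx(2.0)

    def test_no_detections_flags_precision_undefined(self):
        annotations = [ann(0.0, 10.0)]
        match = match_events([], annotations)
        table = tabulate(match, annotations, 3600.0, 2.5)
        assert table.tpr == 0.0 and table.fpr == 0.0
        assert not table.precision_defined

    def test_saturated_recording_is_an_error(self):
        annotations = [ann(0.0, 3600.0)]
        match = match_events([], annotations)
        with pytest.raises(ValueError, match="saturated"):
            tabulate(match, annotations, 3600.0, 13.0)


class TestSweepCurves:
    def test_perfectly_separating_scores_reach_corner(self):
        annotations = [ann(i * 50.0, i * 50.0 + 10.0) for i in range(5)]
        hits = [det(i * 50.0 + 1, i * 50.0 + 9, threshold=10.0) for i in range(5)]
        noisy = hits + [det(i * 50.0 + 20, i * 50.0 + 26, threshold=1.0) for i in range(5)]
        sweep = {1.0: noisy, 10.0: hits}
        points = sweep_curves(sweep, annotations, 3600.0, 13.0)
        corner = [p for p in points if p.tpr == 1.0 and p.fpr == 0.0]
        assert corner, "expected a perfect-separation point"

    def test_single_threshold_point_equals_tabulate(self):
        detections, annotations = TestTabulate()._scenario()
        (point,) = sweep_curves({1.0: detections}, annotations, 3600.0, 2.5)
        table = tabulate(match_events(detections, annotations), annotations, 3600.0, 2.5)
        assert (point.fpr, point.tpr, point.precision, point.recall) == (
            table.fpr,
            table.tpr,
            table.precision,
            table.recall,
        )

    def test_truth_independent_scores_track_the_diagonal(self, rng):
        """Detections placed independently of the annotations give an
        empirical ROC near TPR = FPR."""
        delta = 10.0
        duration = 4000.0
        slots = np.arange(0, duration - delta, delta)
        ann_slots = rng.choice(len(slots), size=80, replace=False)
        annotations = [ann(slots[i], slots[i] + 8.0) for i in sorted(ann_slots)]
        diffs = []
        for frac in (0.1, 0.3, 0.5):
            k = int(frac * len(slots))
            pick = rng.choice(len(slots), size=k, replace=False)
            detections = [det(slots[i] + 0.5, slots[i] + 9.5) for i in sorted(pick)]
            match = match_events(detections, annotations)
            table = tabulate(match, annotations, duration, delta)
            diffs.append(abs(table.tpr - table.fpr))
        # ~4 sd Monte-Carlo band around the diagonal (80 annotations)
        assert max(diffs) < 0.25

    def test_conservation_at_every_threshold(self, rng):
        annotations = [ann(s, s + 8.0) for s in np.sort(rng.uniform(0, 3000, 25))]
        sweep = {}
        for th in (1.0, 2.0, 4.0):
            k = int(30 / th)
            starts = np.sort(rng.uniform(0, 3500, k))
            sweep[th] = [det(s, s + 13.0, threshold=th) for s in starts]
        for th, detections in sweep.items():
            match = match_events(detections, annotations)
            table = tabulate(match, annotations, 3600.0, 13.0)
            assert table.tp + table.fn == len(annotations)
            assert table.tn + table.fp == table.n_neg
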
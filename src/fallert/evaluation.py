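"""Event-level scoring of alert streams against ground truth.

Detection quality is judged per *event*, not per frame: each
ground-truth fall interval counts as one positive event (detected or
missed); each non-fall segment (a sitting spell, an occlusion, walking
between falls, miscellaneous activity) counts as one negative event,
correct unless a false alert lands in it.  The four summary metrics are

    sensitivity = TP / TotalPositives
    specificity = TN / TotalNegatives
    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / TotalEvents

all expressed as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

from fallert.alerting import AlertEvent, AlertType
from fallert.scene_synth import GroundTruthLog


@dataclass
class ConfusionCounts:
    """Event-level confusion totals.

    ``fp_segments`` counts the non-fall segments spoiled by at least one
    false alert, so ``total_negatives = TN + fp_segments`` while
    ``false_positives`` counts every stray alert individually (several
    stray alerts can land in one segment).
    """

    true_positives: int = 0
    false_positives: int = 0
    true_negatives: int = 0
    false_negatives: int = 0
    fp_segments: int = 0

    @property
    def total_positives(self) -> int:
        return self.true_positives + self.false_negatives

    @property
    def total_negatives(self) -> int:
        return self.true_negatives + self.fp_segments

    @property
    def total_events(self) -> int:
        return self.total_positives + self.total_negatives

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.true_positives + other.true_positives,
            self.false_positives + other.false_positives,
            self.true_negatives + other.true_negatives,
            self.false_negatives + other.false_negatives,
            self.fp_segments + other.fp_segments)


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; ``None`` where a denominator was zero."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    zero_denominators: tuple[str, ...] = ()


def score_events(alerts: list[AlertEvent], ground_truth: GroundTruthLog,
                 frame_rate: float, grace_s: float = 2.0) -> ConfusionCounts:
    """Match fall alerts against labelled intervals of one recording.

    A ground-truth fall interval with at least one FALL_ALERT inside it
    (widened by ``grace_s`` on both sides) is a true positive, otherwise
    a false negative.  Every FALL_ALERT outside all widened fall
    intervals is a false positive.  Every non-fall segment free of false
    positives is a true negative.  Order of the alert stream is
    irrelevant.
    """
    ground_truth.validate()
    grace_f = grace_s * frame_rate
    fall_ivs = ground_truth.fall_intervals()
    notfall_ivs = [iv for iv in ground_truth.intervals if iv[2] == "NOT_FALL"]
    fall_frames = [a.frame for a in alerts if a.type is AlertType.FALL_ALERT]

    counts = ConfusionCounts()
    stray: list[float] = []
    for f in fall_frames:
        if not any(s - grace_f <= f < e + grace_f for s, e, _ in fall_ivs):
            stray.append(f)
    counts.false_positives = len(stray)

    for s, e, _ in fall_ivs:
        hit = any(s - grace_f <= f < e + grace_f for f in fall_frames)
        if hit:
            counts.true_positives += 1
        else:
            counts.false_negatives += 1

    for s, e, _ in notfall_ivs:
        contaminated = any(s <= f < e for f in stray)
        if contaminated:
            counts.fp_segments += 1
        else:
            counts.true_negatives += 1
    return counts


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Event-level sensitivity/specificity/precision/accuracy, in percent."""
    zero = []

    def pct(num: int, den: int, name: str) -> float | None:
        if den == 0:
            zero.append(name)
            return None
        return 100.0 * num / den

    sens = pct(counts.true_positives, counts.total_positives, "sensitivity")
    spec = pct(counts.true_negatives, counts.total_negatives, "specificity")
    prec = pct(counts.true_positives,
               counts.true_positives + counts.false_positives, "precision")
    acc = pct(counts.true_positives + counts.true_negatives,
              counts.total_events, "accuracy")
    return MetricsReport(sensitivity=sens, specificity=spec, precision=prec,
                         accuracy=acc, zero_denominators=tuple(zero))
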
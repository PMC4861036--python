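"""Responder / non-responder calls from metric time series.

A PET responder is a metric decrease strictly greater than the policy
threshold; anything else (smaller decrease or any increase) is a
non-responder.  The per-patient rule follows PERCIST: the percent change of
the hottest target lesion at each time point (the lesions may differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .metrics import METRIC_NAMES, LesionMetrics

__all__ = [
    "ThresholdPolicy",
    "ResponsePair",
    "percent_change",
    "classify_change",
    "select_targets",
    "patient_change_percist",
    "evaluate_pair",
    "confusion_cell",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class ThresholdPolicy:
    """Per-metric required percent decrease (positive numbers)."""

    thresholds: dict

    def __post_init__(self):
        for metric, thr in self.thresholds.items():
            if metric not in METRIC_NAMES:
                raise ValueError(f"unknown metric {metric!r}")
            if thr <= 0:
                raise ValueError("thresholds must be positive percent decreases")

    @classmethod
    def percist(cls) -> "ThresholdPolicy":
        """PERCIST preset: 30% for every metric except 45% for TLG."""
        return cls({m: (45.0 if m == "tlg" else 30.0) for m in METRIC_NAMES})

    def threshold(self, metric: str) -> float:
        return float(self.thresholds[metric])


@dataclass
class ResponsePair:
    """One scan-pair evolution: metrics at both time points plus the gold label."""

    pair_id: str
    patient_id: str
    baseline: list = field(default_factory=list)   # list[LesionMetrics]
    followup: list = field(default_factory=list)
    gold_label: str | None = None
    interval_months: float | None = None


def percent_change(m1: float, m2: float) -> float:
    """``100 * (m2 - m1) / m1``; requires a positive baseline value."""
    if m1 <= 0:
        raise ValueError("baseline metric value must be positive")
    return 100.0 * (m2 - m1) / m1


def classify_change(change: float, threshold: float) -> str:
    """Responder iff the decrease strictly exceeds the threshold
    (``change < -threshold``); a decrease exactly at the threshold is a
    non-responder."""
    if threshold <= 0:
        raise ValueError("threshold must be a positive percent decrease")
    return RESPONDER if change < -threshold else NON_RESPONDER


def select_targets(lesions, max_total: int = 5, max_per_organ: int = 2):
    """PERCIST target selection: hottest lesions by baseline SUVmax, at most
    ``max_total`` overall and ``max_per_organ`` per organ; deterministic
    tie-break by lesion_id."""
    lesions = list(lesions)
    if not lesions:
        raise ValueError("at least one lesion required")
    ranked = sorted(lesions, key=lambda m: (-m.suv_max, m.lesion_id))
    chosen, per_organ = [], {}
    for les in ranked:
        if len(chosen) >= max_total:
            break
        if per_organ.get(les.organ, 0) >= max_per_organ:
            continue
        chosen.append(les)
        per_organ[les.organ] = per_organ.get(les.organ, 0) + 1
    return chosen


def patient_change_percist(
    pair: ResponsePair, metric: str, hottest_by: str = "same_metric"
) -> float:
    """Percent change of the most intense lesion at each time point.

    ``hottest_by="same_metric"`` ranks lesions by the metric under evaluation
    at each time point (the lesions may differ between scans);
    ``hottest_by="suv_max"`` always ranks by SUVmax.
    """
    if not pair.baseline or not pair.followup:
        raise ValueError("no measurable lesion at one of the time points")
    key = metric if hottest_by == "same_metric" else "suv_max"

    def hottest(frame):
        best = max(frame, key=lambda m: (m.value(key), m.lesion_id))
        return best.value(metric)

    return percent_change(hottest(pair.baseline), hottest(pair.followup))


def confusion_cell(pet_call: str, gold_label: str) -> str:
    """Cross a PET call with the gold standard: TP / TN / FP / FN."""
    if pet_call == RESPONDER:
        return "TP" if gold_label == RESPONDER else "FP"
    return "FN" if gold_label == RESPONDER else "TN"


def evaluate_pair(
    pair: ResponsePair,
    policy: ThresholdPolicy,
    metric: str,
    new_lesion_progression: bool = False,
) -> str:
    """Confusion cell of one pair under the given policy and metric.

    ``new_lesion_progression=True`` applies the stricter PERCIST reading: any
    follow-up lesion absent at baseline marks the pair a non-responder
    regardless of the hottest-lesion change.  Off by default, matching the
    literal hottest-lesion computation.
    """
    if pair.gold_label is None:
        raise ValueError("gold-standard label missing")
    baseline_ids = {m.lesion_id for m in pair.baseline}
    if new_lesion_progression and any(
        m.lesion_id not in baseline_ids for m in pair.followup
    ):
        return confusion_cell(NON_RESPONDER, pair.gold_label)
    change = patient_change_percist(pair, metric)
    call = classify_change(change, policy.threshold(metric))
    return confusion_cell(call, pair.gold_label)
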
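"""Event-level scoring of detected steps against human annotations.

Matching is greedy and chronological: each detected event is paired with
the earliest still-unmatched annotated step whose interval overlaps the
detection's cycle window, or whose onset lies within a time tolerance of
the detection's flexion-to-extension crossing. True negatives are
annotated non-functional (non-step) activity events containing no
detection.

Scores follow the event-level definitions: accuracy is correctly judged
events over all sampled events, precision tp/(tp+fp), recall tp/(tp+fn);
0/0 ratios are reported as missing (None), never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_core import AnnotationEvent, AnnotationLog
from .step_detection import StepEvent

__all__ = ["MatchResult", "match_events", "score"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tn: int
    matched: list[tuple[StepEvent, AnnotationEvent]] = field(default_factory=list)
    tolerance_s: float = 0.5


def _detection_interval(d: StepEvent) -> tuple[float, float]:
    a = d.swing_start_s if d.swing_start_s is not None else d.peak_time_s
    b = d.stance_end_s if d.stance_end_s is not None else d.zero_cross_s
    return a, b


def match_events(
    detected: list[StepEvent],
    annotations: AnnotationLog,
    tolerance_s: float = 0.5,
) -> MatchResult:
    """Greedy chronological matching of detections to annotated steps.

    A detection matches an unmatched annotated step when their intervals
    overlap or when |zero_cross - onset| <= tolerance. Each annotation is
    consumed at most once, so one detection straddling two annotations
    matches only the first in time.
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be > 0")
    ann = sorted(annotations.events, key=lambda e: e.onset_s)
    steps = [e for e in ann if e.label == "step"]
    non_functional = [e for e in ann if e.label != "step"]
    det = sorted(detected, key=lambda d: d.peak_time_s)

    used = [False] * len(steps)
    matched: list[tuple[StepEvent, AnnotationEvent]] = []
    for d in det:
        a, b = _detection_interval(d)
        for k, e in enumerate(steps):
            if used[k]:
                continue
            overlap = e.onset_s < b and a < e.offset_s
            close = abs(d.zero_cross_s - e.onset_s) <= tolerance_s
            if overlap or close:
                used[k] = True
                matched.append((d, e))
                break

    tp = len(matched)
    fp = len(det) - tp
    fn = len(steps) - tp
    tn = 0
    for e in non_functional:
        inside = any(
            e.onset_s <= d.peak_time_s < e.offset_s
            or e.onset_s <= d.zero_cross_s < e.offset_s
            for d in det
        )
        if not inside:
            tn += 1
    return MatchResult(tp=tp, fp=fp, fn=fn, tn=tn, matched=matched, tolerance_s=tolerance_s)


def score(
    m: MatchResult, total_sampled: Optional[int] = None
) -> dict[str, Optional[float]]:
    """Accuracy, precision and recall from a match result.

    ``total_sampled`` defaults to tp + fp + fn + tn. Undefined ratios (0/0)
    come back as None.
    """
    for name in ("tp", "fp", "fn", "tn"):
        if getattr(m, name) < 0:
            raise ValueError(f"negative count {name}")
    if total_sampled is None:
        total_sampled = m.tp + m.fp + m.fn + m.tn
    if total_sampled < m.tp + m.fn:
        raise ValueError("total_sampled smaller than tp + fn")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "accuracy": ratio(m.tp + m.tn, total_sampled),
        "precision": ratio(m.tp, m.tp + m.fp),
        "recall": ratio(m.tp, m.tp + m.fn),
    }
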
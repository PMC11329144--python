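"""Weak labeling of recordings from PTA intervention timelines.

A recording is labeled *abnormal* if it falls shortly before a percutaneous
transluminal angioplasty (the access was demonstrably stenosed, since it was
intervened on), *normal* if it falls in a window starting a few days after the
PTA (the access was freshly reopened), and *unlabeled* otherwise.  Labels are
derived only from timestamps and PTA dates — never from simulator ground
truth.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass

from .synth import PTAEvent, RecordingRecord

__all__ = ["LabelPolicy", "LabeledRecording", "assign_labels", "label_summary"]

logger = logging.getLogger(__name__)

LABELS = ("normal", "abnormal", "unlabeled")


@dataclass(frozen=True)
class LabelPolicy:
    """Windows (in days) around a PTA event that define the two label classes.

    * abnormal: ``0 <= event_date - timestamp <= pre_window_days``
    * normal:   ``post_start_days <= timestamp - event_date
      <= post_start_days + post_window_days``

    Defaults: one weekly visit before the PTA is abnormal; the normal window
    opens four days post-PTA (by which time the access has settled) and spans
    three further weekly visits.
    """

    pre_window_days: int = 7
    post_start_days: int = 4
    post_window_days: int = 21

    def __post_init__(self) -> None:
        if min(self.pre_window_days, self.post_start_days, self.post_window_days) < 0:
            raise ValueError("all label-policy windows must be >= 0")


@dataclass
class LabeledRecording:
    record: RecordingRecord
    label: str


def _days(a: dt.date, b: dt.date) -> int:
    return (a - b).days


def assign_labels(
    records: list[RecordingRecord],
    events: list[PTAEvent],
    policy: LabelPolicy = LabelPolicy(),
) -> list[LabeledRecording]:
    """Assign exactly one of normal / abnormal / unlabeled to every recording.

    If a recording matches both an abnormal and a normal window (two PTAs in
    close succession), abnormal wins and a warning is logged — conservative
    for a screening tool.  Raises ``ValueError`` for an event whose patient
    has no recordings.
    """
    known = {r.patient_id for r in records}
    for e in events:
        if e.patient_id not in known:
            raise ValueError(f"PTA event for unknown patient {e.patient_id!r}")

    by_patient: dict[str, list[PTAEvent]] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)

    out: list[LabeledRecording] = []
    for r in records:
        abnormal = False
        normal = False
        for e in by_patient.get(r.patient_id, ()):
            before = _days(e.event_date, r.timestamp)
            if 0 <= before <= policy.pre_window_days:
                abnormal = True
            after = _days(r.timestamp, e.event_date)
            if policy.post_start_days <= after <= policy.post_start_days + policy.post_window_days:
                normal = True
        if abnormal and normal:
            logger.warning(
                "recording %s/%s matches both label windows; resolving to abnormal",
                r.patient_id,
                r.timestamp,
            )
        label = "abnormal" if abnormal else ("normal" if normal else "unlabeled")
        out.append(LabeledRecording(r, label))
    return out


def label_summary(labeled: list[LabeledRecording]) -> dict[str, int]:
    """Counts per label; keys always present, values sum to the input length."""
    counts = Counter(lr.label for lr in labeled)
    return {lab: counts.get(lab, 0) for lab in LABELS}
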
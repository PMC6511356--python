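"""Consensus reference-standard ("golden standard") construction.

Each recording enters with one medical description (recording-level labels)
and two independent verifications of that description.  Routing is
deterministic:

* both verifications positive -> the description is accepted outright;
* any other verdict pair -> an acoustician reviews the case: if the
  description is judged *clear*, it is accepted; if *disputable*, a
  consilium (two experienced pediatricians and an acoustician) issues the
  final labels, which are terminal and not further verified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phenomena import CLASSES, RecordingLabels

POSITIVE = "positive"
NEGATIVE = "negative"
CLEAR = "clear"
DISPUTABLE = "disputable"

STATUS_DOUBLE_POSITIVE = "accepted_double_positive"
STATUS_ACOUSTICIAN = "accepted_acoustician"
STATUS_CONSILIUM = "accepted_consilium"
STATUSES = (STATUS_DOUBLE_POSITIVE, STATUS_ACOUSTICIAN, STATUS_CONSILIUM)


class IncompleteRecordError(ValueError):
    """A required downstream field is missing for the record's path."""


class InconsistentRecordError(ValueError):
    """A downstream field is present on a path that does not use it."""


@dataclass
class AdjudicationRecord:
    """One recording's journey through the reference-standard procedure."""

    recording_id: str
    description: RecordingLabels
    verification_1: str
    verification_2: str
    acoustician_verdict: Optional[str] = None
    consilium_labels: Optional[RecordingLabels] = None
    final_status: Optional[str] = None
    final_labels: Optional[RecordingLabels] = None


def adjudicate(record: AdjudicationRecord) -> AdjudicationRecord:
    """Route one record to exactly one terminal status (pure function).

    Double-positive verification accepts the description automatically.
    Every other verdict pair (split or double-negative) goes to the
    acoustician; a *clear* verdict accepts the description, *disputable*
    makes the consilium labels final.
    """
    for v, name in ((record.verification_1, "verification_1"),
                    (record.verification_2, "verification_2")):
        if v not in (POSITIVE, NEGATIVE):
            raise ValueError(f"{record.recording_id}: {name} must be positive/negative, got {v!r}")

    double_positive = record.verification_1 == POSITIVE and record.verification_2 == POSITIVE
    if double_positive:
        if record.consilium_labels is not None:
            raise InconsistentRecordError(
                f"{record.recording_id}: consilium labels on a double-positive record"
            )
        if record.acoustician_verdict is not None:
            raise InconsistentRecordError(
                f"{record.recording_id}: acoustician verdict on a double-positive record"
            )
        return replace(record, final_status=STATUS_DOUBLE_POSITIVE,
                       final_labels=record.description)

    if record.acoustician_verdict is None:
        raise IncompleteRecordError(
            f"{record.recording_id}: non-double-positive verification requires an "
            "acoustician verdict"
        )
    if record.acoustician_verdict == CLEAR:
        if record.consilium_labels is not None:
            raise InconsistentRecordError(
                f"{record.recording_id}: consilium labels on an acoustician-clear record"
            )
        return replace(record, final_status=STATUS_ACOUSTICIAN,
                       final_labels=record.description)
    if record.acoustician_verdict == DISPUTABLE:
        if record.consilium_labels is None:
            raise IncompleteRecordError(
                f"{record.recording_id}: disputable record requires consilium labels"
            )
        return replace(record, final_status=STATUS_CONSILIUM,
                       final_labels=record.consilium_labels)
    raise ValueError(
        f"{record.recording_id}: acoustician verdict must be clear/disputable, "
        f"got {record.acoustician_verdict!r}"
    )


def build_golden_standard(
    records: Iterable[AdjudicationRecord],
) -> tuple[pd.DataFrame, dict]:
    """Adjudicate all records into a reference table plus a composition
    summary (counts per terminal status and per phenomenon)."""
    done = [adjudicate(r) for r in records]
    ids = [r.recording_id for r in done]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate recording ids: {dupes}")
    table = pd.DataFrame(
        [
            {
                "recording_id": r.recording_id,
                **{c: bool(r.final_labels[c]) for c in CLASSES},
                "status": r.final_status,
            }
            for r in done
        ]
    ).set_index("recording_id")
    summary = {
        "total": len(done),
        "by_status": {s: int((table["status"] == s).sum()) for s in STATUSES},
        "by_phenomenon": {c: int(table[c].sum()) for c in CLASSES},
    }
    return table, summary


# -- CSV interchange ---------------------------------------------------

_CSV_COLUMNS = (
    ["recording_id"]
    + [f"desc_{c}" for c in CLASSES]
    + ["v1", "v2", "acoustician"]
    + [f"consilium_{c}" for c in CLASSES]
    + ["status"]
)


def records_to_csv(records: Sequence[AdjudicationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"recording_id": r.recording_id,
               **{f"desc_{c}": int(r.description[c]) for c in CLASSES},
               "v1": r.verification_1, "v2": r.verification_2,
               "acoustician": r.acoustician_verdict or "",
               "status": r.final_status or ""}
        for c in CLASSES:
            row[f"consilium_{c}"] = (
                "" if r.consilium_labels is None else int(r.consilium_labels[c])
            )
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def records_from_csv(path: str | Path) -> list[AdjudicationRecord]:
    df = pd.read_csv(path, dtype={"recording_id": str}, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        cons_vals = [row[f"consilium_{c}"] for c in CLASSES]
        has_cons = any(str(v) != "" for v in cons_vals)
        out.append(
            AdjudicationRecord(
                recording_id=row["recording_id"],
                description=RecordingLabels(**{c: bool(int(row[f"desc_{c}"])) for c in CLASSES}),
                verification_1=row["v1"],
                verification_2=row["v2"],
                acoustician_verdict=row["acoustician"] or None,
                consilium_labels=(
                    RecordingLabels(**{c: bool(int(row[f"consilium_{c}"])) for c in CLASSES})
                    if has_cons else None
                ),
                final_status=row["status"] or None,
            )
        )
    return out
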
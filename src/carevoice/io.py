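"""Readers, writers and eligibility rules for raw feedback streams.

Feedback travels as JSONL (one object per line) or CSV with the columns
``item_id, org_id, source, date, stars, text, is_repost, author_is_org``;
dates are ISO-8601 calendar dates.  Organisation registries and inspection
tables are CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    FeedbackItem,
    Inspection,
    Organisation,
    Registry,
    Source,
    ValidationError,
)

logger = logging.getLogger("carevoice")

FEEDBACK_FIELDS = ["item_id", "org_id", "source", "date", "stars", "text", "is_repost", "author_is_org"]

_TRUTHY = {"true", "1", "yes"}


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None:
        return False
    return str(value).strip().lower() in _TRUTHY


def _coerce_stars(value):
    """Return a valid star integer, None for absent, or raise ValidationError."""
    if value is None or value == "":
        return None
    if isinstance(value, float):
        if math.isnan(value):
            return None
        if value != int(value):
            raise ValidationError(f"non-integer stars {value!r}")
        value = int(value)
    if isinstance(value, bool):
        raise ValidationError(f"non-integer stars {value!r}")
    if isinstance(value, str):
        try:
            value = int(value)
        except ValueError:
            raise ValidationError(f"non-integer stars {value!r}") from None
    if not isinstance(value, int):
        raise ValidationError(f"non-integer stars {value!r}")
    if not 1 <= value <= 5:
        raise ValidationError(f"stars {value} outside [1, 5]")
    return value


def _record_to_item(record: dict, lineno: int) -> FeedbackItem:
    org_id = record.get("org_id")
    date = record.get("date")
    if org_id in (None, "") or (isinstance(org_id, float) and math.isnan(org_id)):
        raise ValidationError(f"line {lineno}: missing org_id")
    if date in (None, "") or (isinstance(date, float) and math.isnan(date)):
        raise ValidationError(f"line {lineno}: missing date")
    text = record.get("text")
    if isinstance(text, float) and math.isnan(text):
        text = None
    return FeedbackItem(
        item_id=str(record.get("item_id", f"line{lineno}")),
        org_id=str(org_id),
        source=Source(record["source"]),
        date=date,
        stars=_coerce_stars(record.get("stars")),
        text=text if text is None else str(text),
        is_repost=_coerce_bool(record.get("is_repost")),
        author_is_org=_coerce_bool(record.get("author_is_org")),
    )


def read_feedback(path, format: str | None = None) -> list[FeedbackItem]:
    """Read feedback items from a JSONL or CSV file.

    Records with malformed star values (non-integer or outside 1-5) are
    rejected and counted in the run log; records missing ``org_id`` or
    ``date`` raise :class:`ValidationError` naming the line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValidationError(f"unknown feedback format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    items: list[FeedbackItem] = []
    n_rejected = 0
    if format == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                record = json.loads(line)
                try:
                    items.append(_record_to_item(record, lineno))
                except ValidationError as exc:
                    if "missing" in str(exc):
                        raise
                    n_rejected += 1
                    logger.warning("rejected feedback record at line %d: %s", lineno, exc)
    else:
        with open(path, newline="") as fh:
            for lineno, record in enumerate(csv.DictReader(fh), start=2):
                try:
                    items.append(_record_to_item(record, lineno))
                except ValidationError as exc:
                    if "missing" in str(exc):
                        raise
                    n_rejected += 1
                    logger.warning("rejected feedback record at line %d: %s", lineno, exc)
    if n_rejected:
        logger.info("read_feedback: rejected %d malformed record(s) from %s", n_rejected, path)
    return items


def write_feedback(path, items: Iterable[FeedbackItem], format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {
            "item_id": it.item_id,
            "org_id": it.org_id,
            "source": it.source.value,
            "date": it.date.isoformat(),
            "stars": it.stars,
            "text": it.text,
            "is_repost": it.is_repost,
            "author_is_org": it.author_is_org,
        }
        for it in items
    ]
    if format == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=FEEDBACK_FIELDS)
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValidationError(f"unknown feedback format {format!r}")


def filter_eligible(items: Sequence[FeedbackItem]) -> list[FeedbackItem]:
    """Drop reposts and organisation-authored items, preserving order.

    Only original feedback should contribute to a collective judgement score:
    reposts would let popular posts count repeatedly, and posts authored by
    the organisation itself are not patient feedback at all.
    """
    kept = [it for it in items if not (it.is_repost or it.author_is_org)]
    removed = len(items) - len(kept)
    if removed:
        logger.info("filter_eligible: removed %d repost/organisation-authored item(s)", removed)
    return kept


def deduplicate(items: Sequence[FeedbackItem]) -> list[FeedbackItem]:
    """Keep the first occurrence of each (org, source, date, text, stars) tuple."""
    seen: set = set()
    kept: list[FeedbackItem] = []
    for it in items:
        key = it.dedup_key()
        if key not in seen:
            seen.add(key)
            kept.append(it)
    removed = len(items) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate item(s)", removed)
    return kept


# ---------------------------------------------------------------------------
# Registry and inspection tables

def read_organisations(path) -> Registry:
    """Read an organisation registry CSV (org_id, kind, name, parent_trust_id)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    orgs = [
        Organisation(
            org_id=row["org_id"],
            kind=row["kind"],
            name=row.get("name", row["org_id"]),
            parent_trust_id=row["parent_trust_id"] or None,
        )
        for row in df.to_dict("records")
    ]
    return Registry(orgs)


def write_organisations(path, registry: Registry) -> None:
    pd.DataFrame(
        [
            {
                "org_id": o.org_id,
                "kind": o.kind.value,
                "name": o.name,
                "parent_trust_id": o.parent_trust_id or "",
            }
            for o in registry
        ]
    ).to_csv(path, index=False)


def read_inspections(path) -> list[Inspection]:
    """Read an inspection table CSV (org_id, start_date, rating; rating may be blank)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Inspection(org_id=row["org_id"], start_date=row["start_date"], rating=row["rating"] or None)
        for row in df.to_dict("records")
    ]


def write_inspections(path, inspections: Iterable[Inspection]) -> None:
    pd.DataFrame(
        [
            {"org_id": i.org_id, "start_date": i.start_date.isoformat(), "rating": i.rating or ""}
            for i in inspections
        ]
    ).to_csv(path, index=False)
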
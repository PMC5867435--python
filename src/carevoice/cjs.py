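"""The time-windowed collective judgement score (CJS).

The CJS for an organisation on a date is the unweighted mean of the 1-5 star
ratings of all its feedback items falling in a trailing calendar-day window
(default 90 days, inclusive of the evaluation date: [d-89, d]).  The score is
only defined when at least ``min_items`` items (default 10) fall in the
window — a volume floor that keeps the score from being whipped around by a
handful of comments.

Trusts pool their own feedback with all child hospitals' feedback by default,
since most social-media presence sits at one level or the other.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import (
    FeedbackItem,
    Inspection,
    Organisation,
    OrgKind,
    Registry,
    ValidationError,
)

logger = logging.getLogger("carevoice")


@dataclass
class CJSConfig:
    window_days: int = 90
    min_items: int = 10
    trust_pooling: str = "pool_hospitals_and_trust"  # or "trust_accounts_only"

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        if self.min_items < 1:
            raise ValidationError("min_items must be >= 1")
        if self.trust_pooling not in ("pool_hospitals_and_trust", "trust_accounts_only"):
            raise ValidationError(f"unknown trust_pooling {self.trust_pooling!r}")


@dataclass
class CJSPoint:
    org_id: str
    date: _dt.date
    score: Optional[float]  # None when n_items < min_items
    n_items: int


def _require_scored(items: Sequence[FeedbackItem]) -> None:
    for it in items:
        if it.stars is None:
            raise ValidationError(
                f"unscored item {it.item_id} reached the CJS engine; "
                "microblog items must be sentiment-scored first"
            )


def attribute_items(
    items: Sequence[FeedbackItem],
    org: Organisation,
    registry: Registry,
    config: CJSConfig,
) -> list[FeedbackItem]:
    """Select the items attributed to an organisation.

    Hospitals get their own items.  Trusts get their own items plus, under
    the default pooling, every child hospital's items.
    """
    if org.org_id not in registry:
        raise ValidationError(f"unknown organisation {org.org_id!r}")
    ids = {org.org_id}
    if org.kind is OrgKind.trust and config.trust_pooling == "pool_hospitals_and_trust":
        ids.update(h.org_id for h in registry.children_of(org.org_id))
    return [it for it in items if it.org_id in ids]


def cjs_at(
    items: Sequence[FeedbackItem],
    org: Organisation,
    date: _dt.date,
    config: CJSConfig = CJSConfig(),
) -> CJSPoint:
    """Collective judgement score for one organisation on one date.

    ``items`` must already be attributed to the organisation (see
    :func:`attribute_items`) and carry stars.
    """
    _require_scored(items)
    lo = date - _dt.timedelta(days=config.window_days - 1)
    stars = [it.stars for it in items if lo <= it.date <= date]
    n = len(stars)
    score = float(np.mean(stars)) if n >= config.min_items else None
    return CJSPoint(org_id=org.org_id, date=date, score=score, n_items=n)


def cjs_series(
    items: Sequence[FeedbackItem],
    org: Organisation,
    dates: Sequence[_dt.date],
    config: CJSConfig = CJSConfig(),
) -> list[CJSPoint]:
    """CJS at each of an ascending sequence of dates, by sliding window.

    Value-identical to calling :func:`cjs_at` per date, but computed with
    prefix sums over the sorted item dates.
    """
    dates = list(dates)
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValidationError("dates must be sorted ascending")
    _require_scored(items)
    if not dates:
        return []
    ordinals = np.array([it.date.toordinal() for it in items], dtype=np.int64)
    stars = np.array([it.stars for it in items], dtype=float)
    order = np.argsort(ordinals, kind="stable")
    ordinals = ordinals[order]
    csum = np.concatenate([[0.0], np.cumsum(stars[order])])
    d_ord = np.array([d.toordinal() for d in dates], dtype=np.int64)
    hi = np.searchsorted(ordinals, d_ord, side="right")
    lo = np.searchsorted(ordinals, d_ord - (config.window_days - 1), side="left")
    counts = hi - lo
    sums = csum[hi] - csum[lo]
    out = []
    for d, n, s in zip(dates, counts, sums):
        n = int(n)
        out.append(CJSPoint(org.org_id, d, float(s / n) if n >= config.min_items else None, n))
    return out


def loess_smooth(series: Sequence[CJSPoint], span: float = 0.75) -> np.ndarray:
    """LOESS-smooth a CJS series (tricube-weighted local linear regression).

    Absent scores are skipped; the output has one value per present score,
    in date order.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must lie in (0, 1]")
    present = [(p.date.toordinal(), p.score) for p in series if p.score is not None]
    if len(present) < 3:
        raise ValidationError("loess_smooth requires at least 3 present scores")
    present.sort()
    x = np.array([d for d, _ in present], dtype=float)
    y = np.array([s for _, s in present], dtype=float)
    smoothed = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(smoothed, dtype=float)


@dataclass
class PairedData:
    """CJS-at-inspection-start rows paired with the inspection rating."""

    rows: pd.DataFrame  # columns: org_id, kind, rating, cjs, n_items
    n_unrated_dropped: int
    n_low_volume_dropped: int


def pair_with_inspections(
    items: Sequence[FeedbackItem],
    inspections: Sequence[Inspection],
    registry: Registry,
    config: CJSConfig = CJSConfig(),
) -> PairedData:
    """Pair each rated inspection with the CJS on its start date.

    Unrated inspections are dropped (counted); so are inspections whose
    window holds fewer than ``min_items`` items — organisations without
    enough feedback cannot be scored.
    """
    _require_scored(items)
    by_org: dict[str, list[FeedbackItem]] = {}
    for it in items:
        by_org.setdefault(it.org_id, []).append(it)

    def org_items(org: Organisation) -> list[FeedbackItem]:
        pools = [by_org.get(org.org_id, [])]
        if org.kind is OrgKind.trust and config.trust_pooling == "pool_hospitals_and_trust":
            pools.extend(by_org.get(h.org_id, []) for h in registry.children_of(org.org_id))
        return [it for pool in pools for it in pool]

    rows = []
    n_unrated = 0
    n_low = 0
    for insp in inspections:
        if insp.rating is None:
            n_unrated += 1
            continue
        org = registry[insp.org_id]
        point = cjs_at(org_items(org), org, insp.start_date, config)
        if point.score is None:
            n_low += 1
            continue
        rows.append(
            {
                "org_id": org.org_id,
                "kind": org.kind.value,
                "rating": insp.rating,
                "cjs": point.score,
                "n_items": point.n_items,
            }
        )
    if n_unrated:
        logger.info("pair_with_inspections: dropped %d unrated inspection(s)", n_unrated)
    if n_low:
        logger.info(
            "pair_with_inspections: dropped %d inspection(s) with < %d items in window",
            n_low, config.min_items,
        )
    df = pd.DataFrame(rows, columns=["org_id", "kind", "rating", "cjs", "n_items"])
    return PairedData(rows=df, n_unrated_dropped=n_unrated, n_low_volume_dropped=n_low)
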
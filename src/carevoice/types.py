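"""Core domain types for patient-feedback surveillance.

One :class:`FeedbackItem` is a single dated, source-tagged piece of patient
feedback (a review on a rating site, a social-media review, or a microblog
post).  Organisations come in two kinds — hospitals and the trusts that
administratively group them — and each may receive dated inspections with an
ordinal rating.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Source(str, Enum):
    """Where a piece of feedback came from.

    ``rating_site`` and ``social_review`` items always carry a 1-5 star
    rating; ``microblog`` items arrive as free text and are scored later.
    """

    rating_site = "rating_site"
    social_review = "social_review"
    microblog = "microblog"


class OrgKind(str, Enum):
    hospital = "hospital"
    trust = "trust"


#: Ordinal inspection ratings, worst first.  Position in this list is the
#: category index used throughout the ordinal model.
RATING_LEVELS = ("Inadequate", "Requires improvement", "Good", "Outstanding")


class ValidationError(ValueError):
    """Raised when an input record or argument violates a documented contract."""


def rating_index(rating: str) -> int:
    """Return the 0-based ordinal index of a rating (Inadequate == 0)."""
    try:
        return RATING_LEVELS.index(rating)
    except ValueError:
        raise ValidationError(f"unknown rating {rating!r}; expected one of {RATING_LEVELS}") from None


@dataclass
class FeedbackItem:
    item_id: str
    org_id: str
    source: Source
    date: _dt.date
    stars: Optional[int] = None
    text: Optional[str] = None
    is_repost: bool = False
    author_is_org: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.source, str) and not isinstance(self.source, Source):
            self.source = Source(self.source)
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)
        if self.stars is not None:
            if not isinstance(self.stars, (int,)) or isinstance(self.stars, bool):
                raise ValidationError(f"stars must be an integer, got {self.stars!r}")
            if not 1 <= self.stars <= 5:
                raise ValidationError(f"stars must be in [1, 5], got {self.stars}")

    def dedup_key(self) -> tuple:
        """Identity used for duplicate removal.

        The key deliberately includes the date and source: the same wording on
        different days, or syndicated to a different source, is treated as
        distinct feedback (under-merging is safer than over-merging for a
        volume-sensitive score).
        """
        return (self.org_id, self.source.value, self.date, self.text, self.stars)


@dataclass
class Organisation:
    org_id: str
    kind: OrgKind
    name: str
    parent_trust_id: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.kind, str) and not isinstance(self.kind, OrgKind):
            self.kind = OrgKind(self.kind)
        if self.kind is OrgKind.trust and self.parent_trust_id is not None:
            raise ValidationError(f"trust {self.org_id} must not have a parent trust")


@dataclass
class Inspection:
    org_id: str
    start_date: _dt.date
    rating: Optional[str] = None  # one of RATING_LEVELS, or None when unrated

    def __post_init__(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = _dt.date.fromisoformat(self.start_date)
        if self.rating is not None:
            rating_index(self.rating)  # validates


@dataclass
class Registry:
    """Organisation registry with parent/child resolution."""

    organisations: list[Organisation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {o.org_id: o for o in self.organisations}
        if len(self._by_id) != len(self.organisations):
            raise ValidationError("duplicate org_id in registry")
        for org in self.organisations:
            if org.kind is OrgKind.hospital:
                parent = self._by_id.get(org.parent_trust_id)
                if parent is None or parent.kind is not OrgKind.trust:
                    raise ValidationError(
                        f"hospital {org.org_id} has unresolvable parent trust {org.parent_trust_id!r}"
                    )

    def __contains__(self, org_id: str) -> bool:
        return org_id in self._by_id

    def __getitem__(self, org_id: str) -> Organisation:
        try:
            return self._by_id[org_id]
        except KeyError:
            raise ValidationError(f"unknown organisation {org_id!r}") from None

    def __iter__(self):
        return iter(self.organisations)

    def __len__(self) -> int:
        return len(self.organisations)

    def hospitals(self) -> list[Organisation]:
        return [o for o in self.organisations if o.kind is OrgKind.hospital]

    def trusts(self) -> list[Organisation]:
        return [o for o in self.organisations if o.kind is OrgKind.trust]

    def children_of(self, trust_id: str) -> list[Organisation]:
        return [o for o in self.organisations if o.parent_trust_id == trust_id]
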
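"""Timestamp handling.

FHIR instants carry an explicit UTC offset; real-world exports frequently do
not.  An offset-free timestamp is interpreted in a configurable default zone
(UTC unless told otherwise) and *flagged*, so downstream minute arithmetic
(door-to-needle times and the like) can surface rather than silently absorb
the ambiguity.  All comparisons happen on timezone-aware datetimes, so two
renderings of the same instant compare equal regardless of offset notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from functools import lru_cache

from .errors import FieldValidationError

#: Zone applied to offset-free timestamps. Module-level because it is a
#: property of the export being read, not of any single call site.
_DEFAULT_ZONE = timezone.utc


def set_default_zone(tz: timezone) -> None:
    """Set the zone assumed for timestamps that carry no UTC offset."""
    global _DEFAULT_ZONE
    _DEFAULT_ZONE = tz


def get_default_zone() -> timezone:
    return _DEFAULT_ZONE


@dataclass(frozen=True)
class Instant:
    """A point in time plus a flag recording whether the source string
    carried an explicit UTC offset."""

    at: datetime  # always timezone-aware
    offset_free: bool = False

    def __post_init__(self):
        if self.at.tzinfo is None:  # pragma: no cover - guarded by parsers
            raise ValueError("Instant requires an aware datetime")

    # Instants compare and hash by the moment they denote; the offset_free
    # flag is provenance, not identity.
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Instant):
            return self.at == other.at
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.at)

    def __lt__(self, other: "Instant") -> bool:
        return self.at < other.at

    def __le__(self, other: "Instant") -> bool:
        return self.at <= other.at

    def __gt__(self, other: "Instant") -> bool:
        return self.at > other.at

    def __ge__(self, other: "Instant") -> bool:
        return self.at >= other.at

    def __sub__(self, other: "Instant") -> timedelta:
        return self.at - other.at

    def __add__(self, delta: timedelta) -> "Instant":
        return Instant(self.at + delta, self.offset_free)

    def isoformat(self) -> str:
        return self.at.isoformat()


def parse_instant(value: str, path: str = "") -> Instant:
    """Parse a FHIR date / dateTime / instant string.

    Accepts ``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD`` and full dateTimes with or
    without an offset (``Z`` included).  Partial dates resolve to the start
    of their period.  Successful parses are memoized (corpora repeat
    timestamps heavily); the cache keys on the default zone too, since it
    decides offset-free interpretation.
    """
    if not isinstance(value, str) or not value:
        raise FieldValidationError(path or "timestamp", f"not a timestamp string: {value!r}")
    try:
        return _parse_instant_cached(value, _DEFAULT_ZONE)
    except FieldValidationError:
        raise FieldValidationError(path or "timestamp", f"malformed timestamp {value!r}") from None


@lru_cache(maxsize=1 << 16)
def _parse_instant_cached(value: str, default_zone: timezone) -> Instant:
    text = value.strip()
    try:
        if len(text) == 4 and text.isdigit():  # YYYY
            dt = datetime(int(text), 1, 1)
        elif len(text) == 7 and text[4] == "-":  # YYYY-MM
            dt = datetime(int(text[:4]), int(text[5:]), 1)
        else:
            dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError as exc:
        raise FieldValidationError("timestamp", f"malformed timestamp {value!r}: {exc}") from None
    if dt.tzinfo is None:
        return Instant(dt.replace(tzinfo=default_zone), offset_free=True)
    return Instant(dt, offset_free=False)


def parse_date(value: str, path: str = "") -> date:
    """Parse a plain FHIR date (birthDate)."""
    try:
        return date.fromisoformat(value)
    except (TypeError, ValueError):
        raise FieldValidationError(path or "date", f"malformed date {value!r}") from None


def whole_minutes(start: Instant, end: Instant) -> int:
    """Minutes from ``start`` to ``end``, floored toward minus infinity.

    59m59s elapses as 59 whole minutes; negative intervals stay negative.
    """
    seconds = (end.at - start.at).total_seconds()
    return int(seconds // 60)
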
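"""Event-log data model and CSV serialization.

One :class:`ChatRecord` describes the full lifecycle of a single chat
request on a text-based counseling platform: arrival, the terms-of-service
(TOS) consent decision, queueing, and either service (pickup -> end) or
abandonment (renege).  The CSV dialect is a plain header row with ISO-8601
timestamps and empty cells for absent fields, so logs round-trip exactly.

Timestamps are stored at one-second resolution; all queueing arithmetic
downstream happens in fractional minutes (the 60-second zero-wait window
needs sub-minute resolution).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

__all__ = [
    "ChatRecord",
    "LogParseError",
    "RecordInvariantError",
    "CSV_HEADER",
    "CHANNELS",
    "USER_TYPES",
    "RISK_LEVELS",
    "DEFAULT_EPOCH",
    "read_log",
    "write_log",
    "minutes_between",
]

CHANNELS = ("web", "whatsapp", "messenger", "wechat", "sms")
USER_TYPES = ("nonrepeat", "repeat")
RISK_LEVELS = ("low", "medium", "high_crisis")

CSV_HEADER = [
    "user_id",
    "channel",
    "arrival_ts",
    "tos_accepted",
    "user_type",
    "pickup_ts",
    "end_ts",
    "renege_ts",
    "risk_level",
    "counselor_id",
]

#: Default origin used when converting simulator minutes to wall-clock stamps.
DEFAULT_EPOCH = datetime(2020, 11, 1, 0, 0, 0)


class LogParseError(ValueError):
    """Malformed CSV cell; carries the offending row and column."""

    def __init__(self, message: str, row: int, column: str):
        super().__init__(f"row {row}, column {column!r}: {message}")
        self.row = row
        self.column = column


class RecordInvariantError(ValueError):
    """A record violates a lifecycle invariant (e.g. pickup before arrival)."""


def minutes_between(later: datetime, earlier: datetime) -> float:
    """Signed difference ``later - earlier`` in fractional minutes."""
    return (later - earlier).total_seconds() / 60.0


@dataclass
class ChatRecord:
    user_id: str
    channel: str
    arrival_ts: datetime
    tos_accepted: bool
    user_type: str
    pickup_ts: Optional[datetime] = None
    end_ts: Optional[datetime] = None
    renege_ts: Optional[datetime] = None
    risk_level: Optional[str] = None
    counselor_id: Optional[str] = None

    def validate(self) -> "ChatRecord":
        """Check lifecycle invariants, raising :class:`RecordInvariantError`.

        A renege followed by a *later* pickup is legal: that is a "zombie"
        case a counselor later opened only to file the post-chat survey.
        """
        if self.channel not in CHANNELS:
            raise RecordInvariantError(f"unknown channel {self.channel!r}")
        if self.user_type not in USER_TYPES:
            raise RecordInvariantError(f"unknown user_type {self.user_type!r}")
        if self.risk_level is not None and self.risk_level not in RISK_LEVELS:
            raise RecordInvariantError(f"unknown risk_level {self.risk_level!r}")
        if self.pickup_ts is not None and self.pickup_ts < self.arrival_ts:
            raise RecordInvariantError(
                f"pickup_ts {self.pickup_ts} precedes arrival_ts {self.arrival_ts}"
            )
        if (
            self.pickup_ts is not None
            and self.end_ts is not None
            and self.end_ts < self.pickup_ts
        ):
            raise RecordInvariantError("end_ts precedes pickup_ts")
        if self.renege_ts is not None and self.pickup_ts is not None:
            if self.pickup_ts <= self.renege_ts:
                raise RecordInvariantError(
                    "pickup_ts must follow renege_ts (zombie pickup) when both present"
                )
        if not self.tos_accepted:
            if any(x is not None for x in (self.pickup_ts, self.renege_ts, self.risk_level)):
                raise RecordInvariantError(
                    "TOS-rejecting record must have no pickup/renege/risk fields"
                )
        return self

    # -- derived quantities (fractional minutes) -------------------------

    @property
    def wait_minutes(self) -> Optional[float]:
        """Queue wait until pickup, or None if never picked up."""
        if self.pickup_ts is None:
            return None
        return minutes_between(self.pickup_ts, self.arrival_ts)

    @property
    def service_minutes(self) -> Optional[float]:
        """Chat duration (end - pickup), or None."""
        if self.pickup_ts is None or self.end_ts is None:
            return None
        return minutes_between(self.end_ts, self.pickup_ts)

    @property
    def renege_wait_minutes(self) -> Optional[float]:
        if self.renege_ts is None:
            return None
        return minutes_between(self.renege_ts, self.arrival_ts)

    @property
    def is_served(self) -> bool:
        """Picked up before (or without) any renege: a real counseling chat."""
        return self.pickup_ts is not None and self.renege_ts is None


_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


def _format_ts(ts: Optional[datetime]) -> str:
    if ts is None:
        return ""
    # 1-second storage resolution
    if ts.microsecond:
        ts = (ts + timedelta(microseconds=500_000)).replace(microsecond=0)
    return ts.strftime(_TS_FORMAT)


def _parse_ts(cell: str, row: int, column: str) -> Optional[datetime]:
    if cell == "":
        return None
    try:
        return datetime.fromisoformat(cell)
    except ValueError as exc:
        raise LogParseError(str(exc), row, column) from None


def _parse_enum(cell: str, allowed, row: int, column: str, optional: bool):
    if cell == "":
        if optional:
            return None
        raise LogParseError("missing required value", row, column)
    if cell not in allowed:
        raise LogParseError(f"unknown value {cell!r}", row, column)
    return cell


def write_log(records: Iterable[ChatRecord], path) -> None:
    """Write records as the documented CSV dialect (header, ISO-8601, empty=absent)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.user_id,
                    rec.channel,
                    _format_ts(rec.arrival_ts),
                    "true" if rec.tos_accepted else "false",
                    rec.user_type,
                    _format_ts(rec.pickup_ts),
                    _format_ts(rec.end_ts),
                    _format_ts(rec.renege_ts),
                    rec.risk_level or "",
                    rec.counselor_id or "",
                ]
            )


def read_log(path, validate: bool = True) -> list[ChatRecord]:
    """Read a CSV event log; inverse of :func:`write_log` on valid logs."""
    out: list[ChatRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise LogParseError(f"unexpected header {header!r}", 0, "header")
        for i, row in enumerate(reader, start=1):
            if len(row) != len(CSV_HEADER):
                raise LogParseError(f"expected {len(CSV_HEADER)} cells, got {len(row)}", i, "row")
            cells = dict(zip(CSV_HEADER, row))
            tos_cell = cells["tos_accepted"].lower()
            if tos_cell not in ("true", "false"):
                raise LogParseError(f"expected true/false, got {cells['tos_accepted']!r}", i, "tos_accepted")
            arrival = _parse_ts(cells["arrival_ts"], i, "arrival_ts")
            if arrival is None:
                raise LogParseError("missing arrival timestamp", i, "arrival_ts")
            rec = ChatRecord(
                user_id=cells["user_id"],
                channel=_parse_enum(cells["channel"], CHANNELS, i, "channel", optional=False),
                arrival_ts=arrival,
                tos_accepted=tos_cell == "true",
                user_type=_parse_enum(cells["user_type"], USER_TYPES, i, "user_type", optional=False),
                pickup_ts=_parse_ts(cells["pickup_ts"], i, "pickup_ts"),
                end_ts=_parse_ts(cells["end_ts"], i, "end_ts"),
                renege_ts=_parse_ts(cells["renege_ts"], i, "renege_ts"),
                risk_level=_parse_enum(cells["risk_level"], RISK_LEVELS, i, "risk_level", optional=True),
                counselor_id=cells["counselor_id"] or None,
            )
            if validate:
                try:
                    rec.validate()
                except RecordInvariantError as exc:
                    raise LogParseError(str(exc), i, "record") from None
            out.append(rec)
    return out
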
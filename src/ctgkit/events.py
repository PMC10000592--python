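"""Transient CTG events: accelerations, decelerations, contractions.

Every event is anchored by three sample indices — where the trace leaves
the baseline (``start``), its extremum (peak or nadir), and where it
returns (``end``). Deceleration events additionally carry a fuzzy
membership degree and, once typed, an early/late/variable label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

ACCELERATION = "acceleration"
DECELERATION = "deceleration"
CONTRACTION = "contraction"
BASELINE_CHANGE = "baseline_change"

_KINDS = {ACCELERATION, DECELERATION, CONTRACTION, BASELINE_CHANGE}
DECEL_TYPES = ("early", "late", "variable", "untyped")


@dataclass(frozen=True)
class Event:
    """One detected or ground-truth event on a CTG channel.

    Parameters
    ----------
    kind : str
        One of ``acceleration``, ``deceleration``, ``contraction`` or
        ``baseline_change`` (an excursion exceeding 10 min, which by
        convention is a shift of baseline rather than an event).
    start, extremum, end : int
        Sample indices; ``start < extremum < end`` with a half-open
        span ``[start, end)``.
    amplitude : float
        Absolute deviation of the extremum from baseline, in bpm for
        heart-rate events and pressure units for contractions.
    sample_rate : float
        Hz; fixes the duration in seconds.
    membership : float or None
        Fuzzy membership degree in [0, 1]; defined only for
        decelerations (crisp NICHD events have membership 1).
    decel_type : str
        ``early``/``late``/``variable`` once typed, else ``untyped``.
    """

    kind: str
    start: int
    extremum: int
    end: int
    amplitude: float
    sample_rate: float
    membership: float | None = None
    decel_type: str = "untyped"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (self.start < self.extremum < self.end):
            raise ValueError(
                f"event indices must satisfy start < extremum < end, "
                f"got ({self.start}, {self.extremum}, {self.end})"
            )
        if self.membership is not None and self.kind not in (DECELERATION, BASELINE_CHANGE):
            raise ValueError("membership is defined only for decelerations")
        if self.decel_type not in DECEL_TYPES:
            raise ValueError(f"unknown deceleration type {self.decel_type!r}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.sample_rate

    def with_type(self, decel_type: str) -> "Event":
        return replace(self, decel_type=decel_type)


class EventLog:
    """Ordered collection of :class:`Event` with per-kind accessors."""

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self._events = sorted(events, key=lambda e: (e.start, e.end))

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self._events == other._events

    def of_kind(self, kind: str) -> "EventLog":
        return EventLog(e for e in self._events if e.kind == kind)

    @property
    def accelerations(self) -> "EventLog":
        return self.of_kind(ACCELERATION)

    @property
    def decelerations(self) -> "EventLog":
        return self.of_kind(DECELERATION)

    @property
    def contractions(self) -> "EventLog":
        return self.of_kind(CONTRACTION)

    def count_decel_types(self) -> dict[str, int]:
        counts = {t: 0 for t in DECEL_TYPES}
        for e in self.decelerations:
            counts[e.decel_type] += 1
        return counts

    def extend(self, events: Iterable[Event]) -> "EventLog":
        return EventLog([*self._events, *events])

    def to_frame(self) -> pd.DataFrame:
        """Interval table (one row per event) for TSV export."""
        rows = [
            {
                "start_s": e.start / e.sample_rate,
                "end_s": e.end / e.sample_rate,
                "extremum_s": e.extremum / e.sample_rate,
                "kind": e.kind,
                "type": e.decel_type if e.kind == DECELERATION else ".",
                "amplitude": e.amplitude,
                "membership": e.membership if e.membership is not None else float("nan"),
            }
            for e in self._events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "start_s", "end_s", "extremum_s", "kind",
                "type", "amplitude", "membership",
            ],
        )

    def __repr__(self) -> str:
        kinds = {}
        for e in self._events:
            kinds[e.kind] = kinds.get(e.kind, 0) + 1
        return f"EventLog({kinds})"
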
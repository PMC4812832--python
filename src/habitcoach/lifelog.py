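"""Life-log construction.

Per-second activity labels are condensed in two stages — minute-level
majority vote, then merging of contiguous same-label minutes — and short
heterogeneous activity sequences (e.g. walk / wait / bus / walk on a
commute) are further combined into single "mixed" events when every
constituent is shorter than a 15-minute window. Food entries and manually
logged exercises are then interleaved to form the chronological life log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity_recognition import GmmClassifier
from .energy import FoodTable, MetTable, activity_kcal, food_kcal, mixed_kcal

logger = logging.getLogger(__name__)

#: Nominal duration assigned to instantaneous food-log entries.
FOOD_EVENT_MINUTES = 1.0


@dataclass(frozen=True)
class LifeEvent:
    """A time-bounded entry in the life log.

    ``kind`` is one of activity / mixed / food / manual_exercise. For mixed
    events ``constituents`` holds the ordered (label, minutes) parts; for
    food events ``label`` is the food_id. ``calories`` is kcal burned for
    activity kinds and kcal consumed for food.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    kind: str
    label: str
    calories: float = 0.0
    trace: np.ndarray | None = None  # (n, 2) lat/lon or None
    constituents: tuple[tuple[str, float], ...] = ()
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("event end must be after start")
        if self.kind == "mixed" and len(self.constituents) < 2:
            raise ValueError("mixed events need >= 2 constituents")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def to_json(self) -> str:
        d = {
            "start": self.start.isoformat(),
            "end": self.end.isoformat(),
            "kind": self.kind,
            "label": self.label,
            "calories": round(self.calories, 3),
            "duration_minutes": round(self.duration_minutes, 3),
        }
        if self.trace is not None and len(self.trace):
            d["trace"] = [[round(a, 6), round(b, 6)] for a, b in np.asarray(self.trace)]
        if self.constituents:
            d["constituents"] = [[lbl, m] for lbl, m in self.constituents]
        return json.dumps(d)


def _tie_break_order(label: str):
    return GmmClassifier._class_sort_key(label)


def aggregate_minute(per_second_labels) -> list[str]:
    """Majority label per minute.

    A tied minute takes the previous minute's label when that label is among
    the tied leaders, otherwise the first tied label in the fixed class
    order. A trailing partial minute is voted over its available seconds.
    """
    labels = list(per_second_labels)
    if not labels:
        return []
    out: list[str] = []
    for i in range(0, len(labels), 60):
        chunk = labels[i : i + 60]
        counts: dict[str, int] = {}
        for lbl in chunk:
            counts[lbl] = counts.get(lbl, 0) + 1
        top = max(counts.values())
        tied = sorted((l for l, c in counts.items() if c == top), key=_tie_break_order)
        if len(tied) == 1:
            out.append(tied[0])
        elif out and out[-1] in tied:
            out.append(out[-1])
        else:
            out.append(tied[0])
    return out


def merge_contiguous(minute_labels, start: pd.Timestamp) -> list[LifeEvent]:
    """Collapse maximal runs of identical minute labels into single events."""
    labels = list(minute_labels)
    events: list[LifeEvent] = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        events.append(
            LifeEvent(
                start=start + pd.Timedelta(minutes=i),
                end=start + pd.Timedelta(minutes=j),
                kind="activity",
                label=labels[i],
            )
        )
        i = j
    return events


def build_mixed_events(events: list[LifeEvent], window_minutes: float = 15.0) -> list[LifeEvent]:
    """Combine short heterogeneous activity sequences into mixed events.

    A maximal chain of consecutive activity events is replaced by one
    ``mixed`` event when it has >= 2 events with >= 2 distinct labels, every
    constituent is shorter than ``window_minutes`` and every gap between
    consecutive chain members is shorter than ``window_minutes``. Events of
    ``window_minutes`` or longer are never absorbed, so long stationary
    blocks survive intact. Idempotent: mixed events never re-chain.
    """
    events = sorted(events, key=lambda e: e.start)
    out: list[LifeEvent] = []
    chain: list[LifeEvent] = []

    def flush():
        if not chain:
            return
        if len(chain) >= 2 and len({e.label for e in chain}) >= 2:
            constituents = tuple((e.label, e.duration_minutes) for e in chain)
            out.append(
                LifeEvent(
                    start=chain[0].start,
                    end=chain[-1].end,
                    kind="mixed",
                    label="mixed",
                    constituents=constituents,
                )
            )
        else:
            out.extend(chain)
        chain.clear()

    for ev in events:
        short = ev.kind == "activity" and ev.duration_minutes < window_minutes
        if not short:
            flush()
            out.append(ev)
            continue
        if chain:
            gap = (ev.start - chain[-1].end).total_seconds() / 60.0
            if gap >= window_minutes:
                flush()
        chain.append(ev)
    flush()
    return sorted(out, key=lambda e: e.start)


@dataclass(frozen=True)
class FoodLogEntry:
    timestamp: pd.Timestamp
    food_id: str | None
    quantity: float = 1.0
    override_kcal: float | None = None  # direct label-calorie entry


@dataclass(frozen=True)
class ManualEntry:
    start: pd.Timestamp
    end: pd.Timestamp
    activity_name: str  # must resolve in the MET table


def _truncate_against(ev: LifeEvent, m_start: pd.Timestamp, m_end: pd.Timestamp) -> list[LifeEvent]:
    """Clip an automatic event against a manual interval (manual wins)."""
    if ev.end <= m_start or ev.start >= m_end:
        return [ev]
    logger.debug("manual entry %s-%s truncates automatic %s event", m_start, m_end, ev.label)
    pieces = []
    orig = ev.duration_minutes
    for s, e in ((ev.start, min(ev.end, m_start)), (max(ev.start, m_end), ev.end)):
        if e > s:
            frac = ((e - s).total_seconds() / 60.0) / orig if orig > 0 else 0.0
            pieces.append(replace(ev, start=s, end=e, calories=ev.calories * frac))
    return pieces


def assemble_lifelog(
    activity_events: list[LifeEvent],
    food_log: list[FoodLogEntry],
    manual_entries: list[ManualEntry],
    *,
    weight_kg: float,
    met_table: MetTable,
    food_table: FoodTable,
) -> list[LifeEvent]:
    """Interleave activity, food and manual-exercise events chronologically.

    Activity and mixed events get MET-based calories here; food events get
    table (or label-override) calories; a manual entry overlapping an
    automatic event wins, and the automatic event is truncated around it.
    """
    auto: list[LifeEvent] = []
    for ev in activity_events:
        if ev.kind == "mixed":
            kcal = mixed_kcal(list(ev.constituents), weight_kg, met_table)
        else:
            kcal = activity_kcal(ev.label, ev.duration_minutes, weight_kg, met_table)
        auto.append(replace(ev, calories=kcal))

    manual_events = [
        LifeEvent(
            start=m.start,
            end=m.end,
            kind="manual_exercise",
            label=m.activity_name,
            calories=activity_kcal(
                m.activity_name,
                (m.end - m.start).total_seconds() / 60.0,
                weight_kg,
                met_table,
            ),
        )
        for m in manual_entries
    ]
    for m in manual_entries:
        auto = [piece for ev in auto for piece in _truncate_against(ev, m.start, m.end)]

    food_events = [
        LifeEvent(
            start=f.timestamp,
            end=f.timestamp + pd.Timedelta(minutes=FOOD_EVENT_MINUTES),
            kind="food",
            label=f.food_id if f.food_id is not None else "direct_entry",
            calories=food_kcal(f.food_id, f.quantity, food_table, f.override_kcal),
        )
        for f in food_log
    ]

    return sorted(auto + manual_events + food_events, key=lambda e: (e.start, e.kind))


def write_jsonl(events: list[LifeEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")
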
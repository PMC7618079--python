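"""Tabular event logs shared by the cell-based engines.

Both simulators emit the same ordered record stream: one row per discrete
event with columns ``time, event, cell_id, cell_type``.  Division, death and
G1-exit events are common to both engines; the vertex engine additionally
logs ``t1swap`` and ``t2swap`` mesh rearrangements.  Survival frequencies
and all downstream competition statistics are computed from these logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["EventLog", "EVENT_KINDS"]

EVENT_KINDS = ("division", "death", "g1exit", "t1swap", "t2swap")


@dataclass
class EventLog:
    """Ordered record of discrete simulation events.

    Invariants: times are non-decreasing in record order, and every event
    kind is one of :data:`EVENT_KINDS`.  ``metadata`` carries run provenance
    (seed, truncation flags, engine name).
    """

    times: list[float] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    cell_ids: list[int] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def record(self, time: float, event: str, cell_id: int, cell_type: str) -> None:
        if event not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {event!r}")
        if self.times and time < self.times[-1] - 1e-12:
            raise ValueError("event times must be non-decreasing")
        self.times.append(float(time))
        self.events.append(event)
        self.cell_ids.append(int(cell_id))
        self.cell_types.append(cell_type)

    def __len__(self) -> int:
        return len(self.times)

    def count(self, event: str, cell_type: Optional[str] = None,
              t_min: float = -float("inf")) -> int:
        """Number of events of a kind, optionally per type and after t_min."""
        return sum(
            1
            for t, e, c in zip(self.times, self.events, self.cell_types)
            if e == event and t >= t_min and (cell_type is None or c == cell_type)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "event": self.events,
                "cell_id": self.cell_ids,
                "cell_type": self.cell_types,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: Optional[dict] = None) -> "EventLog":
        log = cls(metadata=metadata or {})
        log.times = [float(t) for t in frame["time"]]
        log.events = list(frame["event"])
        log.cell_ids = [int(c) for c in frame["cell_id"]]
        log.cell_types = list(frame["cell_type"])
        return log

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        return cls.from_frame(pd.read_csv(path))
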
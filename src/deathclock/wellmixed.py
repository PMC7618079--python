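"""Exact event-driven simulator of the well-mixed G2 death-signal model.

Every cell interacts with every other cell: the raw death signal seen by a
cell is the fraction of *other* cells currently in G2 phase.  Between
discrete events (G1 exits, divisions, deaths) that fraction is constant, so
death-clock trajectories are piecewise linear and threshold crossings can
be computed exactly -- the simulation jumps from event to event with no
integration error.

Cells are stored struct-of-arrays for speed; :meth:`WellMixedState.cell`
materialises a :class:`~deathclock.core.CellRecord` view of one cell for
inspection.  Events are processed one at a time in (time, cell id) order;
if a cell's clock reaches the threshold exactly when its G1 phase would
end, death wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import CellRecord, DeathClockParams, sample_g1
from .events import EventLog

__all__ = [
    "SimConfig",
    "WellMixedState",
    "Event",
    "g2_signal_fraction",
    "next_event",
    "apply_event",
    "run_wellmixed",
]

_G1, _G2 = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a well-mixed run.

    ``initial_counts`` maps type labels to initial cell numbers and
    ``params`` maps the same labels to their death-clock parameters.
    ``init`` selects the initial cycle state: ``"newborn"`` (all cells born
    at t = 0 with fresh G1 draws) or ``"staggered"`` (cycle positions drawn
    from the stationary phase distribution, which shortens the transient).
    """

    end_time: float
    initial_counts: dict
    params: dict
    seed: int = 0
    max_population: int = 100_000
    max_events: Optional[int] = None
    init: str = "newborn"
    log_g1_exits: bool = True

    def __post_init__(self) -> None:
        if not self.end_time > 0:
            raise ValueError("end_time must be positive")
        if any(n < 0 for n in self.initial_counts.values()):
            raise ValueError("initial counts must be non-negative")
        if self.init not in ("newborn", "staggered"):
            raise ValueError(f"unknown init mode {self.init!r}")
        missing = set(self.initial_counts) - set(self.params)
        if missing:
            raise ValueError(f"missing params for types {sorted(missing)}")


@dataclass
class Event:
    """A scheduled discrete event, tagged with the state revision that
    produced it so stale events are rejected."""

    time: float
    kind: str  # "division" | "death" | "g1exit" | "end" | "extinct"
    index: int  # slot index in the state arrays (-1 for end/extinct)
    revision: int


class WellMixedState:
    """Struct-of-arrays population state for the well-mixed engine."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.time = 0.0
        self.revision = 0
        self.type_labels = sorted(config.initial_counts)
        self.params_by_type = {t: config.params[t] for t in self.type_labels}

        n0 = sum(config.initial_counts.values())
        cap = max(16, 2 * n0)
        self.type_idx = np.zeros(cap, dtype=np.int64)
        self.phase = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.tau = np.zeros(cap)
        self.birth = np.zeros(cap)
        self.t_star = np.zeros(cap)
        self.t_g1_end = np.zeros(cap)  # scheduled G1 exit (phase G1)
        self.t_div = np.zeros(cap)  # scheduled division (phase G2)
        self.cell_id = np.zeros(cap, dtype=np.int64)
        self.n = 0
        self.next_id = 0

        # per-type constant vectors aligned with type_idx
        self._c = np.array(
            [self.params_by_type[t].signal_strength for t in self.type_labels]
        )
        self._T = np.array(
            [self.params_by_type[t].death_threshold for t in self.type_labels]
        )
        self._tg2 = np.array(
            [self.params_by_type[t].g2_duration for t in self.type_labels]
        )

        for ti, label in enumerate(self.type_labels):
            for _ in range(config.initial_counts[label]):
                self._add_initial_cell(ti, label)

    # -- construction -----------------------------------------------------

    def _grow(self) -> None:
        cap = len(self.tau)
        for name in ("type_idx", "phase", "alive", "tau", "birth", "t_star",
                     "t_g1_end", "t_div", "cell_id"):
            arr = getattr(self, name)
            new = np.zeros(2 * cap, dtype=arr.dtype)
            new[:cap] = arr
            setattr(self, name, new)

    def _new_slot(self) -> int:
        if self.n >= len(self.tau):
            self._grow()
        i = self.n
        self.n += 1
        return i

    def _add_initial_cell(self, ti: int, label: str) -> None:
        p = self.params_by_type[label]
        i = self._new_slot()
        self.type_idx[i] = ti
        self.alive[i] = True
        self.cell_id[i] = self.next_id
        self.next_id += 1
        self.birth[i] = 0.0
        self.tau[i] = 0.0
        if self.config.init == "staggered" and p.cycle_mean > 0:
            if self.rng.random() < p.g2_duration / p.cycle_mean:
                # mid-G2: residual division time uniform over the phase
                self.phase[i] = _G2
                self.t_star[i] = sample_g1(p, self.rng)
                self.t_div[i] = self.rng.random() * p.g2_duration
                return
            # mid-G1: residual duration is memoryless for the exponential
            # family (drawn fresh), the clock restarts at zero
        self.phase[i] = _G1
        self.t_star[i] = sample_g1(p, self.rng)
        self.t_g1_end[i] = self.t_star[i]

    # -- views ------------------------------------------------------------

    @property
    def population(self) -> int:
        return int(self.alive[: self.n].sum())

    def counts(self) -> dict:
        out = {}
        for ti, label in enumerate(self.type_labels):
            mask = self.alive[: self.n] & (self.type_idx[: self.n] == ti)
            out[label] = int(mask.sum())
        return out

    def cell(self, index: int) -> CellRecord:
        """Materialise a CellRecord view of slot ``index``."""
        label = self.type_labels[self.type_idx[index]]
        return CellRecord(
            params=self.params_by_type[label],
            sampled_g1=float(self.t_star[index]),
            birth_time=float(self.birth[index]),
            clock=float(self.tau[index]),
            phase="G2" if self.phase[index] == _G2 else "G1",
            type_label=label,
            cell_id=int(self.cell_id[index]),
        )


def g2_signal_fraction(state: WellMixedState, index: int) -> float:
    """Fraction of *other* cells in G2 phase, as seen by cell ``index``.

    Zero when the focal cell is alone.
    """
    if not state.alive[index]:
        raise ValueError("focal cell is not alive")
    n = state.population
    if n <= 1:
        return 0.0
    alive = state.alive[: state.n]
    n_g2 = int((state.phase[: state.n][alive] == _G2).sum())
    if state.phase[index] == _G2:
        n_g2 -= 1
    return n_g2 / (n - 1)


def next_event(state: WellMixedState) -> Event:
    """Earliest pending event: G1 exit, division, or threshold crossing.

    Between events the signal seen by each cell is constant, so clock
    crossing times (T_death - tau) / (c * g) are exact.  Ties are broken by
    cell id; a death tying with the same cell's G1 exit is a death.
    """
    n = state.n
    alive = state.alive[:n]
    if not alive.any():
        return Event(state.time, "extinct", -1, state.revision)
    phase = state.phase[:n]
    in_g1 = alive & (phase == _G1)
    in_g2 = alive & (phase == _G2)

    pop = int(alive.sum())
    n_g2_total = int(in_g2.sum())
    g_g1 = n_g2_total / (pop - 1) if pop > 1 else 0.0

    cand = np.full(n, np.inf)
    kind = np.zeros(n, dtype=np.int64)  # 0 g1exit, 1 division, 2 death
    cand[in_g1] = state.t_g1_end[:n][in_g1]
    cand[in_g2] = state.t_div[:n][in_g2]
    kind[in_g2] = 1
    if g_g1 > 0.0:
        c = state._c[state.type_idx[:n]]
        rate = c * g_g1
        # remaining clock headroom; clamped at zero so a clock that has
        # drifted a few ulp past the threshold dies "now", never in the past
        headroom = np.maximum(state._T[state.type_idx[:n]] - state.tau[:n], 0.0)
        with np.errstate(divide="ignore"):
            t_death = np.where(
                in_g1 & (rate > 0),
                state.time + headroom / np.where(rate > 0, rate, 1.0),
                np.inf,
            )
        # death wins a tie with the same cell's G1 exit
        death_first = t_death <= cand
        kind = np.where(in_g1 & death_first, 2, kind)
        cand = np.where(in_g1 & death_first, t_death, cand)

    t_min = cand.min()
    tied = np.flatnonzero(cand == t_min)
    idx = int(tied[np.argmin(state.cell_id[tied])])
    if t_min > state.config.end_time:
        return Event(state.config.end_time, "end", -1, state.revision)
    names = {0: "g1exit", 1: "division", 2: "death"}
    return Event(float(t_min), names[int(kind[idx])], idx, state.revision)


def _advance_clocks(state: WellMixedState, t_new: float) -> None:
    """Integrate every living cell's clock over [state.time, t_new] with the
    signal fraction that held over the interval."""
    dt = t_new - state.time
    if dt < -1e-9:
        raise ValueError("time must advance")
    dt = max(dt, 0.0)
    n = state.n
    alive = state.alive[:n]
    pop = int(alive.sum())
    if pop > 1 and dt > 0:
        in_g2 = alive & (state.phase[:n] == _G2)
        n_g2_total = int(in_g2.sum())
        g = np.where(in_g2, (n_g2_total - 1) / (pop - 1), n_g2_total / (pop - 1))
        c = state._c[state.type_idx[:n]]
        state.tau[:n][alive] += (c * g * dt)[alive]
    state.time = max(state.time, t_new)


def apply_event(state: WellMixedState, event: Event) -> None:
    """Advance all clocks to the event time and apply the event in place."""
    if event.revision != state.revision:
        raise RuntimeError("stale event: state has changed since scheduling")
    _advance_clocks(state, event.time)
    state.revision += 1
    if event.kind in ("end", "extinct"):
        return
    i = event.index
    if event.kind == "death":
        state.alive[i] = False
    elif event.kind == "g1exit":
        p = state.params_by_type[state.type_labels[state.type_idx[i]]]
        state.phase[i] = _G2
        state.t_div[i] = event.time + p.g2_duration
    elif event.kind == "division":
        label = state.type_labels[state.type_idx[i]]
        p = state.params_by_type[label]
        # mother slot is reused for one daughter; the other gets a new slot
        for slot in (i, state._new_slot()):
            state.type_idx[slot] = state.type_idx[i]
            state.alive[slot] = True
            state.phase[slot] = _G1
            state.tau[slot] = 0.0
            state.birth[slot] = event.time
            state.t_star[slot] = sample_g1(p, state.rng)
            state.t_g1_end[slot] = event.time + state.t_star[slot]
            if slot != i:
                state.cell_id[slot] = state.next_id
                state.next_id += 1
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")


def run_wellmixed(config: SimConfig) -> EventLog:
    """Run the event loop to end time, extinction, or the population cap.

    Deterministic given the seed.  Returns the complete event log; the log
    metadata records the final population, truncation and extinction flags.
    """
    rng = np.random.default_rng(config.seed)
    state = WellMixedState(config, rng)
    log = EventLog(metadata={
        "engine": "wellmixed",
        "seed": config.seed,
        "init": config.init,
        "truncated": False,
        "extinct": False,
    })
    n_events = 0
    while True:
        event = next_event(state)
        apply_event(state, event)
        if event.kind == "extinct":
            log.metadata["extinct"] = True
            break
        if event.kind == "end":
            break
        if event.kind != "g1exit" or config.log_g1_exits:
            label = state.type_labels[state.type_idx[event.index]]
            log.record(event.time, event.kind, int(state.cell_id[event.index]), label)
        n_events += 1
        if state.population > config.max_population:
            log.metadata["truncated"] = True
            break
        if config.max_events is not None and n_events >= config.max_events:
            log.metadata["truncated"] = True
            break
    log.metadata["final_time"] = state.time
    log.metadata["final_counts"] = state.counts()
    return log
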
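"""Single-cell death-clock primitives.

A cell accumulates a non-negative extracellular *death signal* ``f(t)`` into
its death clock ``tau`` (dtau/dt = f).  The clock starts at zero at birth.
While the cell is in G1 phase, reaching the death threshold ``T_death``
triggers apoptosis; from G2 onwards the cell is committed to division and is
impervious to the signal (the clock keeps integrating but cannot kill).  The
G1 duration ``t_star`` is a random draw with mean ``g1_mean``; the G2
duration is fixed.

Because both cell-based engines in this package only ever change the signal
at discrete events, signals are represented exactly as piecewise-constant
functions (:class:`SignalPrimitive`), which makes clock crossing times and
the pseudoinverse of the cumulative signal exact -- no ODE solver is
involved anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DeathClockParams",
    "CellRecord",
    "SignalPrimitive",
    "sample_g1",
    "g1_cdf",
    "pseudoinverse",
    "survival_probability",
    "check_survival",
]

#: Sentinel for "the cumulative signal never reaches this level".
INFINITE_TIME = math.inf


@dataclass(frozen=True)
class DeathClockParams:
    """Per-cell-type parameters of the death-clock process.

    Parameters
    ----------
    death_threshold
        Signal level ``T_death > 0`` at which apoptosis triggers in G1.
    signal_strength
        Scale factor ``c >= 0`` multiplying the raw neighbourhood signal.
    g1_mean
        Mean G1 duration ``t_G1 >= 0``.
    g2_duration
        Fixed G2 duration ``t_G2 >= 0`` (S/G2/M lumped together).
    g1_distribution
        Family of the G1 duration draw: ``"exponential"`` (mean ``g1_mean``)
        or ``"fixed"`` (degenerate at ``g1_mean``).
    """

    death_threshold: float
    signal_strength: float = 1.0
    g1_mean: float = 1.0
    g2_duration: float = 1.0
    g1_distribution: str = "exponential"

    def __post_init__(self) -> None:
        if not self.death_threshold > 0:
            raise ValueError("death_threshold must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if self.g1_mean < 0:
            raise ValueError("g1_mean must be non-negative")
        if self.g2_duration < 0:
            raise ValueError("g2_duration must be non-negative")
        if self.g1_distribution not in ("exponential", "fixed"):
            raise ValueError(
                f"unsupported g1_distribution {self.g1_distribution!r}"
            )

    @property
    def cycle_mean(self) -> float:
        """Mean total cell-cycle duration ``t_G = t_G1 + t_G2``."""
        return self.g1_mean + self.g2_duration


@dataclass
class CellRecord:
    """State of a single cell: clock, cycle position, identity.

    ``clock`` is the accumulated death signal tau (non-decreasing over the
    cell's lifetime, zero at birth).  ``phase`` is ``"G1"`` until the cell's
    age reaches its sampled G1 duration, then ``"G2"`` until division.
    """

    params: DeathClockParams
    sampled_g1: float
    birth_time: float = 0.0
    clock: float = 0.0
    phase: str = "G1"
    type_label: str = "A"
    cell_id: int = 0

    def __post_init__(self) -> None:
        if self.clock < 0:
            raise ValueError("clock must be non-negative")
        if self.phase not in ("G1", "G2"):
            raise ValueError(f"invalid phase {self.phase!r}")

    def advance_clock(self, amount: float) -> None:
        """Integrate the clock by ``amount >= 0`` signal-units."""
        if amount < -1e-12:
            raise ValueError("clock increments must be non-negative")
        self.clock += max(amount, 0.0)


class SignalPrimitive:
    """Piecewise-constant non-negative signal ``f(t)`` on ``[0, inf)``.

    Defined by breakpoints ``0 = t_0 < t_1 < ... < t_k`` and values
    ``v_0, ..., v_k`` where ``f(t) = v_i`` on ``[t_i, t_{i+1})`` and
    ``f(t) = v_k`` for ``t >= t_k``.  The cumulative signal
    ``F(t) = int_0^t f`` is continuous, piecewise linear and non-decreasing,
    with ``F(0) = 0``.
    """

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        bp = np.asarray(breakpoints, dtype=float)
        vals = np.asarray(values, dtype=float)
        if bp.ndim != 1 or vals.ndim != 1 or bp.size != vals.size:
            raise ValueError("breakpoints and values must be 1-D and equal length")
        if bp.size == 0 or bp[0] != 0.0:
            raise ValueError("first breakpoint must be t = 0")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("signal must be non-negative")
        self.breakpoints = bp
        self.values = vals
        # cumulative F at each breakpoint
        seg = np.diff(bp) * vals[:-1]
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @classmethod
    def constant(cls, value: float) -> "SignalPrimitive":
        return cls([0.0], [value])

    def __call__(self, t: float) -> float:
        """Signal value f(t)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.values[i])

    def cumulative(self, t: float) -> float:
        """Cumulative signal F(t)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self._cum[i] + self.values[i] * (t - self.breakpoints[i]))


def sample_g1(params: DeathClockParams, rng: np.random.Generator) -> float:
    """Draw a G1 duration ``t_star`` from the configured family.

    Exponential family uses rate ``1/g1_mean`` so that E[t_star] = g1_mean;
    the degenerate limit ``g1_mean = 0`` returns 0 exactly.  The fixed
    family always returns ``g1_mean``.
    """
    if params.g1_distribution == "fixed":
        return params.g1_mean
    if params.g1_mean == 0.0:
        return 0.0
    return float(rng.exponential(params.g1_mean))


def g1_cdf(params: DeathClockParams, t: float) -> float:
    """P(t_star < t) for the configured G1 family.

    For the (continuous) exponential family this is the usual CDF; for the
    fixed family it is the strict step ``1{g1_mean < t}``, matching the
    strict inequality in the survival condition.
    """
    if t == INFINITE_TIME:
        return 1.0
    if t < 0:
        return 0.0
    if params.g1_distribution == "fixed" or params.g1_mean == 0.0:
        return 1.0 if params.g1_mean < t else 0.0
    return 1.0 - math.exp(-t / params.g1_mean)


def pseudoinverse(signal: SignalPrimitive, tau: float) -> float:
    """First time at which the cumulative signal reaches ``tau``.

    Returns ``min{t >= 0 : F(t) = tau}``, or :data:`INFINITE_TIME` if the
    cumulative signal never reaches ``tau``.  Exact for piecewise-constant
    signals: within a segment of positive value the crossing is linear;
    flat segments are skipped (the minimum lands on the earliest attaining
    time).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0.0:
        return 0.0
    cum = signal._cum
    bp = signal.breakpoints
    vals = signal.values
    # first breakpoint whose cumulative value reaches tau; the left bisect
    # guarantees cum[j-1] < tau <= cum[j], so segment j-1 has positive value
    # and the linear crossing inside it is the earliest attaining time (for
    # tau attained at the start of a flat run, the formula lands exactly on
    # the run's first point).
    j = int(np.searchsorted(cum, tau, side="left"))
    if j < len(cum):
        i = j - 1
        return float(bp[i]) + (tau - float(cum[i])) / float(vals[i])
    # beyond the last breakpoint (a subnormal rate may overflow to inf,
    # which correctly degrades to the "never reached" sentinel)
    if vals[-1] == 0.0:
        return INFINITE_TIME
    try:
        return float(bp[-1]) + (tau - float(cum[-1])) / float(vals[-1])
    except OverflowError:
        return INFINITE_TIME


def survival_probability(signal: SignalPrimitive, params: DeathClockParams) -> float:
    """Probability theta that a cell survives G1 under a prescribed signal.

    theta = P(tau(t_star) < T_death) = Psi(F^{-1}(T_death)) where Psi is the
    CDF of the G1 duration.  If the cumulative signal never reaches the
    threshold, the cell survives with probability one.
    """
    t_cross = pseudoinverse(signal, params.death_threshold)
    return g1_cdf(params, t_cross)


def check_survival(cell: CellRecord) -> bool:
    """Survival condition at G1 exit: ``tau(t_star) < T_death``.

    ``cell.clock`` must hold the clock value at the end of G1.  Since the
    signal is non-negative the clock is non-decreasing, so this is
    equivalent to the clock never having reached the threshold during G1.
    Reaching the threshold exactly counts as death.
    """
    return cell.clock < cell.params.death_threshold
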
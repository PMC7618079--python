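"""Closed-form theory of the G2 death-signal model.

Two dimensionless parameters characterise a cell type with an exponential
G1 duration and total cycle time ``t_G``:

* ``beta`` in (0, 1): the mean fraction of the cycle spent in G1, so
  ``t_G1 = beta * t_G`` and ``t_G2 = (1 - beta) * t_G``;
* ``eta = T_death / (c * t_G) > 0``: the normalised death threshold.

Under the ergodic approximation the fraction of cells in G2 -- hence the
raw death signal ``g`` -- is ``1 - beta`` in a homotypic population, and the
population-weighted average ``<1-beta>`` in a heterotypic one.  The
homotypic survival probability is then

    lambda(beta, eta) = 1 - exp(-eta / (beta * (1 - beta)))

and a population is viable when lambda >= 1/2, with the homotypic viability
curve eta = ln(2) * beta * (1 - beta).  Heterotypic survival probabilities,
winner/loser determination, asymptotic survival of the loser, interaction
classes and the full competition-regime taxonomy all follow from the same
approximation and are implemented here, together with the equivalent
tolerance/emission formulation (tolerance ``eta / (ln 2 * beta)``, emission
``1 - beta``).

All classifiers assume the two types share the same total cycle time
``t_G``, so relative success is governed by survival probabilities alone;
mismatched ``t_G`` raises unless explicitly overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

__all__ = [
    "DimensionlessType",
    "PopulationMix",
    "RegimeLabel",
    "homotypic_lambda",
    "viability_curve_eta",
    "ergodic_signal",
    "heterotypic_xi",
    "heterotypic_difference_sign",
    "homotypic_difference_sign",
    "asymptotic_survival",
    "classify_interaction",
    "classify_regime",
    "tolerance_emission",
    "cross_section_curves",
]

LN2 = math.log(2.0)

#: Absolute tolerance for detecting analytic boundary cases (equal
#: tolerances, beta ties, survival probabilities exactly 1/2).
BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class DimensionlessType:
    """A cell type reduced to its dimensionless parameters (beta, eta)."""

    beta: float
    eta: float
    t_g: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if not self.eta > 0.0:
            raise ValueError("eta must be positive")

    @property
    def tolerance(self) -> float:
        """Normalised tolerance to death signals, eta / (ln 2 * beta)."""
        return self.eta / (LN2 * self.beta)

    @property
    def emission(self) -> float:
        """Death-signal emission rate, 1 - beta (time fraction in G2)."""
        return 1.0 - self.beta


@dataclass(frozen=True)
class PopulationMix:
    """Cell counts of a (possibly degenerate) two-type population."""

    n_a: float
    n_b: float

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RegimeLabel:
    """Competition-regime classification of an ordered type pair.

    ``name`` is the most specific regime; coarser memberships are exposed as
    booleans so callers can test e.g. "is this in the competition regime"
    without string gymnastics.
    """

    name: str
    homotypic_viable: bool
    winner: Optional[str] = None
    loser: Optional[str] = None
    loser_eliminated: Optional[bool] = None


def homotypic_lambda(cell_type: DimensionlessType) -> float:
    """Homotypic survival probability lambda = 1 - exp(-eta/(beta(1-beta)))."""
    b, e = cell_type.beta, cell_type.eta
    return 1.0 - math.exp(-e / (b * (1.0 - b)))


def viability_curve_eta(beta: float) -> float:
    """eta on the homotypic viability curve (lambda = 1/2) at this beta."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    return LN2 * beta * (1.0 - beta)


def ergodic_signal(mix: PopulationMix, beta_a: float, beta_b: float) -> float:
    """Population-weighted mean G2 fraction <1-beta>.

    This is the ergodic approximation of the raw death signal g(t) in a
    well-mixed heterotypic population with counts (n_a, n_b).
    """
    total = mix.n_a + mix.n_b
    if total <= 0:
        raise ValueError("population must be non-empty")
    return (mix.n_a * (1.0 - beta_a) + mix.n_b * (1.0 - beta_b)) / total


def heterotypic_xi(cell_type: DimensionlessType, signal: float) -> float:
    """Instantaneous heterotypic survival probability at signal <1-beta>.

    xi = 1 - exp(-eta / (beta * signal)); a vanishing signal means the death
    clock never advances, so xi = 1.
    """
    if signal < 0 or signal > 1:
        raise ValueError("signal must lie in [0, 1]")
    if signal == 0.0:
        return 1.0
    return 1.0 - math.exp(-cell_type.eta / (cell_type.beta * signal))


def _sign(x: float, tol: float = BOUNDARY_TOL) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def _check_common_tg(
    type_a: DimensionlessType, type_b: DimensionlessType, allow_mismatched_tg: bool
) -> None:
    if allow_mismatched_tg:
        return
    if type_a.t_g is not None and type_b.t_g is not None:
        if not math.isclose(type_a.t_g, type_b.t_g, rel_tol=1e-9):
            raise ValueError(
                "winner/loser analysis assumes equal total cycle times; "
                "pass allow_mismatched_tg=True to override"
            )


def heterotypic_difference_sign(
    type_a: DimensionlessType,
    type_b: DimensionlessType,
    tol: float = BOUNDARY_TOL,
    allow_mismatched_tg: bool = False,
) -> int:
    """Sign of the heterotypic survival difference xi_A|B - xi_B|A.

    Equals sgn(eta_A/beta_A - eta_B/beta_B) -- the relative tolerance to
    death signals -- independently of the population state.  +1 means A is
    the winner, -1 means B, 0 means coexistence.
    """
    _check_common_tg(type_a, type_b, allow_mismatched_tg)
    return _sign(type_a.eta / type_a.beta - type_b.eta / type_b.beta, tol)


def homotypic_difference_sign(
    type_a: DimensionlessType,
    type_b: DimensionlessType,
    tol: float = BOUNDARY_TOL,
) -> int:
    """Sign of the homotypic survival difference xi_A|B - lambda_A.

    In a genuinely heterotypic population (both counts positive) this equals
    sgn(beta_B - beta_A): A gains from the interaction exactly when B emits
    less death signal than A itself.  Antisymmetric under a label swap.
    """
    return _sign(type_b.beta - type_a.beta, tol)


def asymptotic_survival(
    type_a: DimensionlessType,
    type_b: DimensionlessType,
    tol: float = BOUNDARY_TOL,
    allow_mismatched_tg: bool = False,
) -> tuple[str, float, float]:
    """Long-run heterotypic survival probabilities (winner first).

    As the winner W comes to dominate, <1-beta> -> 1 - beta_W, so the
    winner's asymptotic survival equals its homotypic lambda while the
    loser's is xi_inf = 1 - exp(-eta_L / (beta_L * (1 - beta_W))).

    Returns ``(winner_label, winner_survival, loser_survival)``.  Raises on
    coexistence (no asymptotic winner exists).
    """
    sign = heterotypic_difference_sign(
        type_a, type_b, tol, allow_mismatched_tg=allow_mismatched_tg
    )
    if sign == 0:
        raise ValueError("types coexist: no asymptotic winner")
    winner_label = "A" if sign > 0 else "B"
    winner = type_a if sign > 0 else type_b
    loser = type_b if sign > 0 else type_a
    return (
        winner_label,
        homotypic_lambda(winner),
        heterotypic_xi(loser, 1.0 - winner.beta),
    )


_INTERACTION_GRID = {
    (1, 1): ("direct competition", "A direct winner, B direct loser"),
    (1, 0): ("neutral competition", "A neutral winner, B neutral loser"),
    (1, -1): ("indirect competition", "A indirect winner, B indirect loser"),
    (0, 1): ("coexistence", "coexistence"),
    (0, 0): ("neutral coexistence", "neutral coexistence"),
    (0, -1): ("coexistence", "coexistence"),
    (-1, 1): ("indirect competition", "A indirect loser, B indirect winner"),
    (-1, 0): ("neutral competition", "A neutral loser, B neutral winner"),
    (-1, -1): ("direct competition", "A direct loser, B direct winner"),
}


def classify_interaction(
    type_a: DimensionlessType,
    type_b: DimensionlessType,
    tol: float = BOUNDARY_TOL,
    allow_mismatched_tg: bool = False,
) -> tuple[str, str]:
    """Interaction class from the two survival-difference signs.

    The 3x3 grid of (heterotypic sign, homotypic sign) collapses into five
    categories: neutral coexistence, coexistence, neutral competition,
    indirect competition and direct competition.  Returns
    ``(category, cell_description)``.
    """
    s_ne = heterotypic_difference_sign(
        type_a, type_b, tol, allow_mismatched_tg=allow_mismatched_tg
    )
    s_eq = homotypic_difference_sign(type_a, type_b, tol)
    return _INTERACTION_GRID[(s_ne, s_eq)]


def classify_regime(
    type_a: DimensionlessType,
    type_b: DimensionlessType,
    tol: float = BOUNDARY_TOL,
    allow_mismatched_tg: bool = False,
) -> RegimeLabel:
    """Most specific competition regime for an ordered type pair.

    The taxonomy (evaluated with tolerance ``tol`` on the analytic
    boundaries):

    * both lambdas > 1/2 is the *homotypic viability regime*; outside it the
      label is ``"outside homotypic viability"``;
    * within it, a vanishing heterotypic difference is *coexistence* (or
      *neutral coexistence* if the homotypic difference vanishes too);
    * otherwise a winner W and loser L exist and the loser's asymptotic
      survival xi_inf decides: < 1/2 *complete cell competition*, = 1/2
      *critical cell competition*, > 1/2 loser survival, subdivided by the
      homotypic-difference sign of the loser into *incomplete cell
      competition* (< 0), *neutral competition* (= 0) and *indirect
      competition* (> 0).
    """
    _check_common_tg(type_a, type_b, allow_mismatched_tg)
    lam_a = homotypic_lambda(type_a)
    lam_b = homotypic_lambda(type_b)
    both_viable = (lam_a - 0.5 > -tol) and (lam_b - 0.5 > -tol)
    # strict > 1/2 defines the analytic homotypic viability regime; points
    # within tol of the curve are on the viability boundary
    strictly_viable = (lam_a - 0.5 > tol) and (lam_b - 0.5 > tol)
    if not both_viable:
        return RegimeLabel("outside homotypic viability", homotypic_viable=False)
    if not strictly_viable:
        return RegimeLabel("homotypic viability boundary", homotypic_viable=True)

    s_ne = heterotypic_difference_sign(
        type_a, type_b, tol, allow_mismatched_tg=allow_mismatched_tg
    )
    if s_ne == 0:
        s_eq = homotypic_difference_sign(type_a, type_b, tol)
        name = "neutral coexistence" if s_eq == 0 else "coexistence"
        return RegimeLabel(name, homotypic_viable=True)

    winner = "A" if s_ne > 0 else "B"
    loser = "B" if s_ne > 0 else "A"
    w = type_a if s_ne > 0 else type_b
    l = type_b if s_ne > 0 else type_a
    xi_inf = heterotypic_xi(l, 1.0 - w.beta)
    s_xi = _sign(xi_inf - 0.5, tol)
    if s_xi < 0:
        name, eliminated = "complete cell competition", True
    elif s_xi == 0:
        name, eliminated = "critical cell competition", True
    else:
        # loser survival regime; subdivide by the loser's homotypic difference
        s_eq_l = homotypic_difference_sign(l, w, tol)
        if s_eq_l < 0:
            name = "incomplete cell competition"
        elif s_eq_l == 0:
            name = "neutral competition"
        else:
            name = "indirect competition"
        eliminated = False
    return RegimeLabel(
        name,
        homotypic_viable=True,
        winner=winner,
        loser=loser,
        loser_eliminated=eliminated,
    )


def tolerance_emission(cell_type: DimensionlessType) -> tuple[float, float]:
    """Transformed parameters (tolerance, emission) of a cell type.

    tolerance = eta / (ln 2 * beta), emission = 1 - beta.  Homotypic
    viability is emission < tolerance; loser elimination is
    loser tolerance < winner emission; complete cell competition is the
    chain  loser emission < loser tolerance < winner emission < winner
    tolerance.
    """
    return cell_type.tolerance, cell_type.emission


def cross_section_curves(
    type_b: DimensionlessType,
) -> dict[str, Callable[[float], float] | float | None]:
    """Regime-boundary curves in the (beta_A, eta_A) plane for fixed type B.

    Returns a dict with:

    * ``"coexistence"``: eta_A as a function of beta_A on the coexistence
      curve, eta_A = (eta_B / beta_B) * beta_A;
    * ``"a_winner"``: the A winner-viability curve
      eta_A = ln 2 * beta_A * (1 - beta_A);
    * ``"a_loser"``: the A loser-viability curve
      eta_A = ln 2 * (1 - beta_B) * beta_A;
    * ``"b_loser_beta"``: the vertical B loser-viability line
      beta_A = 1 - eta_B / (ln 2 * beta_B), or None when
      eta_B / beta_B > ln 2 (the line leaves the physical domain).
    """
    tol_b = type_b.eta / type_b.beta

    def coexistence(beta_a: float) -> float:
        return tol_b * beta_a

    def a_winner(beta_a: float) -> float:
        return LN2 * beta_a * (1.0 - beta_a)

    def a_loser(beta_a: float) -> float:
        return LN2 * (1.0 - type_b.beta) * beta_a

    b_loser: Optional[float]
    if tol_b > LN2:
        b_loser = None
    else:
        b_loser = 1.0 - type_b.eta / (LN2 * type_b.beta)
    return {
        "coexistence": coexistence,
        "a_winner": a_winner,
        "a_loser": a_loser,
        "b_loser_beta": b_loser,
    }
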
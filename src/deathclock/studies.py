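"""Canonical validation studies: theory-versus-simulation at desk scale.

Each function runs one of the package's standard computational studies from
scratch -- generating its own populations, simulating, and measuring -- and
returns a structured result.  They are deliberately sized for a single CPU:
survival frequencies are measured at several hundred to a couple of
thousand division/death events per condition, which is where sampling error
dominates the few-percent demographic deviations of the mean-field theory
(see the methods note).

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import (
    CROSS_SECTION_POINTS,
    CROSS_SECTIONS,
    HOMOTYPIC_GRID_BETAS,
    HOMOTYPIC_GRID_MULTIPLIERS,
    expand_dimensionless,
)
from .events import EventLog
from .metrics import survival_frequency
from .theory import (
    LN2,
    DimensionlessType,
    asymptotic_survival,
    heterotypic_difference_sign,
    homotypic_lambda,
)
from .wellmixed import SimConfig, run_wellmixed

__all__ = [
    "capped_counts",
    "homotypic_grid_study",
    "cross_section_study",
    "coexistence_curve_study",
    "neutral_curve_study",
]


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def capped_counts(log: EventLog, label: str, cap: int) -> tuple[int, int]:
    """(divisions, deaths) of one type over the first ``cap`` such events."""
    d = k = 0
    for event, cell_type in zip(log.events, log.cell_types):
        if cell_type != label:
            continue
        if event == "division":
            d += 1
        elif event == "death":
            k += 1
        if d + k >= cap:
            break
    return d, k


def _run_homotypic(beta, eta, seed, n0=150, end_time=12.0, cap=1500):
    cfg = SimConfig(
        end_time=end_time,
        initial_counts={"A": n0},
        params={"A": expand_dimensionless(beta, eta, t_g=1.0)},
        seed=seed,
        init="staggered",
        max_population=cap,
        log_g1_exits=False,
    )
    return run_wellmixed(cfg)


def _run_heterotypic(type_a, type_b, seed, n0=100, end_time=30.0, cap=4000):
    params = {
        "A": expand_dimensionless(*type_a, t_g=1.0),
        "B": expand_dimensionless(*type_b, t_g=1.0),
    }
    cfg = SimConfig(
        end_time=end_time,
        initial_counts={"A": n0, "B": n0},
        params=params,
        seed=seed,
        init="staggered",
        max_population=cap,
        log_g1_exits=False,
    )
    return run_wellmixed(cfg)


def homotypic_grid_study(seed: int = 0, event_cap: int = 600) -> list[dict]:
    """Well-mixed homotypic runs on the 3x3 validation grid.

    The grid crosses three G1 fractions with three multiples of the
    viability-curve threshold, straddling the predicted boundary.  Each
    point reports the survival frequency over the first ``event_cap``
    division/death events, the predicted survival probability, and the
    binomial standard error at the measured event count.
    """
    results = []
    for i, beta in enumerate(HOMOTYPIC_GRID_BETAS):
        for j, mult in enumerate(HOMOTYPIC_GRID_MULTIPLIERS):
            eta = mult * LN2 * beta * (1.0 - beta)
            lam = homotypic_lambda(DimensionlessType(beta, eta))
            log = _run_homotypic(beta, eta, _derived_seed(seed, i, j))
            d, k = capped_counts(log, "A", event_cap)
            n = d + k
            freq = d / n if n else float("nan")
            results.append({
                "beta": beta,
                "eta": eta,
                "lambda_theory": lam,
                "frequency": freq,
                "n_events": n,
                "binomial_se": math.sqrt(lam * (1 - lam) / n) if n else float("nan"),
            })
    return results


def predicted_viability(type_a: DimensionlessType, type_b: DimensionlessType):
    """(A viable, B viable) predicted from the asymptotic survival theory.

    If the winner is homotypically nonviable both types decline; otherwise
    the winner persists and the loser's fate follows its asymptotic
    survival probability.
    """
    winner, w_surv, l_surv = asymptotic_survival(type_a, type_b)
    if w_surv <= 0.5:
        return False, False
    pw, pl = True, l_surv > 0.5
    return (pw, pl) if winner == "A" else (pl, pw)


def cross_section_study(seed: int = 0) -> list[dict]:
    """Heterotypic well-mixed runs at the representative cross-section
    points, with the empirical viability pattern against the predicted
    regime diagram."""
    results = []
    for s, (section, (beta_b, eta_b)) in enumerate(sorted(CROSS_SECTIONS.items())):
        tb = DimensionlessType(beta_b, eta_b)
        for k, (beta_a, eta_a) in enumerate(CROSS_SECTION_POINTS[section]):
            ta = DimensionlessType(beta_a, eta_a)
            pred = predicted_viability(ta, tb)
            log = _run_heterotypic(
                (beta_a, eta_a), (beta_b, eta_b), _derived_seed(seed, 100 + s, k)
            )
            fa = survival_frequency(log, "A")
            fb = survival_frequency(log, "B")
            obs = (
                fa is not None and fa >= 0.5,
                fb is not None and fb >= 0.5,
            )
            results.append({
                "section": section,
                "type_a": (beta_a, eta_a),
                "type_b": (beta_b, eta_b),
                "winner": "A" if heterotypic_difference_sign(ta, tb) > 0 else "B",
                "predicted_viability": pred,
                "observed_viability": obs,
                "xi_a": fa,
                "xi_b": fb,
                "agrees": pred == obs,
            })
    return results


#: Type pairs on the coexistence curve (equal tolerance eta/beta), chosen
#: near the homotypic viability boundary where the ergodic approximation
#: is quantitatively accurate.
COEXISTENCE_PAIRS = [
    ((0.45, 0.2), (0.55, 0.2 * 0.55 / 0.45)),
    ((0.3, 0.15), (0.6, 0.3)),
]

#: A type pair on the neutral competition curve (equal beta): the shared
#: cycle structure pins the death signal at 1 - beta for both types, so
#: the heterotypic survival of either type equals its homotypic value.
NEUTRAL_PAIR = ((0.5, 0.18), (0.5, 0.3))


def coexistence_curve_study(seed: int = 0, event_cap: int = 800) -> list[dict]:
    """|xi_A - xi_B| on coexistence-curve pairs, with its binomial SE."""
    results = []
    for k, (ta, tb) in enumerate(COEXISTENCE_PAIRS):
        log = _run_heterotypic(ta, tb, _derived_seed(seed, 200, k),
                               n0=150, end_time=12.0, cap=2500)
        da, ka = capped_counts(log, "A", event_cap)
        db, kb = capped_counts(log, "B", event_cap)
        fa, fb = da / (da + ka), db / (db + kb)
        se = math.sqrt(
            fa * (1 - fa) / (da + ka) + fb * (1 - fb) / (db + kb)
        )
        results.append({
            "type_a": ta, "type_b": tb,
            "xi_a": fa, "xi_b": fb,
            "difference": abs(fa - fb),
            "se_difference": se,
            "n_a": da + ka, "n_b": db + kb,
        })
    return results


def neutral_curve_study(seed: int = 0, event_cap: int = 2000) -> dict:
    """|xi_A|B - lambda_A| for an equal-beta pair, with its binomial SE."""
    ta, tb = NEUTRAL_PAIR
    het = _run_heterotypic(ta, tb, _derived_seed(seed, 300),
                           n0=150, end_time=14.0, cap=3000)
    hom = _run_homotypic(*ta, _derived_seed(seed, 301),
                         n0=150, end_time=14.0, cap=3000)
    da, ka = capped_counts(het, "A", event_cap)
    dh, kh = capped_counts(hom, "A", event_cap)
    xi, lam_hat = da / (da + ka), dh / (dh + kh)
    se = math.sqrt(
        xi * (1 - xi) / (da + ka) + lam_hat * (1 - lam_hat) / (dh + kh)
    )
    return {
        "type_a": ta, "type_b": tb,
        "xi_a": xi, "lambda_a_hat": lam_hat,
        "difference": abs(xi - lam_hat),
        "se_difference": se,
        "n_het": da + ka, "n_hom": dh + kh,
    }
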
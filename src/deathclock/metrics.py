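"""Survival frequencies, the viability matrix and cell-competition criteria.

The empirical viability statistic of a simulated population is its
*survival frequency*: divisions / (divisions + deaths) over an event log.
A frequency >= 1/2 means the population grew or held steady (viable); below
1/2 it declined (nonviable).  For a pair of cell types the four frequencies
-- two homotypic, two heterotypic -- place the pair in one cell of a 4x4
*viability matrix*.  The pair is *competitive* exactly when both types are
homotypically viable and precisely one remains heterotypically viable; the
surviving type is the winner.

A significance protocol for competitive classifications is included: four
one-sided exact binomial tests on pooled division/death counts
(winner heterotypically viable, loser heterotypically nonviable, both types
homotypically viable), Bonferroni-corrected.  This protocol is this
package's own specification of the statistical check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .events import EventLog

__all__ = [
    "SurvivalFrequencies",
    "ViabilityOutcome",
    "survival_frequency",
    "classify_viability",
    "tabulate_viability_matrix",
    "matrix_aggregates",
    "significance_test",
]

#: Keys of the four survival frequencies in canonical order.
FREQ_KEYS = ("lambda_a", "lambda_b", "xi_a", "xi_b")


def survival_frequency(
    log: EventLog, type_label: str, t_min: float = -np.inf
) -> Optional[float]:
    """divisions / (divisions + deaths) for one type; None if no events.

    ``t_min`` discards events before a burn-in time (useful when the initial
    condition is far from the stationary cycle-phase distribution).
    """
    div = log.count("division", type_label, t_min)
    death = log.count("death", type_label, t_min)
    if div + death == 0:
        return None
    return div / (div + death)


def event_counts(
    log: EventLog, type_label: str, t_min: float = -np.inf
) -> tuple[int, int]:
    """(divisions, deaths) for one type, after an optional burn-in."""
    return (
        log.count("division", type_label, t_min),
        log.count("death", type_label, t_min),
    )


@dataclass(frozen=True)
class SurvivalFrequencies:
    """The four survival frequencies of a type pair, with backing counts.

    ``lambda_a``/``lambda_b`` come from the two homotypic runs; ``xi_a``/
    ``xi_b`` from the heterotypic run.  ``None`` marks an undefined
    frequency (no division or death events).  ``counts`` maps each key to
    its (divisions, deaths) pair.
    """

    lambda_a: Optional[float]
    lambda_b: Optional[float]
    xi_a: Optional[float]
    xi_b: Optional[float]
    counts: dict = field(default_factory=dict)

    @classmethod
    def from_logs(
        cls,
        homotypic_a: EventLog,
        homotypic_b: EventLog,
        heterotypic: EventLog,
        t_min: float = -np.inf,
    ) -> "SurvivalFrequencies":
        counts = {
            "lambda_a": event_counts(homotypic_a, "A", t_min),
            "lambda_b": event_counts(homotypic_b, "B", t_min),
            "xi_a": event_counts(heterotypic, "A", t_min),
            "xi_b": event_counts(heterotypic, "B", t_min),
        }

        def freq(key: str) -> Optional[float]:
            d, k = counts[key]
            return None if d + k == 0 else d / (d + k)

        return cls(*(freq(k) for k in FREQ_KEYS), counts=counts)

    @classmethod
    def from_values(cls, lambda_a, lambda_b, xi_a, xi_b) -> "SurvivalFrequencies":
        return cls(lambda_a, lambda_b, xi_a, xi_b, counts={})


@dataclass(frozen=True)
class ViabilityOutcome:
    """Viability booleans of a type pair and their viability-matrix cell.

    ``matrix_cell = (row, col)`` indexes the 4x4 grid: columns enumerate the
    homotypic pattern and rows the heterotypic pattern, both ordered
    (B nonviable, A nonviable), (B nonviable, A viable),
    (B viable, A nonviable), (B viable, A viable).
    """

    a_homotypic_viable: bool
    b_homotypic_viable: bool
    a_heterotypic_viable: bool
    b_heterotypic_viable: bool
    matrix_cell: tuple[int, int]
    competitive: bool
    winner: Optional[str]

    def swap_labels(self) -> "ViabilityOutcome":
        """The outcome with cell-type labels A and B exchanged."""
        return classify_viability_bools(
            self.b_homotypic_viable,
            self.a_homotypic_viable,
            self.b_heterotypic_viable,
            self.a_heterotypic_viable,
        )


def _viable(freq: Optional[float]) -> bool:
    # an undefined frequency means the population persisted without any
    # division or death, which counts as "grown or stayed the same"
    if freq is None:
        warnings.warn(
            "undefined survival frequency (no events); treating as viable",
            stacklevel=3,
        )
        return True
    return freq >= 0.5


def classify_viability_bools(
    a_homo: bool, b_homo: bool, a_hetero: bool, b_hetero: bool
) -> ViabilityOutcome:
    """Build a :class:`ViabilityOutcome` from the four viability booleans."""
    col = 2 * int(b_homo) + int(a_homo)
    row = 2 * int(b_hetero) + int(a_hetero)
    competitive = a_homo and b_homo and (a_hetero != b_hetero)
    winner = None
    if competitive:
        winner = "A" if a_hetero else "B"
    return ViabilityOutcome(
        a_homotypic_viable=a_homo,
        b_homotypic_viable=b_homo,
        a_heterotypic_viable=a_hetero,
        b_heterotypic_viable=b_hetero,
        matrix_cell=(row, col),
        competitive=competitive,
        winner=winner,
    )


def classify_viability(freqs: SurvivalFrequencies) -> ViabilityOutcome:
    """Apply the viability threshold (frequency >= 1/2) and the
    cell-competition criteria to a set of survival frequencies."""
    return classify_viability_bools(
        _viable(freqs.lambda_a),
        _viable(freqs.lambda_b),
        _viable(freqs.xi_a),
        _viable(freqs.xi_b),
    )


def tabulate_viability_matrix(
    outcomes: Iterable[ViabilityOutcome],
) -> np.ndarray:
    """4x4 count table of viability outcomes (rows heterotypic, cols homotypic)."""
    table = np.zeros((4, 4), dtype=int)
    for out in outcomes:
        table[out.matrix_cell] += 1
    return table


def matrix_aggregates(table: np.ndarray) -> dict[str, float]:
    """Summary statistics of a viability matrix.

    * ``competitive``: counts in the two competitive cells (last column,
      middle rows -- exactly one type heterotypically viable while both are
      homotypically viable);
    * ``diagonal``: heterotypic pattern identical to homotypic pattern;
    * ``bottom_middle`` / ``top_middle``: the label-swap-equivalent middle
      cells of the bottom and top rows (loser-rescue and mutual-collapse
      outcomes, respectively);
    * ``antidiagonal_bottom_left``: both homotypically nonviable types
      becoming viable together;
    * percentages are relative to the table total.
    """
    table = np.asarray(table)
    total = int(table.sum())
    diagonal = int(np.trace(table))
    competitive = int(table[1, 3] + table[2, 3])
    bottom_middle = int(table[3, 1] + table[3, 2])
    top_middle = int(table[0, 1] + table[0, 2])
    anti_bl = int(table[3, 0])
    pct = lambda x: 100.0 * x / total if total else float("nan")
    return {
        "total": total,
        "competitive": competitive,
        "diagonal": diagonal,
        "bottom_middle": bottom_middle,
        "top_middle": top_middle,
        "antidiagonal_bottom_left": anti_bl,
        "competitive_pct": pct(competitive),
        "diagonal_pct": pct(diagonal),
        "bottom_middle_pct": pct(bottom_middle),
        "top_middle_pct": pct(top_middle),
        "diagonal_plus_bottom_middle_pct": pct(diagonal + bottom_middle),
    }


def _pooled(counts_list: Sequence[dict], key: str) -> tuple[int, int]:
    div = sum(c[key][0] for c in counts_list)
    death = sum(c[key][1] for c in counts_list)
    return div, death


def significance_test(
    replicate_freqs: Sequence[SurvivalFrequencies],
    alpha: float = 0.05,
) -> dict:
    """Exact-binomial significance check of a competitive classification.

    Pools division/death counts over replicates and runs four one-sided
    exact binomial tests against p = 1/2:

    * winner heterotypic frequency: reject "nonviable-or-borderline"
      (alternative: divisions more likely than deaths);
    * loser heterotypic frequency: reject "viable" (alternative: less);
    * each homotypic frequency: reject "nonviable" (alternative: greater).

    The classification is *significant* when all four Bonferroni-corrected
    tests reject at level ``alpha``.  Zero pooled events in any condition
    makes the verdict inconclusive.
    """
    if len(replicate_freqs) < 2:
        return {"significant": False, "inconclusive": True,
                "reason": "need >= 2 replicates", "p_values": {}}
    counts_list = [f.counts for f in replicate_freqs]
    if any(not c for c in counts_list):
        raise ValueError("replicates must carry event counts")
    pooled = {k: _pooled(counts_list, k) for k in FREQ_KEYS}
    if any(d + k == 0 for d, k in pooled.values()):
        return {"significant": False, "inconclusive": True,
                "reason": "zero events in a condition", "p_values": {}}

    # identify winner/loser from pooled heterotypic point estimates
    xi_a = pooled["xi_a"][0] / sum(pooled["xi_a"])
    xi_b = pooled["xi_b"][0] / sum(pooled["xi_b"])
    winner_key, loser_key = ("xi_a", "xi_b") if xi_a >= xi_b else ("xi_b", "xi_a")

    def one_sided(key: str, alternative: str) -> float:
        div, death = pooled[key]
        return binomtest(div, div + death, 0.5, alternative=alternative).pvalue

    p_values = {
        "winner_heterotypic_viable": one_sided(winner_key, "greater"),
        "loser_heterotypic_nonviable": one_sided(loser_key, "less"),
        "a_homotypic_viable": one_sided("lambda_a", "greater"),
        "b_homotypic_viable": one_sided("lambda_b", "greater"),
    }
    corrected = alpha / len(p_values)
    significant = all(p < corrected for p in p_values.values())
    return {
        "significant": significant,
        "inconclusive": False,
        "winner": "A" if winner_key == "xi_a" else "B",
        "p_values": p_values,
        "alpha": alpha,
        "bonferroni_level": corrected,
    }


def write_matrix_report(
    table: np.ndarray, outcomes: Sequence[ViabilityOutcome], out_dir: str | Path
) -> None:
    """Write the viability matrix as CSV plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["xiB<0.5,xiA<0.5", "xiB<0.5,xiA>=0.5", "xiB>=0.5,xiA<0.5", "xiB>=0.5,xiA>=0.5"]
    cols = ["lamB<0.5,lamA<0.5", "lamB<0.5,lamA>=0.5", "lamB>=0.5,lamA<0.5", "lamB>=0.5,lamA>=0.5"]
    pd.DataFrame(table, index=rows, columns=cols).to_csv(out / "viability_matrix.csv")
    summary = matrix_aggregates(table)
    summary["competitive_pairs"] = [
        {"winner": o.winner} for o in outcomes if o.competitive
    ]
    (out / "viability_summary.json").write_text(json.dumps(summary, indent=2))
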
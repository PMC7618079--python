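"""Reference tabulation of the full mechanical-model parameter sweep.

The complete study design evaluates 2 809 OA-LHS parameter sets of the
mechanical model with three vertex simulations each (cluster-scale; 23 sets
errored with too large a timestep and are excluded).  The resulting per-set
viability outcomes, tabulated on the 4x4 viability matrix, are shipped here
as package data so the tabulation and aggregation machinery can be
exercised and checked against the full-scale result without re-running it.

Row/column layout matches :func:`deathclock.metrics.tabulate_viability_matrix`:
columns enumerate the homotypic viability pattern, rows the heterotypic
pattern, both ordered (B nonviable, A nonviable), (B nonviable, A viable),
(B viable, A nonviable), (B viable, A viable).
"""

from __future__ import annotations

import numpy as np

from .metrics import ViabilityOutcome, classify_viability_bools

__all__ = [
    "MECHANICAL_SWEEP_MATRIX",
    "MECHANICAL_SWEEP_TOTAL_SETS",
    "MECHANICAL_SWEEP_ERRORED_SETS",
    "mechanical_sweep_outcomes",
]

MECHANICAL_SWEEP_MATRIX = np.array(
    [
        [305, 17, 11, 0],
        [0, 407, 0, 4],
        [0, 0, 476, 16],
        [4, 105, 128, 1313],
    ],
    dtype=int,
)

MECHANICAL_SWEEP_TOTAL_SETS = 2809
MECHANICAL_SWEEP_ERRORED_SETS = 23


def mechanical_sweep_outcomes() -> list[ViabilityOutcome]:
    """Expand the count matrix into individual viability outcomes.

    Useful for feeding the tabulation machinery end to end: re-tabulating
    the expanded outcomes must reproduce :data:`MECHANICAL_SWEEP_MATRIX`.
    """
    outcomes = []
    for row in range(4):
        for col in range(4):
            a_homo, b_homo = bool(col & 1), bool(col & 2)
            a_het, b_het = bool(row & 1), bool(row & 2)
            out = classify_viability_bools(a_homo, b_homo, a_het, b_het)
            outcomes.extend([out] * int(MECHANICAL_SWEEP_MATRIX[row, col]))
    return outcomes
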
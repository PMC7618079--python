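"""Orthogonal-array Latin hypercube sweeps of the mechanical model.

The mechanical model asks whether differences in mechanical and cell-cycle
parameters alone (passive extrusion as the only death mode) can generate
cell competition.  Its 13-factor parameter space is sampled with a
strength-2 orthogonal-array Latin hypercube (OA-LHS): an OA(q^2, k, q, 2)
built over the prime field GF(q) guarantees that every pair of factors is
stratified on a q x q grid with exactly one run per coarse cell, and the
Latin-hypercube randomisation within array cells refines each single-factor
projection to q^2 equal bins with one run each.  The full study design uses
q = 53, giving 2 809 parameter sets.

Each parameter set is evaluated with three simulations -- two homotypic
(one per cell type) and one heterotypic -- whose survival frequencies feed
the viability matrix.  Runs that fail (e.g. mesh degeneration) are recorded
as errors and excluded, and a targeted retest with replicates applies the
exact-binomial significance protocol to candidate competitive sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DeathClockParams
from .metrics import (
    SurvivalFrequencies,
    ViabilityOutcome,
    classify_viability,
    significance_test,
    tabulate_viability_matrix,
)
from .vertex import MechanicalParams, SimulationError, VertexConfig, run_vertex
from .wellmixed import SimConfig, run_wellmixed

__all__ = [
    "SweepDesign",
    "table1_design",
    "oa_lhs_sample",
    "run_sweep",
    "targeted_retest",
]

#: Sweep bounds of the mechanical model: target areas and elasticities in
#: [0.5, 1.5], contractilities in [0.01, 0.07], line tensions in
#: [0.06, 0.18], G1 means in [0, 60] and G2 durations in [40, 100].
TABLE1_BOUNDS = {
    "target_area_A": (0.5, 1.5),
    "target_area_B": (0.5, 1.5),
    "elasticity_A": (0.5, 1.5),
    "elasticity_B": (0.5, 1.5),
    "contractility_A": (0.01, 0.07),
    "contractility_B": (0.01, 0.07),
    "tension_AA": (0.06, 0.18),
    "tension_AB": (0.06, 0.18),
    "tension_BB": (0.06, 0.18),
    "t_g1_A": (0.0, 60.0),
    "t_g1_B": (0.0, 60.0),
    "t_g2_A": (40.0, 100.0),
    "t_g2_B": (40.0, 100.0),
}


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(math.isqrt(n)) + 1))


@dataclass(frozen=True)
class SweepDesign:
    """Factors with bounds, the number of levels q (prime), and a seed."""

    factors: dict
    levels: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not _is_prime(self.levels):
            raise ValueError(f"levels q = {self.levels} must be prime")
        if len(self.factors) > self.levels + 1:
            raise ValueError(
                f"{len(self.factors)} factors exceed the OA limit q + 1 = "
                f"{self.levels + 1}"
            )
        for name, (lo, hi) in self.factors.items():
            if not lo < hi:
                raise ValueError(f"factor {name!r}: lower bound must be < upper")

    @property
    def n_runs(self) -> int:
        return self.levels**2


def table1_design(levels: int = 53, seed: int = 0) -> SweepDesign:
    """The 13-factor mechanical-model design (q = 53 gives 2 809 sets)."""
    return SweepDesign(factors=dict(TABLE1_BOUNDS), levels=levels, seed=seed)


def _orthogonal_array(q: int, k: int) -> np.ndarray:
    """OA(q^2, k, q, 2) over GF(q): columns i, i+j, i+2j, ..., j."""
    i, j = np.divmod(np.arange(q * q), q)
    cols = []
    for m in range(k):
        if m < q:
            cols.append((i + m * j) % q)
        else:  # the (q+1)-th column
            cols.append(j)
    return np.column_stack(cols)


def oa_lhs_sample(design: SweepDesign) -> pd.DataFrame:
    """q^2 parameter sets: strength-2 OA, LHS-randomised, scaled to bounds.

    Within each column, the q runs sharing an OA level are assigned the q
    sub-bins of that level in random order, then jittered uniformly within
    their bin -- so every 1-D projection hits each of the q^2 equal bins
    exactly once while every 2-D projection retains the one-run-per-cell
    OA property on the coarse q x q grid.
    """
    rng = np.random.default_rng(design.seed)
    q = design.levels
    names = list(design.factors)
    oa = _orthogonal_array(q, len(names))
    n = q * q
    data = {}
    for col, name in enumerate(names):
        levels = oa[:, col]
        u = np.empty(n)
        for level in range(q):
            idx = np.flatnonzero(levels == level)
            ranks = rng.permutation(q)
            u[idx] = (level * q + ranks + rng.random(q)) / (q * q)
        lo, hi = design.factors[name]
        data[name] = lo + (hi - lo) * u
    return pd.DataFrame(data)


def _vertex_params(row: pd.Series) -> tuple[MechanicalParams, dict]:
    mech = MechanicalParams(
        elasticity={"A": row["elasticity_A"], "B": row["elasticity_B"]},
        target_area={"A": row["target_area_A"], "B": row["target_area_B"]},
        contractility={"A": row["contractility_A"], "B": row["contractility_B"]},
        line_tension={
            "AA": row["tension_AA"],
            "AB": row["tension_AB"],
            "BB": row["tension_BB"],
        },
    )
    clock = {
        label: DeathClockParams(
            death_threshold=np.inf,
            signal_strength=0.0,
            g1_mean=row[f"t_g1_{label}"],
            g2_duration=row[f"t_g2_{label}"],
        )
        for label in ("A", "B")
    }
    return mech, clock


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _run_one(
    engine: str,
    row: pd.Series,
    kind: str,  # "homotypic_A" | "homotypic_B" | "heterotypic"
    seed: int,
    end_time: float,
    n_cells: int,
    arrangement: str,
    max_population: int,
):
    if engine == "vertex":
        mech, clock = _vertex_params(row)
        if kind == "homotypic_A":
            arr, label = "homotypic", "A"
        elif kind == "homotypic_B":
            arr, label = "homotypic", "B"
        else:
            arr, label = arrangement, "A"
        cfg = VertexConfig(
            end_time=end_time,
            mech=mech,
            clock_params=clock,
            n_cells=n_cells,
            arrangement=arr,
            homotypic_label=label,
            seed=seed,
            death_clock=False,
            max_population=max_population,
            log_g1_exits=False,
        )
        log, _ = run_vertex(cfg)
        return log
    if engine == "wellmixed":
        _, clock = _vertex_params(row)
        if kind == "homotypic_A":
            counts = {"A": n_cells}
        elif kind == "homotypic_B":
            counts = {"B": n_cells}
        else:
            counts = {"A": n_cells // 2, "B": n_cells - n_cells // 2}
        cfg = SimConfig(
            end_time=end_time,
            initial_counts=counts,
            params=clock,
            seed=seed,
            max_population=max_population,
            log_g1_exits=False,
        )
        return run_wellmixed(cfg)
    raise ValueError(f"unknown engine {engine!r}")


def run_sweep(
    design_points: pd.DataFrame,
    engine: str = "vertex",
    seed: int = 0,
    end_time: float = 250.0,
    n_cells: int = 36,
    arrangement: str = "random",
    max_population: int = 1000,
    subsample: Optional[int] = None,
) -> dict:
    """Evaluate each parameter set with two homotypic + one heterotypic run.

    Per-set seeds derive deterministically from the sweep seed and the set
    index.  Simulation failures are recorded and the sweep continues.
    Returns a dict with per-set ``results`` (index, freqs, outcome or
    error), the 4x4 viability ``matrix`` over non-errored sets, and the
    ``errors`` list.  ``subsample`` runs a seeded subset of the design at
    desk scale.
    """
    points = design_points
    if subsample is not None and subsample < len(points):
        rng = np.random.default_rng(_derived_seed(seed, 987))
        idx = np.sort(rng.choice(len(points), size=subsample, replace=False))
        points = points.iloc[idx]

    results = []
    outcomes: list[ViabilityOutcome] = []
    errors = []
    for set_index, (_, row) in enumerate(points.iterrows()):
        logs = {}
        try:
            for run_idx, kind in enumerate(
                ("homotypic_A", "homotypic_B", "heterotypic")
            ):
                logs[kind] = _run_one(
                    engine, row, kind,
                    seed=_derived_seed(seed, set_index, run_idx),
                    end_time=end_time, n_cells=n_cells,
                    arrangement=arrangement, max_population=max_population,
                )
        except SimulationError as exc:
            errors.append({"set_index": set_index, "error": str(exc)})
            results.append({"set_index": set_index, "error": str(exc)})
            continue
        freqs = SurvivalFrequencies.from_logs(
            logs["homotypic_A"], logs["homotypic_B"], logs["heterotypic"]
        )
        outcome = classify_viability(freqs)
        outcomes.append(outcome)
        results.append(
            {"set_index": set_index, "freqs": freqs, "outcome": outcome}
        )
    return {
        "results": results,
        "outcomes": outcomes,
        "matrix": tabulate_viability_matrix(outcomes),
        "errors": errors,
        "n_evaluated": len(outcomes),
    }


def targeted_retest(
    design_points: pd.DataFrame,
    set_indices: Sequence[int],
    n_replicates: int = 4,
    alpha: float = 0.05,
    initial_condition: str = "random",
    engine: str = "vertex",
    seed: int = 0,
    end_time: float = 250.0,
    n_cells: int = 36,
    max_population: int = 1000,
) -> list[dict]:
    """Replicate candidate competitive sets and test significance.

    For each flagged set, ``n_replicates`` independent triples of
    simulations are run (optionally with segregated initial conditions) and
    the pooled exact-binomial protocol is applied.
    """
    reports = []
    for set_index in set_indices:
        row = design_points.iloc[set_index]
        reps = []
        failed = None
        for rep in range(n_replicates):
            try:
                logs = {
                    kind: _run_one(
                        engine, row, kind,
                        seed=_derived_seed(seed, 7919, set_index, rep, run_idx),
                        end_time=end_time, n_cells=n_cells,
                        arrangement=initial_condition,
                        max_population=max_population,
                    )
                    for run_idx, kind in enumerate(
                        ("homotypic_A", "homotypic_B", "heterotypic")
                    )
                }
            except SimulationError as exc:
                failed = str(exc)
                continue
            reps.append(
                SurvivalFrequencies.from_logs(
                    logs["homotypic_A"], logs["homotypic_B"], logs["heterotypic"]
                )
            )
        verdict = significance_test(reps, alpha=alpha)
        reports.append(
            {
                "set_index": set_index,
                "n_replicates_completed": len(reps),
                "initial_condition": initial_condition,
                "error": failed,
                **verdict,
            }
        )
    return reports
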
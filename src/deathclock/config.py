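"""Run configuration, dimensionless parameter expansion, and fixtures.

Cell types may be specified either dimensionally (``t_g1``, ``t_g2``,
``death_threshold``, ``signal_strength``) or dimensionlessly as
``(beta, eta, t_g)``, which expand as

    t_g1 = beta * t_g,   t_g2 = (1 - beta) * t_g,   T_death = eta * c * t_g

with the signal scale ``c`` defaulting to 1 (only the ratio enters eta, so
c is a free scale).  The two styles are mutually exclusive within one type
spec, and expansion round-trips exactly with nondimensionalisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .core import DeathClockParams
from .events import EventLog

__all__ = [
    "RunConfig",
    "expand_dimensionless",
    "nondimensionalise",
    "fixture_scenarios",
]

DIMENSIONLESS_KEYS = {"beta", "eta", "t_g", "c"}
DIMENSIONAL_KEYS = {"t_g1", "t_g2", "death_threshold", "signal_strength"}


def expand_dimensionless(
    beta: float,
    eta: float,
    t_g: float = 1.0,
    c: float = 1.0,
    g1_distribution: str = "exponential",
) -> DeathClockParams:
    """Dimensional death-clock parameters from (beta, eta, t_g, c)."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if eta <= 0 or t_g <= 0 or c <= 0:
        raise ValueError("eta, t_g and c must be positive")
    return DeathClockParams(
        death_threshold=eta * c * t_g,
        signal_strength=c,
        g1_mean=beta * t_g,
        g2_duration=(1.0 - beta) * t_g,
        g1_distribution=g1_distribution,
    )


def nondimensionalise(params: DeathClockParams) -> tuple[float, float, float]:
    """(beta, eta, t_g) of dimensional parameters; inverse of expansion."""
    t_g = params.cycle_mean
    if t_g <= 0 or params.signal_strength <= 0:
        raise ValueError("nondimensionalisation needs t_g > 0 and c > 0")
    beta = params.g1_mean / t_g
    eta = params.death_threshold / (params.signal_strength * t_g)
    return beta, eta, t_g


def _parse_type(spec: dict) -> DeathClockParams:
    keys = set(spec)
    if keys & DIMENSIONLESS_KEYS and keys & DIMENSIONAL_KEYS:
        raise ValueError(
            "a cell type must be specified either dimensionlessly "
            "(beta, eta, t_g, c) or dimensionally, not both"
        )
    if "beta" in spec:
        return expand_dimensionless(
            spec["beta"],
            spec["eta"],
            spec.get("t_g", 1.0),
            spec.get("c", 1.0),
            spec.get("g1_distribution", "exponential"),
        )
    return DeathClockParams(
        death_threshold=spec["death_threshold"],
        signal_strength=spec.get("signal_strength", 1.0),
        g1_mean=spec["t_g1"],
        g2_duration=spec["t_g2"],
        g1_distribution=spec.get("g1_distribution", "exponential"),
    )


@dataclass
class RunConfig:
    """Engine-agnostic run description, serialisable to YAML/JSON.

    ``cell_types`` maps labels to type specs (dimensionless or
    dimensional); engine-specific fields are ignored by the other engine.
    """

    engine: str  # "wellmixed" | "vertex"
    cell_types: dict
    end_time: float
    seed: int = 0
    initial_counts: Optional[dict] = None  # wellmixed
    n_cells: int = 36  # vertex
    arrangement: str = "homotypic"  # vertex
    dt: float = 0.05  # vertex
    init: str = "newborn"
    max_population: int = 100_000
    out: Optional[str] = None

    def clock_params(self) -> dict:
        return {label: _parse_type(spec) for label, spec in self.cell_types.items()}

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- execution --------------------------------------------------------

    def run(self):
        """Dispatch to the configured engine; returns the event log (and
        the final mesh for the vertex engine)."""
        params = self.clock_params()
        if self.engine == "wellmixed":
            from .wellmixed import SimConfig, run_wellmixed

            counts = self.initial_counts or {
                label: 50 for label in self.cell_types
            }
            cfg = SimConfig(
                end_time=self.end_time,
                initial_counts=counts,
                params=params,
                seed=self.seed,
                max_population=self.max_population,
                init=self.init,
            )
            return run_wellmixed(cfg)
        if self.engine == "vertex":
            from .vertex import MechanicalParams, VertexConfig, run_vertex

            mech = MechanicalParams.uniform(tuple(sorted(self.cell_types)))
            cfg = VertexConfig(
                end_time=self.end_time,
                mech=mech,
                clock_params=params,
                dt=self.dt,
                n_cells=self.n_cells,
                arrangement=self.arrangement,
                seed=self.seed,
                max_population=min(self.max_population, 5000),
                init=self.init,
            )
            return run_vertex(cfg)
        raise ValueError(f"unknown engine {self.engine!r}")


#: Homotypic validation grid: three G1 fractions crossed with three
#: multiples of the viability-curve threshold eta = m ln2 beta (1 - beta),
#: so each beta column straddles the predicted viable/nonviable boundary.
#: Near the boundary the population is quasi-stationary, which is where the
#: ergodic mean-field survival probability is quantitatively reliable;
#: far from it, demographic age-structure effects in growing or declining
#: populations shift survival frequencies by a few percent.
HOMOTYPIC_GRID_BETAS = (0.25, 0.5, 0.75)
HOMOTYPIC_GRID_MULTIPLIERS = (0.9, 1.0, 1.1)

#: The three reference heterotypic cross sections: fixed (beta_B, eta_B).
#: Section I has tolerance eta_B/beta_B > ln 2 (type B can never be
#: eliminated), II is homotypically viable with tolerance below ln 2, III
#: is homotypically nonviable.
CROSS_SECTIONS = {
    "I": (0.2, 0.2),
    "II": (0.8, 0.2),
    "III": (0.4, 0.1),
}

#: Representative (beta_A, eta_A) points per cross section, chosen from the
#: regime diagram so every predicted viability pattern in the section is
#: visited with a clear analytic margin from the regime boundaries.
CROSS_SECTION_POINTS = {
    "I": [(0.3, 0.6), (0.5, 0.2), (0.6, 0.5), (0.5, 0.15)],
    "II": [(0.3, 0.5), (0.25, 0.07), (0.75, 0.5), (0.85, 0.15)],
    "III": [(0.2, 0.5), (0.6, 0.05), (0.75, 0.5), (0.5, 0.3)],
}


def fixture_scenarios(seed: int = 0) -> dict:
    """Ready-to-run named configurations for the standard studies.

    * ``homotypic-grid-*``: well-mixed homotypic runs on a 3x3 (beta, eta)
      grid straddling the viability curve;
    * ``cross-section-{I,II,III}-*``: well-mixed heterotypic runs at
      representative points of the three reference cross sections;
    * ``segregation-{random,segregated}``: the vertex-model spatial-mixing
      comparison at a complete-competition parameter pair;
    * ``sweep-smoke``: placeholder vertex run at mechanical defaults.
    """
    scenarios: dict[str, RunConfig] = {}
    for b in HOMOTYPIC_GRID_BETAS:
        for m in HOMOTYPIC_GRID_MULTIPLIERS:
            e = round(m * math.log(2.0) * b * (1.0 - b), 6)
            scenarios[f"homotypic-grid-b{b}-m{m}"] = RunConfig(
                engine="wellmixed",
                cell_types={"A": {"beta": b, "eta": e, "t_g": 1.0}},
                initial_counts={"A": 150},
                end_time=12.0,
                seed=seed,
                init="staggered",
                max_population=1500,
            )
    for section, (beta_b, eta_b) in CROSS_SECTIONS.items():
        for k, (beta_a, eta_a) in enumerate(CROSS_SECTION_POINTS[section]):
            scenarios[f"cross-section-{section}-{k}"] = RunConfig(
                engine="wellmixed",
                cell_types={
                    "A": {"beta": beta_a, "eta": eta_a, "t_g": 1.0},
                    "B": {"beta": beta_b, "eta": eta_b, "t_g": 1.0},
                },
                initial_counts={"A": 100, "B": 100},
                end_time=30.0,
                seed=seed,
                init="staggered",
                max_population=30_000,
            )
    for arrangement in ("random", "segregated"):
        scenarios[f"segregation-{arrangement}"] = RunConfig(
            engine="vertex",
            cell_types={
                "A": {"beta": 0.2, "eta": 0.4, "t_g": 100.0},
                "B": {"beta": 0.8, "eta": 0.2, "t_g": 100.0},
            },
            n_cells=36,
            arrangement=arrangement,
            end_time=300.0,
            seed=seed,
            max_population=400,
        )
    scenarios["sweep-smoke"] = RunConfig(
        engine="vertex",
        cell_types={
            "A": {"t_g1": 30.0, "t_g2": 70.0, "death_threshold": 1e9,
                  "signal_strength": 0.0},
        },
        n_cells=36,
        arrangement="homotypic",
        end_time=50.0,
        seed=seed,
        max_population=400,
    )
    return scenarios
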
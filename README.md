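# deathclock

Cell competition is the process by which two co-cultured cell types
determine a *winner* and a *loser*: the loser is eliminated by programmed
cell death even though it is perfectly viable on its own. This package is
a framework for studying how winner/loser status *emerges* from cell-level
rules, rather than being assumed. Cells exchange abstract "death signals"
with their neighbours and integrate them into a **death clock**
`dτ/dt = f(t)`; a cell whose clock reaches the threshold `T†` during G1
phase initiates apoptosis, while cells in G2 are committed to division and
impervious. In the **G2 death-signal model**, the signal a cell receives
is proportional to the fraction of its neighbours currently in G2 phase.

The package provides, for computational biologists and modellers:

* an **exact event-driven well-mixed simulator** of the death-clock
  population (piecewise-constant signals, closed-form crossing times);
* a **2D vertex-based epithelium** (area elasticity, perimeter
  contractility, type-dependent line tension; T1/T2 rearrangements,
  division, death-clock apoptosis by target-area collapse);
* the **closed-form theory**: with `β` the G1 fraction of the cycle and
  `η = T†/(c t_G)` the normalised threshold, the homotypic survival
  probability is `λ = 1 − exp(−η/(β(1−β)))`, the viability curve is
  `η = ln2·β(1−β)`, winners are decided by the tolerance ratio `η/β`, and
  the competition regimes reduce to inequality chains between tolerance
  `η̃ = η/(ln2·β)` and emission `d = 1 − β` — e.g. complete cell
  competition is exactly `d_L < η̃_L < d_W < η̃_W`;
* **viability and competition metrics**: survival frequencies
  (divisions/(divisions+deaths)), the 4×4 viability matrix, the cell
  competition criteria, and an exact-binomial significance protocol;
* **orthogonal-array Latin hypercube sweeps** (strength-2, q² runs) of the
  13-parameter mechanical model, with the reference tabulation of the
  full 2 809-set study shipped as package data.

## Worked example

Classify a type pair analytically, then watch the prediction play out in
the well-mixed simulator. Type A tolerates more signal per unit G1 time
than it emits; type B does not:

```bash
deathclock regimes --beta-a 0.2 --eta-a 0.4 --beta-b 0.8 --eta-b 0.2
```

```json
{
  "lambda_a": 0.9179150013761012,
  "lambda_b": 0.71349520313981,
  "interaction": "direct competition",
  "regime": "complete cell competition",
  "winner": "A",
  "loser_eliminated": true,
  "tolerance_a": 2.885390081777927,
  "emission_a": 0.8,
  "tolerance_b": 0.3606737602222409,
  "emission_b": 0.19999999999999996
}
```

Both types are homotypically viable (`λ_A = 0.918`, `λ_B = 0.713`, both
above one half), yet the chain `d_B < η̃_B < d_A < η̃_A`
(0.2 < 0.361 < 0.8 < 2.885) predicts that A completely eliminates B in
co-culture. Simulating a 50:50 mixture:

```python
from deathclock import SimConfig, run_wellmixed, survival_frequency, expand_dimensionless

params = {"A": expand_dimensionless(0.2, 0.4), "B": expand_dimensionless(0.8, 0.2)}
cfg = SimConfig(end_time=25.0, initial_counts={"A": 100, "B": 100},
                params=params, seed=1, init="staggered", max_population=4000)
log = run_wellmixed(cfg)
print("xi_A =", round(survival_frequency(log, "A"), 3),
      " xi_B =", round(survival_frequency(log, "B"), 3),
      " final counts:", log.metadata["final_counts"])
```

```
xi_A = 0.912  xi_B = 0.384  final counts: {'A': 4001, 'B': 0}
```

The winner's heterotypic survival frequency (0.912) sits at its homotypic
value, the loser's (0.384) falls below one half, and the B population is
driven extinct — a competitive outcome under the cell competition
criteria, emerging purely from the two parameter pairs. In the
vertex-based tissue the same pair produces loser elimination only when
the types are spatially mixed; segregated clones behave like homotypic
populations (see `tests/test_vertex.py::TestSegregationEffect`).

Other entry points: `deathclock simulate-wellmixed/simulate-vertex`
(YAML-configured runs writing event-log CSVs), `deathclock cross-section`
(regime-boundary curves), `deathclock sweep` (OA-LHS mechanical sweeps),
`deathclock report` (viability matrix from logs), and
`deathclock fixtures` (the named study configurations).

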
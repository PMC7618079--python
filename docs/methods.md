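# Methods

## The death-clock framework

Each cell runs a two-phase cycle: a stochastic G1 phase of duration
`t* ~ C` with mean `t_G1` (exponential by default; a degenerate "fixed"
family is also supported), followed by a fixed G2 phase of duration `t_G2`
that lumps S, G2 and M together. In parallel, the cell integrates the
non-negative extracellular *death signal* `f(t)` into its death clock,
`dτ/dt = f(t)`, with `τ = 0` at birth. If the clock reaches the death
threshold `T†` while the cell is still in G1, apoptosis is triggered; from
G2 onwards the cell is committed to division and impervious (the clock
keeps integrating but cannot kill, and is discarded at division — both
daughters restart at zero). Reaching the threshold *exactly* counts as
death, so the survival condition is the strict inequality `τ(t*) < T†`;
if threshold crossing and G1 exit coincide, death wins.

For a prescribed signal, survival has the closed form
`θ = Ψ(F⁻¹(T†))`, where `F(t) = ∫₀ᵗ f`, `F⁻¹(τ) = min{t : F(t) = τ}`
(infinite when the level is never reached, in which case `θ = 1`) and `Ψ`
is the CDF of `t*`. Signals are represented exactly as piecewise-constant
functions, because in both simulators the signal changes only at discrete
events; the pseudoinverse and all clock crossings are therefore computed
in closed form with no ODE solver anywhere.

## The G2 death signal and the dimensionless parameters

In the G2 death-signal model a cell's raw signal is the fraction of its
neighbours currently in G2 phase, scaled by a constant `c`:
`f = c · g(t)`. Two dimensionless parameters characterise a cell type with
total cycle time `t_G = t_G1 + t_G2`:

* `β = t_G1 / t_G` — the mean G1 fraction of the cycle, which doubles as
  the complement of the cell's death-signal *emission* `d = 1 − β`;
* `η = T† / (c t_G)` — the normalised death threshold; `η/β` acts as the
  cell's *tolerance* to death signals.

`c` is a free scale absorbed by `η`; configurations default to `c = 1` so
`T† = η t_G`. Under the ergodic approximation (the fraction of cells in
G2 equals the mean cycle fraction `1 − β`; the population-weighted mean
`⟨1 − β⟩` in a two-type mixture) the homotypic survival probability is

    λ(β, η) = 1 − exp(−η / (β(1 − β))),

with viability curve `η = ln 2 · β(1 − β)` (λ = 1/2), heterotypic
instantaneous survival `ξ = 1 − exp(−η/(β⟨1 − β⟩))`, winner determined by
the tolerance ordering `sgn(η_A/β_A − η_B/β_B)`, the loser's asymptotic
survival `ξ∞ = 1 − exp(−η_L/(β_L(1 − β_W)))`, and the full regime
taxonomy (coexistence, complete/critical/incomplete cell competition,
neutral and indirect competition) reducible to inequality chains among
tolerances and emissions — e.g. complete cell competition is exactly
`d_L < η̃_L < d_W < η̃_W` with `η̃ = η/(ln 2 · β)`. The classifiers treat
analytic ties with an absolute tolerance of 1e−12 and refuse pairs with
unequal `t_G` (the winner/loser analysis assumes equal cycle times)
unless explicitly overridden.

## Well-mixed engine

Every cell interacts with every other cell: `g` for a focal cell is the
fraction of *other* cells in G2 (zero for a lone cell — which is why a
homotypic population can never go fully extinct: the last survivor is
immortal). Between discrete events `g` is constant for every cell, so the
engine is event-driven and exact: the next event is the minimum over all
cells of (a) G1 exit at `birth + t*`, (b) division at `birth + t* + t_G2`,
and (c) threshold crossing at `t + (T† − τ)/(c g)`. Ties are processed in
(time, cell id) order with cell ids assigned monotonically at birth, and a
crossing that ties the same cell's G1 exit is a death. All clocks advance
synchronously at each event boundary. Division reuses the mother's slot
for one daughter and appends the other; both start with fresh G1 draws.

Two initial conditions are available: `newborn` (all cells born at t = 0)
and `staggered`, which draws each cell's phase from the stationary
renewal distribution (P(G2) = 1 − β, residual G2 uniform, residual G1
memoryless) with clocks at zero. Staggered initialisation shortens the
composition transient and is used by the validation studies. A population
cap (default 1e5) bounds runaway growth; truncation is flagged in the log
metadata and frequencies are still computed from the logged events.

## Vertex engine

The tissue is a polygonal mesh evolving by overdamped dynamics
`μ dr/dt = F` with `F = −∇E` and

    E = Σ_α K_α/2 (S_α − S⁰_α)² + Σ_α Γ_α/2 L_α² + Σ_edges Λ_ij ℓ_ij.

We implement the force as the *negative* energy gradient: this is the
standard choice for this energy and is required for free relaxation to
approach mechanical equilibrium (the analytic gradient is validated
against central finite differences to relative error < 1e−6 in the test
suite). The line tension is resolved per edge: `Λ_AA`, `Λ_AB`, `Λ_BB` by
the incident cell types, and per-type boundary tensions `Λ_A`, `Λ_B`
defaulting to the same-type pair values. Reference parameterisation:
`K = 1`, `S⁰ = 1`, `Γ = 0.04`, `Λ = 0.12`, `μ = 1`, timestep `dt = 0.05`,
36-cell initial hexagonal patch of unit-area cells.

Integration is explicit Euler with mesh rearrangements after every step:

* **T1 swaps** on interior edges shorter than 0.1. Only the canonical
  configuration is rearranged (both endpoints interior, degree 3, no
  triangular incident cell); the new perpendicular edge has length
  1.05 × threshold so it does not immediately re-trigger, and the
  deterministic cycle-update rule is validated geometrically (a swap that
  would produce a non-positively-oriented polygon is reverted). Short
  boundary edges are left alone.
* **T2 extrusions** remove triangular cells below area 0.001 (and any
  cell with non-positive area). Dying cells are additionally extruded
  once below area 0.1: a contracting cell in a mechanically quiescent
  neighbourhood can otherwise stall at an equilibrium area above the
  strict threshold. A neighbour degenerating below three vertices in the
  collapse is extruded with it.
* **Division** bisects the mother through its centroid at a uniformly
  random orientation (redrawn, up to ten times, if the cut degenerates);
  both cut points are inserted into the adjacent cells, so daughter areas
  sum to the mother's exactly. Daughters inherit the type and start as
  newborns.

Cycle and clock events are checked once per step (the mechanics already
force a fixed step). The local death signal is the fraction of
edge-adjacent, non-dying neighbours in G2. Apoptosis sets the cell's
target area to zero and marks it dying: it stops cycling, dividing and
emitting, but keeps exerting forces until extruded. *Deaths are logged at
the trigger time*; extrusions of non-dying cells (passive, mechanical
deaths — the only death mode of the mechanical model) are logged as
deaths at extrusion time. Tissues with any non-positive cell area after a
step abort with a simulation error, mirroring the timestep-too-large
failure mode; sweep orchestration records such sets and continues.

## Survival frequencies, viability and competition

The empirical viability statistic of a type in a run is
`divisions / (divisions + deaths)`; at least one half means the
population grew or held steady (viable). A type pair is evaluated with
two homotypic runs and one heterotypic run, giving `λ̂_A, λ̂_B, ξ̂_A|B,
ξ̂_B|A`, one cell of the 4×4 viability matrix, and the competition
criteria: *competitive* iff both types are homotypically viable and
exactly one is heterotypically viable. An undefined frequency (no events)
is treated as viable with a warning, since the population persisted
unchanged. Note the two conventions deliberately coexist: empirical
viability uses `frequency ≥ 1/2`, while the analytic regime definitions
use `λ > 1/2` viable / `λ ≤ 1/2` nonviable; each layer documents its own.

Significance of a competitive classification is assessed with a protocol
of this package's own design: replicate triples are pooled and four
one-sided exact binomial tests against p = 1/2 are run (winner
heterotypically viable, loser heterotypically nonviable, both types
homotypically viable), Bonferroni-corrected at α/4. Fewer than two
replicates, or zero events in any condition, is inconclusive.

## OA-LHS parameter sweeps

The 13-factor mechanical sweep design is a strength-2 orthogonal array
`OA(q², k, q, 2)` over GF(q), q prime, with columns `i`, `i + m·j`
(m = 1..q−1) and `j`, supporting up to q + 1 factors. Latin-hypercube
randomisation assigns the q runs within each level to the level's q
sub-bins in seeded random order with uniform jitter, so each 1-D
projection is stratified into q² equal bins with exactly one run each
while every 2-D projection keeps one run per coarse q×q cell. The
full-scale design uses q = 53 (53² = 2 809 parameter sets); desk-scale
runs use a seeded subsample. Each set is evaluated with two homotypic and
one heterotypic simulation; per-set seeds derive deterministically from
the sweep seed and set index.

## Validation studies and their problem sizes

The studies in `deathclock.studies` are sized for a single CPU:

* **Homotypic grid** — β ∈ {0.25, 0.5, 0.75} crossed with
  η = m·ln2·β(1−β), m ∈ {0.9, 1.0, 1.1}; 150 starting cells, staggered
  init, frequencies over the first 600 division/death events per point,
  compared to λ(β, η) at 3 binomial SE.
* **Cross sections** — four representative (β_A, η_A) points in each of
  the three reference cross sections (β_B, η_B) ∈ {(0.2, 0.2),
  (0.8, 0.2), (0.4, 0.1)}, chosen with clear analytic margin from the
  regime boundaries; 100 + 100 starting cells run to t = 30 t_G (capped
  at 4 000 cells), with the empirical viability pattern compared to the
  asymptotic prediction.
* **Coexistence / neutral curves** — equal-tolerance pairs near the
  viability boundary, and an equal-β pair; frequency gaps over the first
  800–2 000 events compared to 3 SE.
* **Vertex checks** — finite-difference force validation, energy descent
  under relaxation, exact area conservation at division, and 36-cell
  homotypic death-clock tissues at a clearly viable and a clearly
  nonviable point run to t = 250 (population cap 250).
* **Sweep smoke** — a seeded 20-set subsample of the q = 53 design run
  with the vertex engine at reduced duration (t = 30), standing in for
  the cluster-scale 2 809 × 3 study.

## Validity of the mean-field comparison

The closed forms rest on the ergodic approximation: a population whose
phase composition matches the stationary renewal distribution of a single
cell's cycle. A *growing* population is young-biased (its G2 fraction
falls below `1 − β`, weakening the signal and inflating survival above
λ), and death in G1 selects for short G1 durations, shifting declining
populations as well. These are genuine properties of the branching
dynamics, not integration error: an independent brute-force fixed-step
simulation reproduces the event-driven engine's frequencies to four
decimals at points where both deviate from λ by several percent. The
deviation vanishes near the viability boundary, where the population is
quasi-stationary — which is why the homotypic grid straddles the
boundary (the theory's central, falsifiable claim is the boundary's
location) and why frequency comparisons are made at event counts
(≈ 500–2 000) where binomial sampling error dominates the residual
few-percent mean-field bias. Far from the boundary the theory remains
qualitatively correct (viable/nonviable sides, regime structure) and all
regime-classification studies use points with clear analytic margins.

What the synthetic populations do *not* emulate: real tissues have
heritable cycle-length variation, mechanical feedback on cycle
progression, and death signals with biochemical identity and diffusion;
passing these studies shows the implementation realises this model
faithfully, not that the model describes any particular tissue.

## Other numerical choices

* Exponential G1 is assumed by all closed forms; the generic Ψ-based
  forms accept the fixed family as well, whose CDF uses the strict step
  `1{t_G1 < t}` to match the strict survival condition.
* Simultaneous well-mixed events are ordered by (time, cell id); clock
  headroom is clamped at zero so floating-point drift a few ulp past the
  threshold kills a cell "now", never in the past.
* The well-mixed engine stores explicit next-transition times per cell,
  decoupling phase scheduling from birth times so staggered starts are
  expressible.
* Hexagonal patches are built for any n that tiles as r×r or r×(r+1);
  the segregated arrangement splits the patch by centroid abscissa into
  two contiguous halves (18 + 18 at the default 36).
* Event logs are CSV (`time,event,cell_id,cell_type`) with kinds
  `division, death, g1exit, t1swap, t2swap`; configs are YAML with
  explicit seeds; all randomness flows through `numpy.random.Generator`
  seeded from run configs.

## Known limitations

* Boundary T1 swaps and vertices of degree > 3 are not rearranged; very
  contorted boundaries can therefore retain short edges.
* The vertex engine's survival frequencies sit a few percent below the
  well-mixed ones at the same (β, η) because passive extrusion adds a
  death channel the mean-field theory ignores.
* The well-mixed engine's per-event cost grows with the total number of
  cells ever created (slots are never recycled), so very long runs at
  large caps are quadratic-ish; the validation studies stay well below
  that regime.
* `significance_test` is a stand-in protocol: the original study's exact
  replicate structure is not public, so counts, replicate numbers and the
  correction are configurable.
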
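"""Vertex model: energetics, forces, rearrangements, cycle, death clock."""

import math

import numpy as np
import pytest

from deathclock.core import DeathClockParams
from deathclock.config import expand_dimensionless
from deathclock.metrics import survival_frequency
from deathclock.theory import DimensionlessType, homotypic_lambda
from deathclock.vertex import (
    MechanicalParams,
    VertexConfig,
    VertexMesh,
    advance,
    divide_cell,
    energy,
    init_tissue,
    local_g2_fraction,
    run_vertex,
    trigger_apoptosis,
    vertex_forces,
)
from deathclock.vertex import _Cell


def hexagon_mesh(side=1.0, label="A", target_area=1.0):
    pts = np.array([
        [side * math.cos(math.pi / 6 + k * math.pi / 3),
         side * math.sin(math.pi / 6 + k * math.pi / 3)]
        for k in range(6)
    ])
    cell = _Cell(vertices=list(range(6)), type_label=label, cell_id=0,
                 target_area=target_area)
    return VertexMesh(pts, [cell])


def clock(beta, eta, t_g=100.0):
    return expand_dimensionless(beta, eta, t_g=t_g)


class TestEnergy:
    def test_regular_hexagon_value(self):
        # K/2 (S - 1)^2 + Gamma/2 L^2 + Lambda L with S = 3 sqrt(3)/2, L = 6
        mech = MechanicalParams.uniform(("A",))
        e = energy(hexagon_mesh(), mech)
        expected = 0.5 * (3 * math.sqrt(3) / 2 - 1) ** 2 + 0.02 * 36 + 0.12 * 6
        assert e == pytest.approx(expected, rel=1e-12)

    def test_zero_energy_configuration(self):
        side = math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))  # unit-area hexagon
        mech = MechanicalParams.uniform(("A",), contractility=0.0, line_tension=0.0)
        assert energy(hexagon_mesh(side=side), mech) == pytest.approx(0.0, abs=1e-12)

    def test_heterotypic_edge_uses_ab_tension(self, rng):
        mesh = init_tissue(36, "segregated", rng)
        mech_lo = MechanicalParams.uniform(("A", "B"))
        tensions = dict(mech_lo.line_tension)
        tensions["AB"] = 0.5
        mech_hi = MechanicalParams(
            elasticity=mech_lo.elasticity, target_area=mech_lo.target_area,
            contractility=mech_lo.contractility, line_tension=tensions,
        )
        # only the A-B interface length times the tension change differs
        interface = 0.0
        for a, b, cs in mesh.unique_edges():
            if len(cs) == 2:
                t1, t2 = mesh.cells[cs[0]].type_label, mesh.cells[cs[1]].type_label
                if t1 != t2:
                    interface += np.linalg.norm(mesh.points[a] - mesh.points[b])
        assert interface > 0
        diff = energy(mesh, mech_hi) - energy(mesh, mech_lo)
        assert diff == pytest.approx((0.5 - 0.12) * interface, rel=1e-10)

    def test_degenerate_polygon_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        mesh = VertexMesh(pts, [_Cell(vertices=[0, 1], type_label="A", cell_id=0)])
        with pytest.raises(Exception):
            energy(mesh, MechanicalParams.uniform(("A",)))


class TestForces:
    def test_matches_finite_differences(self, rng):
        mesh = init_tissue(36, "random", rng)
        mesh.points += rng.normal(0.0, 0.05, mesh.points.shape)
        mech = MechanicalParams.uniform(("A", "B"))
        forces = vertex_forces(mesh, mech)
        h = 1e-5
        for vi in rng.choice(len(mesh.points), 25, replace=False):
            for d in range(2):
                orig = mesh.points[vi, d]
                mesh.points[vi, d] = orig + h
                e_plus = energy(mesh, mech)
                mesh.points[vi, d] = orig - h
                e_minus = energy(mesh, mech)
                mesh.points[vi, d] = orig
                fd = -(e_plus - e_minus) / (2 * h)
                assert abs(fd - forces[vi, d]) / max(abs(fd), 1e-6) < 1e-6

    def test_interior_vertex_balanced_by_symmetry(self, rng):
        mesh = init_tissue(36, "homotypic", rng)
        mech = MechanicalParams.uniform(("A",))
        forces = vertex_forces(mesh, mech)
        # interior vertices (3 incident cells) sit in a symmetric
        # neighbourhood of the regular lattice: net force cancels
        counts = np.zeros(len(mesh.points), dtype=int)
        for cell in mesh.cells:
            counts[cell.vertices] += 1
        interior = counts == 3
        assert interior.sum() > 10
        assert np.abs(forces[interior]).max() < 1e-10

    def test_pure_line_tension_force_is_sum_of_unit_vectors(self):
        lam = 0.3
        mech = MechanicalParams.uniform(("A",), elasticity=1e-12,
                                        contractility=0.0, line_tension=lam)
        mesh = hexagon_mesh()
        forces = vertex_forces(mesh, mech)
        # for an isolated hexagon each vertex has two incident edges
        for j in range(6):
            p = mesh.points[j]
            nbrs = [mesh.points[(j + 1) % 6], mesh.points[(j - 1) % 6]]
            expected = sum(
                lam * (q - p) / np.linalg.norm(q - p) for q in nbrs
            )
            assert np.allclose(forces[j], expected, atol=1e-10)


class TestRelaxation:
    def test_energy_nonincreasing_from_perturbed_lattice(self, rng):
        mesh = init_tissue(36, "homotypic", rng)
        mesh.points += rng.normal(0.0, 0.08, mesh.points.shape)
        mech = MechanicalParams.uniform(("A",))
        energies = []
        for k in range(300):
            energies.append(energy(mesh, mech))
            advance(mesh, mech, 0.05, rng, time=0.05 * k)
        energies = np.array(energies)
        assert np.all(np.diff(energies) <= 1e-9)

    def test_zero_force_mesh_unchanged(self, rng):
        side = math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))
        mech = MechanicalParams.uniform(("A",), contractility=0.0, line_tension=0.0)
        mesh = hexagon_mesh(side=side)
        before = mesh.points.copy()
        advance(mesh, mech, 0.05, np.random.default_rng(0))
        assert np.allclose(mesh.points, before, atol=1e-12)


class TestTopology:
    def test_t1_and_t2_keep_mesh_valid_through_a_busy_run(self):
        p = clock(0.5, 0.1)  # nonviable: lots of deaths and extrusions
        mech = MechanicalParams.uniform(("A",))
        cfg = VertexConfig(end_time=150.0, mech=mech, clock_params={"A": p},
                           seed=21, arrangement="homotypic", max_population=300)
        log, mesh = run_vertex(cfg)
        assert log.count("t2swap") > 0
        for a, b, cs in mesh.unique_edges():
            assert 1 <= len(cs) <= 2
        for cell in mesh.cells:
            assert len(cell.vertices) >= 3
            assert len(set(cell.vertices)) == len(cell.vertices)

    def test_t1_logged_during_remodelling(self):
        p = clock(0.5, 0.1)
        mech = MechanicalParams.uniform(("A",))
        cfg = VertexConfig(end_time=150.0, mech=mech, clock_params={"A": p},
                           seed=21, arrangement="homotypic", max_population=300)
        log, _ = run_vertex(cfg)
        assert log.count("t1swap") > 0


class TestDivision:
    def test_area_conserved_exactly(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=30, g2_duration=70)
        mesh = init_tissue(36, "homotypic", rng, clock_params={"A": p})
        before = mesh.cell_area(14)
        n = len(mesh.cells)
        d1, d2 = divide_cell(mesh, 14, rng)
        assert mesh.cell_area(d1) + mesh.cell_area(d2) == pytest.approx(
            before, abs=1e-12
        )
        assert len(mesh.cells) == n + 1

    def test_daughters_inherit_type_and_reset_clock(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=30, g2_duration=70)
        mesh = init_tissue(36, "random", rng, clock_params={"A": p, "B": p})
        ci = next(i for i, c in enumerate(mesh.cells) if c.type_label == "B")
        mesh.cells[ci].record.clock = 0.7
        d1, d2 = divide_cell(mesh, ci, rng, time=12.0)
        for di in (d1, d2):
            cell = mesh.cells[di]
            assert cell.type_label == "B"
            assert cell.record.clock == 0.0
            assert cell.record.birth_time == 12.0
            assert cell.record.phase == "G1"


class TestApoptosis:
    def test_dying_cell_shrinks_until_extruded(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=1e9, g2_duration=70)
        mesh = init_tissue(36, "homotypic", rng, clock_params={"A": p})
        victim = 14
        victim_id = mesh.cells[victim].cell_id
        trigger_apoptosis(mesh, victim)
        assert mesh.cells[victim].target_area == 0.0
        mech = MechanicalParams.uniform(("A",))
        areas = []
        for k in range(2000):
            idx = next(
                (i for i, c in enumerate(mesh.cells) if c.cell_id == victim_id),
                None,
            )
            if idx is None:
                break
            areas.append(mesh.cell_area(idx))
            advance(mesh, mech, 0.05, rng, time=0.05 * k, death_clock=False)
        assert idx is None, "dying cell was never extruded"
        drops = np.diff(areas)
        # overwhelmingly monotone contraction (small T1 jumps allowed)
        assert (drops < 1e-6).mean() > 0.95
        assert areas[-1] < 0.15 < areas[0]

    def test_dying_cell_never_divides_or_emits(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=0.01, g2_duration=0.01)
        mesh = init_tissue(36, "homotypic", rng, clock_params={"A": p})
        trigger_apoptosis(mesh, 10)
        mesh.cells[10].record.phase = "G2"
        # dying neighbour is excluded from its neighbours' G2 fractions
        for cj in mesh.neighbours(10):
            assert local_g2_fraction(mesh, cj) == 0.0

    def test_death_logged_at_trigger_time_not_extrusion(self):
        p = clock(0.5, 0.05)  # aggressively lethal
        mech = MechanicalParams.uniform(("A",))
        cfg = VertexConfig(end_time=100.0, mech=mech, clock_params={"A": p},
                           seed=5, arrangement="homotypic", max_population=100)
        log, _ = run_vertex(cfg)
        frame = log.to_frame()
        deaths = frame[frame.event == "death"]
        swaps = frame[frame.event == "t2swap"]
        assert len(deaths) > 0
        both = set(deaths.cell_id) & set(swaps.cell_id)
        assert both, "expected extrusions of clock-triggered deaths"
        for cid in both:
            t_death = deaths[deaths.cell_id == cid].time.min()
            t_swap = swaps[swaps.cell_id == cid].time.min()
            assert t_death <= t_swap


class TestLocalSignal:
    def test_interior_cell_fraction(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=30, g2_duration=70)
        mesh = init_tissue(36, "homotypic", rng, clock_params={"A": p})
        interior = max(range(len(mesh.cells)),
                       key=lambda i: len(mesh.neighbours(i)))
        nbrs = mesh.neighbours(interior)
        assert len(nbrs) == 6
        for cj in nbrs[:3]:
            mesh.cells[cj].record.phase = "G2"
        assert local_g2_fraction(mesh, interior) == pytest.approx(0.5)

    def test_boundary_cell_counts_existing_neighbours_only(self, rng):
        p = DeathClockParams(death_threshold=1.0, g1_mean=30, g2_duration=70)
        mesh = init_tissue(36, "homotypic", rng, clock_params={"A": p})
        corner = min(range(len(mesh.cells)),
                     key=lambda i: len(mesh.neighbours(i)))
        nbrs = mesh.neighbours(corner)
        assert len(nbrs) < 6
        for cj in nbrs:
            mesh.cells[cj].record.phase = "G2"
        assert local_g2_fraction(mesh, corner) == 1.0


class TestInitTissue:
    def test_random_split_is_exactly_half(self, rng):
        mesh = init_tissue(36, "random", rng)
        labels = [c.type_label for c in mesh.cells]
        assert labels.count("A") == 18 and labels.count("B") == 18

    def test_homotypic_has_no_heterotypic_edges(self, rng):
        mesh = init_tissue(36, "homotypic", rng)
        assert all(c.type_label == "A" for c in mesh.cells)

    def test_segregated_single_interface(self, rng):
        mesh = init_tissue(36, "segregated", rng)
        hetero = 0
        for a, b, cs in mesh.unique_edges():
            if len(cs) == 2:
                if mesh.cells[cs[0]].type_label != mesh.cells[cs[1]].type_label:
                    hetero += 1
        # one straight interface through a 6x6 patch: far fewer heterotypic
        # edges than a random split would produce (~45)
        assert 0 < hetero <= 14

    def test_unsupported_count_rejected(self, rng):
        with pytest.raises(ValueError):
            init_tissue(37, "random", rng)


class TestViabilitySides:
    @pytest.mark.parametrize(
        "beta,eta,side", [(0.5, 0.5, "viable"), (0.5, 0.08, "nonviable")]
    )
    def test_homotypic_run_lands_on_predicted_side(self, beta, eta, side):
        lam = homotypic_lambda(DimensionlessType(beta, eta))
        p = clock(beta, eta)
        mech = MechanicalParams.uniform(("A",))
        cfg = VertexConfig(end_time=250.0, mech=mech, clock_params={"A": p},
                           seed=13, arrangement="homotypic", max_population=250)
        log, _ = run_vertex(cfg)
        freq = survival_frequency(log, "A")
        if side == "viable":
            assert lam > 0.5 and freq >= 0.5
        else:
            assert lam < 0.5 and freq < 0.5


class TestSegregationEffect:
    def test_segregated_types_behave_homotypically(self):
        """At a complete-competition parameter pair, random mixing
        eliminates the loser while a segregated tissue keeps the loser's
        survival frequency close to its own vertex homotypic value: the
        heterotypic interaction only acts at the clone interface."""
        pair = {"A": clock(0.2, 0.4), "B": clock(0.8, 0.2)}
        mech = MechanicalParams.uniform(("A", "B"))
        freqs = {}
        for arrangement in ("random", "segregated"):
            cfg = VertexConfig(end_time=300.0, mech=mech, clock_params=pair,
                               seed=7, arrangement=arrangement,
                               max_population=400)
            log, _ = run_vertex(cfg)
            freqs[arrangement] = survival_frequency(log, "B")
        cfg = VertexConfig(end_time=300.0, mech=mech, clock_params=pair,
                           seed=7, arrangement="homotypic",
                           homotypic_label="B", max_population=400)
        log, _ = run_vertex(cfg)
        homotypic_b = survival_frequency(log, "B")
        assert freqs["random"] < 0.5  # loser eliminated under mixing
        assert homotypic_b >= 0.5  # homotypically viable
        # segregation shields the loser: its frequency sits much nearer the
        # homotypic value than the randomly mixed one does
        assert abs(freqs["segregated"] - homotypic_b) < abs(
            freqs["random"] - homotypic_b
        )
        assert freqs["segregated"] > freqs["random"]
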
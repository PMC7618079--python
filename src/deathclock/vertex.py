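"""2D vertex model of an epithelium with the death-clock extension.

The tissue is a polygonal mesh; each polygon is a cell.  Vertices move by
overdamped dynamics ``mu dr/dt = F`` with ``F = -grad E`` and the standard
area-elasticity / perimeter-contractility / line-tension energy

    E = sum_cells K/2 (S - S0)^2 + sum_cells Gamma/2 L^2 + sum_edges Lam * l

where the line tension of an edge depends on the types of the two cells it
separates (heterotypic edges get their own value, boundary edges a per-type
value).  Mesh rearrangements keep the tiling valid as cells move, divide
and die: T1 swaps exchange neighbours across edges that become too short,
and T2 swaps extrude cells whose area collapses.

Cells run the two-phase cycle (exponential G1, fixed G2) and, when the
death clock is active, integrate the local G2 death signal: the fraction of
edge-adjacent neighbours in G2 phase.  A clock reaching its threshold in G1
marks the cell as dying -- its target area is set to zero so it contracts
until a T2 swap removes it.  Deaths are logged at the trigger time;
extrusions of cells that were *not* dying (passive, mechanical deaths) are
logged as deaths at extrusion time.

Integration is explicit Euler with a fixed step (default 0.05); cycle and
clock events are checked once per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import CellRecord, DeathClockParams, sample_g1
from .events import EventLog

__all__ = [
    "MechanicalParams",
    "VertexMesh",
    "VertexConfig",
    "SimulationError",
    "energy",
    "vertex_forces",
    "advance",
    "divide_cell",
    "trigger_apoptosis",
    "local_g2_fraction",
    "init_tissue",
    "run_vertex",
]


class SimulationError(RuntimeError):
    """The mesh became invalid (typically: timestep too large)."""


@dataclass(frozen=True)
class MechanicalParams:
    """Per-type mechanics plus rearrangement thresholds.

    ``line_tension`` is keyed by unordered type pairs ("AA", "AB", "BB");
    ``boundary_tension`` by type, defaulting to the same-type pair value.
    Defaults follow the reference parameterisation of the mechanical model
    (K = 1, S0 = 1, Gamma = 0.04, Lambda = 0.12, timestep 0.05, T1
    threshold 0.1).
    """

    elasticity: Mapping[str, float]
    target_area: Mapping[str, float]
    contractility: Mapping[str, float]
    line_tension: Mapping[str, float]
    boundary_tension: Optional[Mapping[str, float]] = None
    friction: float = 1.0
    t1_threshold: float = 0.1
    t1_new_length_factor: float = 1.05
    t2_area_threshold: float = 0.001
    #: dying cells extrude once below this area: their contraction can
    #: stall above the strict threshold when the neighbourhood is static
    t2_dying_area_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.t1_threshold <= 0 or self.t2_area_threshold <= 0:
            raise ValueError("rearrangement thresholds must be positive")

    @classmethod
    def uniform(
        cls,
        types: Sequence[str] = ("A", "B"),
        elasticity: float = 1.0,
        target_area: float = 1.0,
        contractility: float = 0.04,
        line_tension: float = 0.12,
        **kwargs,
    ) -> "MechanicalParams":
        pairs = {}
        for i, a in enumerate(types):
            for b in types[i:]:
                pairs["".join(sorted(a + b))] = line_tension
        return cls(
            elasticity={t: elasticity for t in types},
            target_area={t: target_area for t in types},
            contractility={t: contractility for t in types},
            line_tension=pairs,
            **kwargs,
        )

    def edge_tension(self, type_a: str, type_b: Optional[str]) -> float:
        if type_b is None:
            if self.boundary_tension and type_a in self.boundary_tension:
                return self.boundary_tension[type_a]
            type_b = type_a
        return self.line_tension["".join(sorted(type_a + type_b))]


@dataclass
class _Cell:
    """Internal per-cell bookkeeping of the mesh."""

    vertices: list  # vertex indices, counter-clockwise
    type_label: str
    cell_id: int
    record: Optional[CellRecord] = None
    target_area: float = 1.0
    dying: bool = False


class VertexMesh:
    """Polygonal tiling with per-cell state.

    ``points`` is the (n_vertices, 2) coordinate array; ``cells`` the list
    of living cells, each an ordered counter-clockwise vertex cycle.
    Derived flat index arrays (for vectorised geometry) and the edge table
    are cached and rebuilt lazily after any topology change.
    """

    def __init__(self, points: np.ndarray, cells: list):
        self.points = np.asarray(points, dtype=float)
        self.cells: list[_Cell] = cells
        self.next_cell_id = max((c.cell_id for c in cells), default=-1) + 1
        self._dirty = True

    def invalidate(self) -> None:
        self._dirty = True

    # -- cached topology --------------------------------------------------

    def _rebuild(self) -> None:
        fv, fnext, fprev, fcell = [], [], [], []
        for ci, cell in enumerate(self.cells):
            vs = cell.vertices
            k = len(vs)
            if k < 3:
                raise SimulationError(f"cell {cell.cell_id} degenerated (<3 vertices)")
            for j in range(k):
                fv.append(vs[j])
                fnext.append(vs[(j + 1) % k])
                fprev.append(vs[(j - 1) % k])
                fcell.append(ci)
        self._fv = np.array(fv, dtype=np.int64)
        self._fnext = np.array(fnext, dtype=np.int64)
        self._fprev = np.array(fprev, dtype=np.int64)
        self._fcell = np.array(fcell, dtype=np.int64)
        # edge table: unordered vertex pair -> incident cell indices
        edges: dict = {}
        for ci, cell in enumerate(self.cells):
            vs = cell.vertices
            for j in range(len(vs)):
                key = (vs[j], vs[(j + 1) % len(vs)])
                key = (min(key), max(key))
                edges.setdefault(key, []).append(ci)
        self._edges = edges
        self._dirty = False

    def _ensure(self) -> None:
        if self._dirty:
            self._rebuild()

    @property
    def edge_table(self) -> dict:
        self._ensure()
        return self._edges

    # -- geometry ---------------------------------------------------------

    def areas(self) -> np.ndarray:
        """Signed (shoelace) areas; positive for valid ccw cells."""
        self._ensure()
        p = self.points[self._fv]
        q = self.points[self._fnext]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        return 0.5 * np.bincount(self._fcell, cross, minlength=len(self.cells))

    def perimeters(self) -> np.ndarray:
        self._ensure()
        seg = np.linalg.norm(self.points[self._fnext] - self.points[self._fv], axis=1)
        return np.bincount(self._fcell, seg, minlength=len(self.cells))

    def cell_area(self, ci: int) -> float:
        vs = self.cells[ci].vertices
        p = self.points[vs]
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def cell_centroid(self, ci: int) -> np.ndarray:
        vs = self.cells[ci].vertices
        p = self.points[vs]
        x, y = p[:, 0], p[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        if abs(a) < 1e-14:
            return p.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def neighbours(self, ci: int) -> list:
        """Indices of cells sharing an edge with cell ``ci``."""
        self._ensure()
        vs = self.cells[ci].vertices
        out = set()
        for j in range(len(vs)):
            key = (vs[j], vs[(j + 1) % len(vs)])
            key = (min(key), max(key))
            for other in self._edges[key]:
                if other != ci:
                    out.add(other)
        return sorted(out)

    def unique_edges(self) -> list:
        """[(a, b, incident cell indices)] over unordered edges."""
        self._ensure()
        return [(a, b, cells) for (a, b), cells in self._edges.items()]


# -- energy and forces -----------------------------------------------------


def _edge_tensions(mesh: VertexMesh, params: MechanicalParams):
    """Arrays (a, b, tension) over unique edges."""
    rows = mesh.unique_edges()
    a = np.array([r[0] for r in rows], dtype=np.int64)
    b = np.array([r[1] for r in rows], dtype=np.int64)
    lam = np.empty(len(rows))
    for k, (_, _, cs) in enumerate(rows):
        t1 = mesh.cells[cs[0]].type_label
        t2 = mesh.cells[cs[1]].type_label if len(cs) > 1 else None
        lam[k] = params.edge_tension(t1, t2)
    return a, b, lam


def energy(mesh: VertexMesh, params: MechanicalParams) -> float:
    """Total tissue energy (elastic + contractile + line tension)."""
    areas = mesh.areas()
    perims = mesh.perimeters()
    k_arr = np.array([params.elasticity[c.type_label] for c in mesh.cells])
    s0_arr = np.array([c.target_area for c in mesh.cells])
    g_arr = np.array([params.contractility[c.type_label] for c in mesh.cells])
    e = float(np.sum(0.5 * k_arr * (areas - s0_arr) ** 2))
    e += float(np.sum(0.5 * g_arr * perims**2))
    a, b, lam = _edge_tensions(mesh, params)
    lengths = np.linalg.norm(mesh.points[a] - mesh.points[b], axis=1)
    e += float(np.sum(lam * lengths))
    return e


def vertex_forces(mesh: VertexMesh, params: MechanicalParams) -> np.ndarray:
    """Analytic force -grad E on every vertex, shape (n_vertices, 2).

    The negative gradient drives free relaxation downhill in energy; the
    analytic expression is validated against finite differences in the test
    suite.
    """
    mesh._ensure()
    n_pts = len(mesh.points)
    grad = np.zeros((n_pts, 2))

    areas = mesh.areas()
    perims = mesh.perimeters()
    k_arr = np.array([params.elasticity[c.type_label] for c in mesh.cells])
    s0_arr = np.array([c.target_area for c in mesh.cells])
    g_arr = np.array([params.contractility[c.type_label] for c in mesh.cells])

    fv, fnext, fprev, fcell = mesh._fv, mesh._fnext, mesh._fprev, mesh._fcell
    pv = mesh.points[fv]
    pn = mesh.points[fnext]
    pp = mesh.points[fprev]

    # elastic: dS/dr_v = 0.5 * (y_next - y_prev, x_prev - x_next)
    ds = 0.5 * np.column_stack([pn[:, 1] - pp[:, 1], pp[:, 0] - pn[:, 0]])
    coef = (k_arr * (areas - s0_arr))[fcell]
    np.add.at(grad, fv, coef[:, None] * ds)

    # contractile: dL/dr_v = unit(v - prev) + unit(v - next)
    d_prev = pv - pp
    d_next = pv - pn
    l_prev = np.linalg.norm(d_prev, axis=1)
    l_next = np.linalg.norm(d_next, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_prev = np.where(l_prev[:, None] > 0, d_prev / l_prev[:, None], 0.0)
        u_next = np.where(l_next[:, None] > 0, d_next / l_next[:, None], 0.0)
    coef_l = (g_arr * perims)[fcell]
    np.add.at(grad, fv, coef_l[:, None] * (u_prev + u_next))

    # line tension per unique edge
    a, b, lam = _edge_tensions(mesh, params)
    d = mesh.points[a] - mesh.points[b]
    lengths = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(lengths[:, None] > 0, d / lengths[:, None], 0.0)
    np.add.at(grad, a, lam[:, None] * unit)
    np.add.at(grad, b, -lam[:, None] * unit)

    return -grad


# -- mesh rearrangements ----------------------------------------------------


def _remove_vertex(cycle: list, v: int) -> list:
    return [x for x in cycle if x != v]


def _has_directed_edge(cell: _Cell, u: int, v: int) -> bool:
    vs = cell.vertices
    k = len(vs)
    return any(vs[j] == u and vs[(j + 1) % k] == v for j in range(k))


def _t1_swap(mesh: VertexMesh, a: int, b: int, params: MechanicalParams) -> bool:
    """Attempt a T1 swap on interior edge (a, b); returns True on success.

    Let X be the cell whose ccw cycle contains the directed edge a->b and Y
    the cell containing b->a; P and Q are the third cells at vertices a and
    b, respectively.  After the swap X and Y lose the edge (X keeps a, Y
    keeps b) while P and Q gain it: in P's cycle, a's slot becomes [b, a];
    in Q's cycle, b's slot becomes [a, b].  These orders follow from which
    pre-swap edges survive at each vertex and keep every cycle ccw.  The
    new edge is perpendicular to the old one, of length
    ``t1_new_length_factor * t1_threshold``, with a displaced toward X and
    b toward Y.  Swaps at the tissue boundary, at vertices of degree other
    than 3, or adjacent to triangular cells are skipped.
    """
    edge_cells = mesh.edge_table.get((min(a, b), max(a, b)), [])
    if len(edge_cells) != 2:
        return False
    if _has_directed_edge(mesh.cells[edge_cells[0]], a, b):
        xi, yi = edge_cells
    else:
        xi, yi = edge_cells[1], edge_cells[0]
    if len(mesh.cells[xi].vertices) <= 3 or len(mesh.cells[yi].vertices) <= 3:
        return False
    cells_with_a = [ci for ci, c in enumerate(mesh.cells) if a in c.vertices]
    cells_with_b = [ci for ci, c in enumerate(mesh.cells) if b in c.vertices]
    # only the canonical interior degree-3 configuration is rearranged
    if len(cells_with_a) != 3 or len(cells_with_b) != 3:
        return False
    p_idx = next(ci for ci in cells_with_a if ci not in (xi, yi))
    q_idx = next(ci for ci in cells_with_b if ci not in (xi, yi))
    if p_idx == q_idx:
        return False

    old_points = mesh.points[[a, b]].copy()
    old_cycles = {ci: list(mesh.cells[ci].vertices) for ci in (xi, yi, p_idx, q_idx)}

    mid = 0.5 * (mesh.points[a] + mesh.points[b])
    tangent = mesh.points[b] - mesh.points[a]
    norm = float(np.linalg.norm(tangent))
    perp = (
        np.array([-tangent[1], tangent[0]]) / norm
        if norm > 0
        else np.array([1.0, 0.0])
    )
    # a stays with X: displace it toward X's interior
    if np.dot(perp, mesh.cell_centroid(xi) - mid) < 0:
        perp = -perp
    half = 0.5 * params.t1_new_length_factor * params.t1_threshold
    mesh.points[a] = mid + half * perp
    mesh.points[b] = mid - half * perp

    mesh.cells[xi].vertices = _remove_vertex(old_cycles[xi], b)
    mesh.cells[yi].vertices = _remove_vertex(old_cycles[yi], a)
    pc = list(old_cycles[p_idx])
    j = pc.index(a)
    pc[j : j + 1] = [b, a]
    mesh.cells[p_idx].vertices = pc
    qc = list(old_cycles[q_idx])
    j = qc.index(b)
    qc[j : j + 1] = [a, b]
    mesh.cells[q_idx].vertices = qc
    mesh.invalidate()

    ok = all(
        mesh.cell_area(ci) > 0
        and len(set(mesh.cells[ci].vertices)) == len(mesh.cells[ci].vertices)
        for ci in (xi, yi, p_idx, q_idx)
    )
    if ok:
        return True
    # geometric validation failed: revert and leave the edge alone
    mesh.points[a], mesh.points[b] = old_points
    for ci, cyc in old_cycles.items():
        mesh.cells[ci].vertices = cyc
    mesh.invalidate()
    return False


def _t2_remove(mesh: VertexMesh, ci: int) -> None:
    """Extrude cell ``ci``: collapse its polygon to a point shared by its
    neighbours.  Standard T2 for triangles; small cells that still have
    more vertices are collapsed the same way."""
    cell = mesh.cells[ci]
    centroid = mesh.cell_centroid(ci)
    keep = cell.vertices[0]
    gone = set(cell.vertices[1:])
    mesh.points[keep] = centroid
    for cj, other in enumerate(mesh.cells):
        if cj == ci:
            continue
        if gone.intersection(other.vertices) or keep in other.vertices:
            cyc = [keep if v in gone else v for v in other.vertices]
            dedup = []
            for v in cyc:
                if not dedup or dedup[-1] != v:
                    dedup.append(v)
            if len(dedup) > 1 and dedup[0] == dedup[-1]:
                dedup.pop()
            other.vertices = dedup
    del mesh.cells[ci]
    mesh.invalidate()


# -- cell operations --------------------------------------------------------


def divide_cell(
    mesh: VertexMesh,
    ci: int,
    rng: np.random.Generator,
    time: float = 0.0,
    max_retries: int = 10,
) -> tuple[int, int]:
    """Split cell ``ci`` along a random line through its centroid.

    A new edge bisects the mother; the two daughters inherit its type, get
    fresh G1 draws and zeroed death clocks, and the per-type target area.
    The division axis is redrawn if the cut degenerates (crosses other than
    two edges, or lands on a vertex).  Returns the two daughter indices.
    """
    cell = mesh.cells[ci]
    centroid = mesh.cell_centroid(ci)
    eps = 1e-9

    for _ in range(max_retries):
        theta = rng.uniform(0.0, math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        normal = np.array([-direction[1], direction[0]])
        vs = cell.vertices
        d = (mesh.points[vs] - centroid) @ normal
        if np.any(np.abs(d) < eps):
            continue
        crossings = []
        k = len(vs)
        for j in range(k):
            if d[j] * d[(j + 1) % k] < 0:
                t = d[j] / (d[j] - d[(j + 1) % k])
                pt = mesh.points[vs[j]] + t * (
                    mesh.points[vs[(j + 1) % k]] - mesh.points[vs[j]]
                )
                crossings.append((j, pt))
        if len(crossings) != 2:
            continue
        (j1, pt1), (j2, pt2) = crossings

        # new vertices on the two cut edges
        v1 = len(mesh.points)
        v2 = v1 + 1
        mesh.points = np.vstack([mesh.points, pt1[None, :], pt2[None, :]])

        # insert into the neighbour sharing each cut edge
        for (j, _), new_v in (((j1, pt1), v1), ((j2, pt2), v2)):
            va, vb = vs[j], vs[(j + 1) % k]
            key = (min(va, vb), max(va, vb))
            for cj in mesh.edge_table.get(key, []):
                if cj == ci:
                    continue
                cyc = mesh.cells[cj].vertices
                # in the neighbour the edge runs vb -> va
                pos = cyc.index(vb)
                if cyc[(pos + 1) % len(cyc)] == va:
                    cyc.insert(pos + 1, new_v)
                else:
                    pos = cyc.index(va)
                    cyc.insert(pos + 1, new_v)

        # split the mother cycle: walk from just after edge j1 to edge j2
        child1 = [v1] + [vs[(j1 + 1 + m) % k] for m in range((j2 - j1) % k)] + [v2]
        child2 = [v2] + [vs[(j2 + 1 + m) % k] for m in range((j1 - j2) % k)] + [v1]

        label = cell.type_label
        old_record = cell.record
        daughters = []
        for cyc in (child1, child2):
            rec = None
            if old_record is not None:
                rec = CellRecord(
                    params=old_record.params,
                    sampled_g1=sample_g1(old_record.params, rng),
                    birth_time=time,
                    clock=0.0,
                    phase="G1",
                    type_label=label,
                    cell_id=mesh.next_cell_id,
                )
            daughters.append(
                _Cell(
                    vertices=cyc,
                    type_label=label,
                    cell_id=mesh.next_cell_id,
                    record=rec,
                    target_area=cell.target_area,
                )
            )
            mesh.next_cell_id += 1
        del mesh.cells[ci]
        mesh.cells.extend(daughters)
        mesh.invalidate()
        return len(mesh.cells) - 2, len(mesh.cells) - 1

    raise SimulationError(f"could not find a valid division axis for cell {cell.cell_id}")


def trigger_apoptosis(mesh: VertexMesh, ci: int) -> None:
    """Mark cell ``ci`` as dying: its target area shrinks to zero so it
    contracts until extruded by a T2 swap.  Dying cells no longer progress
    through the cycle, divide, or count toward the G2 death signal, but
    they keep exerting mechanical forces until removed."""
    cell = mesh.cells[ci]
    cell.dying = True
    cell.target_area = 0.0


def local_g2_fraction(mesh: VertexMesh, ci: int) -> float:
    """Fraction of edge-adjacent, non-dying neighbours in G2 phase.

    Zero for an isolated cell; dying neighbours are excluded from both the
    numerator and the denominator.
    """
    neigh = [
        mesh.cells[cj]
        for cj in mesh.neighbours(ci)
        if not mesh.cells[cj].dying
    ]
    neigh = [c for c in neigh if c.record is not None]
    if not neigh:
        return 0.0
    in_g2 = sum(1 for c in neigh if c.record.phase == "G2")
    return in_g2 / len(neigh)


# -- tissue construction ----------------------------------------------------


def _hex_patch(n_rows: int, n_cols: int) -> tuple[np.ndarray, list]:
    """Pointy-top hexagonal lattice of unit-area cells, ccw cycles."""
    r = math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))  # circumradius for area 1
    dx = math.sqrt(3.0) * r
    dy = 1.5 * r
    verts: dict = {}
    points: list = []

    def vid(x: float, y: float) -> int:
        key = (round(x, 9), round(y, 9))
        if key not in verts:
            verts[key] = len(points)
            points.append([x, y])
        return verts[key]

    cycles = []
    for row in range(n_rows):
        for col in range(n_cols):
            cx = col * dx + (row % 2) * dx / 2.0
            cy = row * dy
            cyc = []
            for k in range(6):
                ang = math.pi / 6.0 + k * math.pi / 3.0
                cyc.append(vid(cx + r * math.cos(ang), cy + r * math.sin(ang)))
            cycles.append(cyc)
    return np.array(points), cycles


def init_tissue(
    n_cells: int,
    arrangement: str,
    rng: np.random.Generator,
    clock_params: Optional[Mapping[str, DeathClockParams]] = None,
    target_area: Optional[Mapping[str, float]] = None,
    init: str = "newborn",
    homotypic_label: str = "A",
) -> VertexMesh:
    """Hexagonal starting tissue with the requested type arrangement.

    ``homotypic`` makes every cell type A; ``random`` splits the population
    equally and shuffles placements; ``segregated`` assigns the left and
    right halves (by centroid) to types A and B.  ``n_cells`` must tile as
    a near-square hexagonal patch (default study size: 36 = 6 x 6).
    Cells start as newborns (age 0, fresh G1 draws, zero clocks) unless
    ``init="staggered"``, which draws cycle positions from the stationary
    phase distribution.
    """
    n_rows = int(round(math.sqrt(n_cells)))
    if n_rows * n_rows == n_cells:
        n_cols = n_rows
    elif n_rows * (n_rows + 1) == n_cells:
        n_cols = n_rows + 1
    else:
        raise ValueError(f"cannot tile {n_cells} cells as a hexagonal patch")
    points, cycles = _hex_patch(n_rows, n_cols)

    if arrangement == "homotypic":
        labels = [homotypic_label] * n_cells
    elif arrangement in ("random", "segregated"):
        if n_cells % 2:
            raise ValueError("two-type arrangements need an even cell count")
        half = n_cells // 2
        if arrangement == "random":
            labels = ["A"] * half + ["B"] * half
            rng.shuffle(labels)
        else:
            centroids_x = [
                np.mean([points[v][0] for v in cyc]) for cyc in cycles
            ]
            order = np.argsort(centroids_x, kind="stable")
            labels = [""] * n_cells
            for rank, idx in enumerate(order):
                labels[idx] = "A" if rank < half else "B"
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    cells = []
    for i, (cyc, label) in enumerate(zip(cycles, labels)):
        rec = None
        s0 = 1.0
        if clock_params is not None:
            p = clock_params[label]
            phase = "G1"
            t_star = sample_g1(p, rng)
            birth = 0.0
            if init == "staggered" and p.cycle_mean > 0:
                if rng.random() < p.g2_duration / p.cycle_mean:
                    phase = "G2"
                    # residual G2 uniform: back-date the birth accordingly
                    birth = -(t_star + rng.random() * p.g2_duration)
            rec = CellRecord(
                params=p, sampled_g1=t_star, birth_time=birth,
                phase=phase, type_label=label, cell_id=i,
            )
        if target_area is not None:
            s0 = target_area[label]
        cells.append(
            _Cell(vertices=list(cyc), type_label=label, cell_id=i,
                  record=rec, target_area=s0)
        )
    return VertexMesh(points, cells)


# -- time stepping ----------------------------------------------------------


def _apply_rearrangements(
    mesh: VertexMesh,
    params: MechanicalParams,
    log: Optional[EventLog],
    time: float,
) -> None:
    # T1 swaps on short interior edges (bounded passes; an edge that cannot
    # be swapped, e.g. at the boundary, does not block the others)
    for _ in range(10):
        swapped = False
        for a, b, cs in mesh.unique_edges():
            if len(cs) != 2:
                continue
            if np.linalg.norm(mesh.points[a] - mesh.points[b]) >= params.t1_threshold:
                continue
            if _t1_swap(mesh, a, b, params):
                swapped = True
                if log is not None:
                    log.record(time, "t1swap", -1, "-")
                break  # topology changed: rescan edges
        if not swapped:
            break
    # T2 extrusions of collapsed cells
    while True:
        areas = mesh.areas()
        small = [
            ci
            for ci, cell in enumerate(mesh.cells)
            if (
                cell.dying and areas[ci] < params.t2_dying_area_threshold
            )
            or (
                areas[ci] < params.t2_area_threshold
                and (len(cell.vertices) == 3 or areas[ci] <= 0)
            )
        ]
        if not small:
            break
        ci = small[0]
        cell = mesh.cells[ci]
        if log is not None:
            log.record(time, "t2swap", cell.cell_id, cell.type_label)
            if not cell.dying:
                # passive (mechanical) death: extrusion of a live cell
                log.record(time, "death", cell.cell_id, cell.type_label)
        _t2_remove(mesh, ci)
        # a neighbour sharing two edges with the extruded cell can collapse
        # below three vertices; extrude it as well
        for cj in sorted(
            (j for j, c in enumerate(mesh.cells) if len(c.vertices) < 3),
            reverse=True,
        ):
            degenerate = mesh.cells[cj]
            if log is not None:
                log.record(time, "t2swap", degenerate.cell_id, degenerate.type_label)
                if not degenerate.dying:
                    log.record(time, "death", degenerate.cell_id, degenerate.type_label)
            del mesh.cells[cj]
            mesh.invalidate()


def advance(
    mesh: VertexMesh,
    params: MechanicalParams,
    dt: float,
    rng: np.random.Generator,
    time: float = 0.0,
    log: Optional[EventLog] = None,
    death_clock: bool = True,
    log_g1_exits: bool = True,
) -> None:
    """One fixed step: Euler vertex update, rearrangements, cycle events.

    Cycle and clock transitions are checked once per step at the post-move
    time ``time + dt``.  If a cell's clock reaches its threshold in the
    same step in which its G1 phase would end, death wins.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    forces = vertex_forces(mesh, params)
    mesh.points = mesh.points + (dt / params.friction) * forces
    _apply_rearrangements(mesh, params, log, time + dt)

    if np.any(mesh.areas() <= 0):
        raise SimulationError("cell with non-positive area: timestep too large?")

    if not any(c.record is not None for c in mesh.cells):
        return

    t_new = time + dt
    # snapshot signals before mutating phases so updates are synchronous
    fractions = {
        ci: local_g2_fraction(mesh, ci)
        for ci, cell in enumerate(mesh.cells)
        if cell.record is not None and not cell.dying
    }
    to_divide = []
    for ci, cell in enumerate(mesh.cells):
        rec = cell.record
        if rec is None or cell.dying:
            continue
        p = rec.params
        rec.advance_clock(p.signal_strength * fractions[ci] * dt)
        age = t_new - rec.birth_time
        if rec.phase == "G1":
            if death_clock and rec.clock >= p.death_threshold:
                if log is not None:
                    log.record(t_new, "death", cell.cell_id, cell.type_label)
                trigger_apoptosis(mesh, ci)
                continue
            if age >= rec.sampled_g1:
                rec.phase = "G2"
                if log is not None and log_g1_exits:
                    log.record(t_new, "g1exit", cell.cell_id, cell.type_label)
        if rec.phase == "G2" and age >= rec.sampled_g1 + p.g2_duration:
            to_divide.append(ci)

    # divisions mutate the cell list: process from the highest index down
    for ci in sorted(to_divide, reverse=True):
        cell = mesh.cells[ci]
        if log is not None:
            log.record(t_new, "division", cell.cell_id, cell.type_label)
        divide_cell(mesh, ci, rng, time=t_new)


@dataclass(frozen=True)
class VertexConfig:
    """Configuration of a vertex-model run.

    ``clock_params`` maps type labels to death-clock parameters (use a zero
    signal strength for the purely mechanical model); ``death_clock=False``
    additionally disables the apoptosis trigger so only passive extrusion
    removes cells.
    """

    end_time: float
    mech: MechanicalParams
    clock_params: Mapping[str, DeathClockParams]
    dt: float = 0.05
    n_cells: int = 36
    arrangement: str = "homotypic"
    seed: int = 0
    death_clock: bool = True
    max_population: int = 2000
    init: str = "newborn"
    homotypic_label: str = "A"
    log_g1_exits: bool = True


def run_vertex(config: VertexConfig) -> tuple[EventLog, VertexMesh]:
    """Fixed-step vertex simulation to end time or the population cap."""
    rng = np.random.default_rng(config.seed)
    mesh = init_tissue(
        config.n_cells,
        config.arrangement,
        rng,
        clock_params=config.clock_params,
        target_area=config.mech.target_area,
        init=config.init,
        homotypic_label=config.homotypic_label,
    )
    log = EventLog(metadata={
        "engine": "vertex",
        "seed": config.seed,
        "arrangement": config.arrangement,
        "truncated": False,
        "extinct": False,
    })
    n_steps = int(round(config.end_time / config.dt))
    time = 0.0
    for _ in range(n_steps):
        advance(
            mesh, config.mech, config.dt, rng, time=time, log=log,
            death_clock=config.death_clock, log_g1_exits=config.log_g1_exits,
        )
        time += config.dt
        if not mesh.cells:
            log.metadata["extinct"] = True
            break
        if len(mesh.cells) > config.max_population:
            log.metadata["truncated"] = True
            break
    log.metadata["final_time"] = time
    counts: dict = {}
    for cell in mesh.cells:
        counts[cell.type_label] = counts.get(cell.type_label, 0) + 1
    log.metadata["final_counts"] = counts
    return log, mesh
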
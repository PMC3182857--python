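"""Overdamped vertex dynamics with T1/T2 topological plasticity.

Vertices follow the relaxational equation of motion

    mu dx_i/dt = F_i = -dE/dx_i

integrated with a forward-Euler (FTCS) scheme.  Because the preferred areas
grow with the cell cycle, the energy landscape is time dependent and the
tissue is driven continuously out of equilibrium; at frozen preferred areas
the scheme is a plain gradient flow and the energy is non-increasing, which
is enforced by halving the step whenever a move would raise the energy.

Topological plasticity: an interior edge shorter than a fraction ``f_T`` of
the characteristic length ``l_h`` (the side of the regular hexagon of area
``A_min``) is swapped (T1), exchanging the neighbor relations of the four
surrounding cells; a triangular cell whose every edge is below the threshold
is extruded (T2) and replaced by a single vertex.  The tissue boundary is
free: exterior vertices obey the same dynamics, with a larger exterior line
tension keeping the tissue compact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cycle import CellClock, CycleParams, divide_cell, new_clock, update_preferred_area
from .identity import CellIdentity, update_characters
from .mechanics import ForceEngine, MechanicsParams
from .mesh import EdgeKey, TissueMesh, cell_centroid, edge_key, hexagon_side, polygon_area

__all__ = [
    "TopologyThresholds",
    "EventLog",
    "SimState",
    "DynamicsError",
    "step",
    "detect_and_apply_T1",
    "detect_and_apply_T2",
    "evolve",
    "relax",
]


class DynamicsError(RuntimeError):
    """Raised on numerical divergence (NaN/inf positions or forces)."""


@dataclass
class TopologyThresholds:
    """Thresholds of the T1/T2 transitions.

    ``a_min`` is the minimum prescribed cell area; ``l_h`` is the side of
    the regular hexagon of that area; transitions trigger on edges shorter
    than ``f_t * l_h``; a T1 leaves a new edge of ``post_t1_factor`` times
    the threshold length.
    """

    a_min: float = 0.25
    f_t: float = 0.1
    post_t1_factor: float = 1.05

    def __post_init__(self) -> None:
        if not 0.0 < self.f_t < 1.0:
            raise ValueError("f_t must lie in (0, 1)")
        if self.a_min <= 0.0:
            raise ValueError("a_min must be positive")

    @property
    def l_h(self) -> float:
        return hexagon_side(self.a_min)

    @property
    def edge_threshold(self) -> float:
        return self.f_t * self.l_h


class EventLog:
    """Time-stamped record of divisions, T1/T2 events and character switches."""

    COLUMNS = [
        "time",
        "event",
        "cell",
        "edge",
        "x",
        "y",
        "angle_deg",
        "duration",
        "cell_type",
    ]

    def __init__(self) -> None:
        self.rows: List[dict] = []

    def add(self, time: float, event: str, **fields) -> None:
        row = {c: None for c in self.COLUMNS}
        row["time"] = time
        row["event"] = event
        row.update(fields)
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def divisions(self) -> pd.DataFrame:
        df = self.to_dataframe()
        return df[df["event"] == "division"].reset_index(drop=True)


@dataclass
class SimState:
    """Complete simulation state: geometry, identities, clocks, parameters."""

    mesh: TissueMesh
    identities: Dict[int, CellIdentity]
    clocks: Dict[int, CellClock]
    mechanics: MechanicsParams
    cycle: CycleParams
    thresholds: TopologyThresholds
    rng: np.random.Generator
    events: EventLog = field(default_factory=EventLog)
    ablated: FrozenSet[EdgeKey] = frozenset()
    identity_mode: str = "maintenance"  # or "inherit"

    def preferred_areas(self) -> Dict[int, float]:
        return {cid: ck.preferred_area for cid, ck in self.clocks.items()}

    def cell_type(self, cid: int) -> str:
        return self.identities[cid].cell_type


def step(
    positions: np.ndarray, forces: np.ndarray, mu: float, dt: float
) -> np.ndarray:
    """One forward-Euler move: x <- x + (dt/mu) F."""
    new = positions + (dt / mu) * forces
    if not np.all(np.isfinite(new)):
        raise DynamicsError("non-finite vertex position after step")
    return new


# -- T1 ----------------------------------------------------------------------


def _third_cell(mesh: TissueMesh, vid: int, exclude: Tuple[int, int]) -> Optional[int]:
    cells = [c for c in mesh.cells_of_vertex(vid) if c not in exclude]
    return cells[0] if len(cells) == 1 else None


def _cycle_ok(mesh: TissueMesh, cid: int) -> bool:
    from shapely.geometry import Polygon

    cyc = mesh.cells[cid]
    if len(cyc) < 3 or len(set(cyc)) != len(cyc):
        return False
    if polygon_area(mesh, cid) <= 0.0:
        return False
    return Polygon(mesh.cell_vertices(cid)).is_valid


def _apply_T1(
    mesh: TissueMesh, edge: EdgeKey, thresholds: TopologyThresholds
) -> bool:
    """Attempt the T1 swap on one short interior edge; False if skipped."""
    a, b = edge
    cells = mesh.edge_map().get(edge)
    if cells is None or len(cells) != 2:
        return False
    p_cell, q_cell = cells
    if len(mesh.cells[p_cell]) <= 3 or len(mesh.cells[q_cell]) <= 3:
        return False  # would create a 2-sided cell
    r_cell = _third_cell(mesh, a, (p_cell, q_cell))
    s_cell = _third_cell(mesh, b, (p_cell, q_cell))
    if r_cell is None or s_cell is None or r_cell == s_cell:
        return False  # boundary or non-generic configuration
    if s_cell in mesh.adjacency()[r_cell]:
        return False  # would create a double edge

    pos = mesh.positions
    m = 0.5 * (pos[a] + pos[b])
    d = pos[b] - pos[a]
    nd = np.linalg.norm(d)
    if nd < 1e-300:
        u = np.array([1.0, 0.0])
    else:
        u = np.array([-d[1], d[0]]) / nd
    half = 0.5 * thresholds.post_t1_factor * thresholds.edge_threshold
    cp = cell_centroid(mesh, p_cell)
    sign = 1.0 if float(np.dot(u, cp - m)) >= 0.0 else -1.0

    saved = {c: list(mesh.cells[c]) for c in (p_cell, q_cell, r_cell, s_cell)}
    saved_pos = (pos[a].copy(), pos[b].copy())

    def neighbors_in_cycle(cyc: List[int], v: int) -> Tuple[int, int]:
        k = cyc.index(v)
        return cyc[k - 1], cyc[(k + 1) % len(cyc)]

    q_old = set(saved[q_cell])
    p_old = set(saved[p_cell])
    n1, n2 = neighbors_in_cycle(saved[r_cell], a)
    r_side = [n for n in (n1, n2) if n in q_old and n != b]
    m1, m2 = neighbors_in_cycle(saved[s_cell], b)
    s_side = [n for n in (m1, m2) if n in p_old and n != a]
    if len(r_side) != 1 or len(s_side) != 1:
        return False

    for flip in (1.0, -1.0):
        s = sign * flip
        pos[a] = m + s * half * u
        pos[b] = m - s * half * u
        # P keeps a, Q keeps b; R gains b next to a (Q side), S gains a (P side)
        mesh.replace_cycle(p_cell, [v for v in saved[p_cell] if v != b])
        mesh.replace_cycle(q_cell, [v for v in saved[q_cell] if v != a])
        r_cyc = list(saved[r_cell])
        k = r_cyc.index(a)
        if r_cyc[(k + 1) % len(r_cyc)] == r_side[0]:
            r_cyc.insert(k + 1, b)
        else:
            r_cyc.insert(k, b)
        mesh.replace_cycle(r_cell, r_cyc)
        s_cyc = list(saved[s_cell])
        k = s_cyc.index(b)
        if s_cyc[(k + 1) % len(s_cyc)] == s_side[0]:
            s_cyc.insert(k + 1, a)
        else:
            s_cyc.insert(k, a)
        mesh.replace_cycle(s_cell, s_cyc)

        if all(_cycle_ok(mesh, c) for c in (p_cell, q_cell, r_cell, s_cell)):
            return True
        for c, cyc in saved.items():
            mesh.replace_cycle(c, cyc)
        pos[a], pos[b] = saved_pos
    return False


def detect_and_apply_T1(
    mesh: TissueMesh,
    thresholds: TopologyThresholds,
    rng: Optional[np.random.Generator] = None,
    events: Optional[EventLog] = None,
) -> int:
    """Swap every interior edge below threshold (randomized scan order).

    Each edge undergoes at most one transition per call; swaps that would
    create a two-sided cell or an invalid polygon are skipped.  Returns the
    number of T1 events applied.
    """
    thr = thresholds.edge_threshold
    pos = mesh.positions
    keys, pairs, interior = mesh.edge_arrays()
    if not keys:
        return 0
    lengths = np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1)
    idx = np.flatnonzero(interior & (lengths < thr))
    candidates = [keys[k] for k in idx]
    if rng is not None and len(candidates) > 1:
        order = rng.permutation(len(candidates))
        candidates = [candidates[k] for k in order]
    count = 0
    for e in candidates:
        emap = mesh.edge_map()
        if e not in emap:  # consumed by an earlier swap
            continue
        if np.linalg.norm(pos[e[1]] - pos[e[0]]) >= thr:
            continue
        if _apply_T1(mesh, e, thresholds):
            count += 1
            if events is not None:
                mid = 0.5 * (pos[e[0]] + pos[e[1]])
                events.add(
                    mesh.time, "T1", edge=str(e), x=float(mid[0]), y=float(mid[1])
                )
    return count


# -- T2 ----------------------------------------------------------------------


def detect_and_apply_T2(
    mesh: TissueMesh,
    thresholds: TopologyThresholds,
    events: Optional[EventLog] = None,
) -> int:
    """Extrude every triangular cell whose edges are all below threshold.

    The cell is replaced by a single vertex at its centroid and the
    neighboring cells are reconnected; returns the number of extrusions.
    Shrinking cells with more than three sides are first reduced by T1s, so
    only triangles are handled here.
    """
    thr = thresholds.edge_threshold
    count = 0
    for cid in list(mesh.cells.keys()):
        cyc = mesh.cells.get(cid)
        if cyc is None or len(cyc) != 3:
            continue
        pts = mesh.positions[cyc]  # re-fetch: add_vertex reallocates
        lengths = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        if not np.all(lengths < thr):
            continue
        center = cell_centroid(mesh, cid)
        tri = set(cyc)
        neighbor_cells = {
            c for v in cyc for c in mesh.cells_of_vertex(v) if c != cid
        }
        new_cycles = {}
        ok = True
        for nc in neighbor_cells:
            cyc_n = list(mesh.cells[nc])
            # rotate so the cycle does not start inside the triangle run
            start = next((k for k, v in enumerate(cyc_n) if v not in tri), None)
            if start is None:
                ok = False
                break
            cyc_n = cyc_n[start:] + cyc_n[:start]
            out: List[int] = []
            replaced = False
            for v in cyc_n:
                if v in tri:
                    if not replaced:
                        out.append(-1)  # placeholder for the new vertex
                        replaced = True
                    # triangle vertices must form one consecutive run
                    elif out[-1] != -1:
                        ok = False
                        break
                else:
                    out.append(v)
            if not ok or len(out) < 3:
                ok = False
                break
            new_cycles[nc] = out
        if not ok:
            continue
        w = mesh.add_vertex(center)
        for nc, out in new_cycles.items():
            mesh.replace_cycle(nc, [w if v == -1 else v for v in out])
        for v in cyc:
            mesh._remove_vertex(v)
        mesh.remove_cell(cid)
        count += 1
        if events is not None:
            events.add(
                mesh.time, "T2", cell=cid, x=float(center[0]), y=float(center[1])
            )
    return count


# -- orchestration -----------------------------------------------------------


def relax(
    state: SimState,
    force_tol: float = 1e-4,
    max_time: float = 200.0,
    check_every: int = 20,
) -> float:
    """Integrate with frozen clocks until max |F_i| < force_tol.

    Returns the residual max-force norm.  Used to prepare equilibrium
    tissues (e.g. before in silico ablation).
    """
    engine = ForceEngine(state.mechanics)
    mu, dt = state.mechanics.mu, state.mechanics.dt
    mesh = state.mesh
    t0 = mesh.time
    residual = math.inf
    k = 0
    while mesh.time - t0 < max_time:
        if engine.needs_compile(mesh, state.ablated):
            engine.compile(mesh, state.identities, state.ablated)
        a0 = engine.a0_from_clocks(state.clocks)
        f = engine.forces(mesh.positions, a0)
        if k % check_every == 0:
            residual = float(np.max(np.linalg.norm(f, axis=1)))
            if residual < force_tol:
                break
        mesh.set_positions(step(mesh.positions, f, mu, dt))
        mesh.time += dt
        detect_and_apply_T1(mesh, state.thresholds, state.rng, state.events)
        detect_and_apply_T2(mesh, state.thresholds, state.events)
        k += 1
    return residual


def evolve(
    state: SimState,
    t_end: float,
    freeze_cycle: bool = False,
    hook: Optional[Callable[[SimState], None]] = None,
    hook_every: Optional[float] = None,
    trace: Optional[Callable[[SimState, "ForceEngine"], None]] = None,
    energy_guard: bool = True,
    max_halvings: int = 8,
) -> SimState:
    """Advance the tissue to absolute time ``t_end``.

    Per-step order: forces -> Euler move -> T1/T2 checks -> preferred-area /
    clock update -> division checks -> character maintenance (after any
    topological or division event).  With ``energy_guard`` a move that would
    raise the energy at the current preferred areas is retried with a halved
    step (gradient-flow property of the relaxational dynamics); the
    accumulated time advances by the step actually taken.

    ``hook(state)`` runs every ``hook_every`` time units; ``trace`` runs
    every step with the compiled engine (for cheap per-step measurements).
    """
    mesh = state.mesh
    mech = state.mechanics
    engine = ForceEngine(mech)
    next_hook = mesh.time if hook is not None else math.inf

    while mesh.time < t_end - 1e-12:
        dt = min(mech.dt, t_end - mesh.time)
        if engine.needs_compile(mesh, state.ablated):
            engine.compile(mesh, state.identities, state.ablated)
        a0 = engine.a0_from_clocks(state.clocks)
        pos = mesh.positions
        f = engine.forces(pos, a0)

        if energy_guard:
            # tolerate roundoff-level increases; halve only on real ascent
            e0 = engine.energy(pos, a0)
            tol = 1e-9 * max(abs(e0), 1.0)
            dt_try = dt
            for _ in range(max_halvings):
                new_pos = step(pos, f, mech.mu, dt_try)
                if engine.energy(new_pos, a0) <= e0 + tol:
                    dt = dt_try
                    break
                dt_try *= 0.5
            else:
                new_pos = step(pos, f, mech.mu, dt)
        else:
            new_pos = step(pos, f, mech.mu, dt)
        mesh.set_positions(new_pos)
        mesh.time += dt

        n_topo = detect_and_apply_T1(mesh, state.thresholds, state.rng, state.events)
        n_topo += detect_and_apply_T2(mesh, state.thresholds, state.events)
        if n_topo:
            _purge_dead_cells(state)

        n_div = 0
        if not freeze_cycle:
            for ck in state.clocks.values():
                update_preferred_area(ck, mesh.time - dt, dt, state.cycle)
            n_div = _division_sweep(state, engine)

        if (n_topo or n_div) and state.identity_mode == "maintenance":
            state.identities, switched = update_characters(mesh, state.identities)
            for cid in switched:
                c = cell_centroid(mesh, cid)
                state.events.add(
                    mesh.time,
                    "character-switch",
                    cell=cid,
                    x=float(c[0]),
                    y=float(c[1]),
                )

        if trace is not None:
            if engine.needs_compile(mesh, state.ablated):
                engine.compile(mesh, state.identities, state.ablated)
            trace(state, engine)
        if mesh.time >= next_hook - 1e-12:
            hook(state)  # type: ignore[misc]
            next_hook += hook_every if hook_every else math.inf
    return state


def _purge_dead_cells(state: SimState) -> None:
    """Drop bookkeeping of cells removed by T2."""
    live = state.mesh.cells
    for d in (state.clocks, state.identities):
        for cid in [c for c in d if c not in live]:
            del d[cid]


def _division_sweep(state: SimState, engine: ForceEngine) -> int:
    """Divide every growth-phase cell whose actual area reached A_div."""
    mesh = state.mesh
    params = state.cycle
    if engine.needs_compile(mesh, state.ablated):
        engine.compile(mesh, state.identities, state.ablated)
    areas = engine.cell_areas(mesh.positions)
    t = mesh.time
    ready = [
        cid
        for cid, slot in engine.cell_slot.items()
        if areas[slot] >= params.a_div
        and state.clocks[cid].phase(t, params.latent_fraction) == "growing"
    ]
    for cid in ready:
        ctype = state.cell_type(cid)
        clock = state.clocks[cid]
        d1, d2, rec = divide_cell(
            mesh, cid, state.rng, params, clock=clock, cell_type=ctype
        )
        ident = state.identities.pop(cid)
        state.identities[d1] = ident
        state.identities[d2] = ident
        del state.clocks[cid]
        state.clocks[d1] = new_clock(params, ident.cell_type, t, state.rng)
        state.clocks[d2] = new_clock(params, ident.cell_type, t, state.rng)
        state.events.add(
            t,
            "division",
            cell=cid,
            x=rec.x,
            y=rec.y,
            angle_deg=rec.angle_deg,
            duration=rec.realized_duration,
            cell_type=rec.cell_type,
        )
    return len(ready)
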
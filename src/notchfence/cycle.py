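"""Stochastic cell cycle, area growth, and Hertwig-rule cell division.

Each cell carries an internal clock.  At birth it samples an intended cycle
duration ``t' = T_det + xi`` where ``T_det`` is a deterministic, type
dependent time scale and ``xi ~ Exp(lambda)`` captures cell-to-cell
variability; this law reproduces the exponentially decaying steady-state age
distribution in which newborn cells are twice as frequent as cells about to
divide.  The cycle has two phases: a latent phase (first half of ``t'``)
during which the preferred apical area stays at the reference area, and a
growth phase during which the preferred area increases linearly at a common
speed ``v_A`` shared by every cell type.  The *actual* division happens when
the measured polygon area reaches the threshold ``A_div`` (while in the
growth phase), so the realized cycle duration emerges from the mechanics:
crowded cells divide late.

Cleavage follows the Hertwig rule: the division plane passes through the
cell centroid orthogonally to the cell's longest axis (from the rod inertia
tensor of its edges), perturbed by a Gaussian angle truncated at a hard
bound, reflecting the dispersion observed in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mesh import (
    TissueMesh,
    cell_centroid,
    longest_axis,
    polygon_area,
)

__all__ = [
    "CycleParams",
    "CellClock",
    "DivisionRecord",
    "sample_cycle_duration",
    "new_clock",
    "update_preferred_area",
    "division_ready",
    "cleavage_direction",
    "divide_cell",
]


@dataclass
class CycleParams:
    """Cell-cycle parameters (dimensionless time; 1 hour ~ 10 time units).

    ``t_det_*`` are the deterministic base durations per cell type; the
    organizer value is twice the bulk value (the geometric requirement for a
    stripe growing in one dimension inside a disc growing in two), and
    clones cycle at half the bulk duration.  ``dispersion_fraction`` sets
    the exponential noise scale ``1/lambda = dispersion_fraction * T_det``.

    ``growth_mode`` selects how the preferred apical area grows after the
    latent phase.  In the default ``"per_cell"`` mode every cell doubles its
    preferred area over its own growth phase, so the time to double A0 is
    the random variable ``(1 - latent_fraction) t'`` and slow-cycling
    organizer cells also grow slowly — the regime in which the realized
    organizer cycle is about twice the bulk one and a two-cell-wide stripe
    is sustainable.  In ``"common"`` mode one shared speed ``v_a`` applies
    to every cell regardless of its intended duration.  ``a_div`` is the
    actual-area division threshold.
    """

    t_det_bulk: float = 100.0  # ~10 h
    t_det_organizer: float = 200.0  # ~20 h (twice rule)
    clone_speedup: float = 0.5  # clone T_det = 0.5 * bulk
    dispersion_fraction: float = 0.25  # 1/lambda relative to T_det
    latent_fraction: float = 0.5  # latent phase = first half of t'
    a_ref: float = 1.0
    a_div: float = 1.65  # divide when actual area reaches this
    growth_mode: str = "per_cell"  # or "common"
    v_a: Optional[float] = None  # growth speed of the "common" mode
    sigma_theta: float = 15.0  # cleavage noise std (degrees)
    theta_max: float = 30.0  # hard bound on cleavage deviation (degrees)
    random_cleavage: bool = False  # mutant: ignore the Hertwig rule

    def __post_init__(self) -> None:
        if self.t_det_bulk <= 0 or self.t_det_organizer <= 0:
            raise ValueError("deterministic cycle durations must be positive")
        if self.dispersion_fraction <= 0:
            raise ValueError("dispersion fraction must be positive")
        if not 0.0 < self.latent_fraction < 1.0:
            raise ValueError("latent fraction must lie in (0, 1)")
        if self.a_div <= self.a_ref:
            raise ValueError("division threshold must exceed the reference area")
        if self.growth_mode not in ("per_cell", "common"):
            raise ValueError("growth_mode must be 'per_cell' or 'common'")
        if self.v_a is None:
            # uncrowded bulk cell doubles A0 within its mean growth phase
            mean_cycle = self.mean_cycle("C")
            self.v_a = self.a_ref / ((1.0 - self.latent_fraction) * mean_cycle)
        if self.v_a <= 0:
            raise ValueError("area growth speed must be positive")
        if not 0.0 < self.sigma_theta <= self.theta_max:
            raise ValueError("need 0 < sigma_theta <= theta_max")

    def t_det(self, cell_type: str) -> float:
        if cell_type == "O":
            return self.t_det_organizer
        if cell_type == "clone":
            return self.clone_speedup * self.t_det_bulk
        return self.t_det_bulk

    def rate(self, cell_type: str) -> float:
        """Exponential rate lambda of the stochastic duration increment."""
        return 1.0 / (self.dispersion_fraction * self.t_det(cell_type))

    def mean_cycle(self, cell_type: str) -> float:
        """Mean intended duration T_det + 1/lambda."""
        return self.t_det(cell_type) * (1.0 + self.dispersion_fraction)

    def copy(self, **changes) -> "CycleParams":
        return replace(self, **changes)


@dataclass
class CellClock:
    """Per-cell cycle state: birth time, intended duration, preferred area.

    ``growth_speed`` is the cell's own preferred-area growth speed; in the
    "common" growth mode it simply holds the shared value.
    """

    birth_time: float
    duration: float  # sampled intended duration t'
    preferred_area: float
    growth_speed: float = 0.0

    def elapsed(self, t: float) -> float:
        return t - self.birth_time

    def phase(self, t: float, latent_fraction: float) -> str:
        return "latent" if self.elapsed(t) < latent_fraction * self.duration else "growing"


@dataclass
class DivisionRecord:
    time: float
    mother: int
    daughters: Tuple[int, int]
    x: float
    y: float
    realized_duration: float
    angle_deg: float  # cleavage edge angle relative to the DV (x) axis
    cell_type: str


def sample_cycle_duration(t_det: float, lam: float, rng: np.random.Generator) -> float:
    """Intended cycle duration t' = T_det + xi with xi ~ Exp(lam)."""
    if t_det <= 0 or lam <= 0:
        raise ValueError("t_det and lambda must be positive")
    return t_det + rng.exponential(1.0 / lam)


def new_clock(
    params: CycleParams,
    cell_type: str,
    t: float,
    rng: np.random.Generator,
    random_phase: bool = False,
) -> CellClock:
    """Fresh clock for a newborn cell (or a random-phase initial cell).

    With ``random_phase`` the elapsed age is uniform over the sampled
    duration and the preferred area is set consistently with the growth law,
    as prescribed for the initial configuration.
    """
    duration = sample_cycle_duration(params.t_det(cell_type), params.rate(cell_type), rng)
    if params.growth_mode == "per_cell":
        speed = params.a_ref / ((1.0 - params.latent_fraction) * duration)
    else:
        speed = params.v_a
    birth = t
    a0 = params.a_ref
    if random_phase:
        age = rng.uniform(0.0, duration)
        birth = t - age
        grow_time = max(0.0, age - params.latent_fraction * duration)
        a0 = params.a_ref + speed * grow_time
    return CellClock(
        birth_time=birth, duration=duration, preferred_area=a0, growth_speed=speed
    )


def update_preferred_area(
    clock: CellClock, t: float, dt: float, params: CycleParams
) -> None:
    """Advance the preferred area over [t, t+dt] in place.

    No growth during the latent phase; linear growth at the cell's speed
    afterwards, uncapped until division.  A step straddling the phase
    transition grows only for the overlapping sub-interval, so the
    accumulated preferred area is exact regardless of the step size.
    """
    growth_start = clock.birth_time + params.latent_fraction * clock.duration
    grow = (t + dt) - max(t, growth_start)
    if grow > 0.0:
        speed = clock.growth_speed if clock.growth_speed > 0 else params.v_a
        clock.preferred_area += speed * min(grow, dt)


def division_ready(area: float, clock: CellClock, t: float, params: CycleParams) -> bool:
    """True iff the cell is in its growth phase and its *actual* polygon
    area has reached the division threshold."""
    return clock.phase(t, params.latent_fraction) == "growing" and area >= params.a_div


def _truncated_gaussian_deg(
    rng: np.random.Generator, sigma: float, bound: float
) -> float:
    """Gaussian deviate (degrees) truncated to [-bound, bound] by rejection."""
    for _ in range(1000):
        x = rng.normal(0.0, sigma)
        if abs(x) <= bound:
            return float(x)
    return 0.0  # pragma: no cover - sigma <= bound makes this unreachable


def cleavage_direction(
    mesh: TissueMesh,
    cid: int,
    rng: np.random.Generator,
    params: CycleParams,
) -> np.ndarray:
    """Unit direction of the cleavage line through the cell centroid.

    Hertwig rule: orthogonal to the cell's longest axis, then rotated by a
    bounded Gaussian perturbation.  With ``random_cleavage`` the direction
    is uniform (the orientation-rule knockout).
    """
    if params.random_cleavage:
        ang = rng.uniform(0.0, math.pi)
        return np.array([math.cos(ang), math.sin(ang)])
    axis = longest_axis(mesh, cid, rng=rng)
    cleave = np.array([-axis[1], axis[0]])  # transverse to the longest axis
    dev = math.radians(_truncated_gaussian_deg(rng, params.sigma_theta, params.theta_max))
    c, s = math.cos(dev), math.sin(dev)
    return np.array([c * cleave[0] - s * cleave[1], s * cleave[0] + c * cleave[1]])


def _line_crossings(
    pts: np.ndarray, center: np.ndarray, direction: np.ndarray
) -> List[Tuple[int, float]]:
    """Indices k and parameters t of polygon edges (k, k+1) crossed by the
    line through ``center`` with the given direction."""
    rel = pts - center
    s = direction[0] * rel[:, 1] - direction[1] * rel[:, 0]
    crossings: List[Tuple[int, float]] = []
    n = len(pts)
    for k in range(n):
        s0, s1 = s[k], s[(k + 1) % n]
        if s0 == 0.0 or s1 == 0.0:
            # vertex exactly on the line: signal the caller to nudge
            return []
        if (s0 > 0) != (s1 > 0):
            t = s0 / (s0 - s1)
            crossings.append((k, float(min(max(t, 1e-3), 1.0 - 1e-3))))
    return crossings


def _insert_between(mesh: TissueMesh, cid: int, a: int, b: int, w: int) -> None:
    """Insert vertex w between adjacent vertices a, b of a cell's cycle."""
    cyc = mesh.cells[cid]
    n = len(cyc)
    for k in range(n):
        u, v = cyc[k], cyc[(k + 1) % n]
        if {u, v} == {a, b}:
            mesh.replace_cycle(cid, cyc[: k + 1] + [w] + cyc[k + 1 :])
            return
    raise ValueError(f"vertices {a},{b} not adjacent in cell {cid}")


def divide_cell(
    mesh: TissueMesh,
    cid: int,
    rng: np.random.Generator,
    params: CycleParams,
    clock: Optional[CellClock] = None,
    cell_type: str = "C",
) -> Tuple[int, int, DivisionRecord]:
    """Split a cell along its cleavage line; returns (d1, d2, record).

    Two new vertices are inserted where the line crosses the cell perimeter
    (splitting the crossed edges, also in the neighbor cells that share
    them) and one new edge is created between them.  Daughter cycles stay
    counterclockwise and their areas sum exactly to the mother's.  Identity
    inheritance and fresh clocks are the caller's concern.

    If the line fails to cross the perimeter in exactly two points (very
    non-convex cell), the unrotated Hertwig axis is retried; as a last
    resort the cell is split through its two most distant edge midpoints.
    """
    cyc = list(mesh.cells[cid])
    pts = mesh.positions[cyc]
    center = cell_centroid(mesh, cid)

    direction = cleavage_direction(mesh, cid, rng, params)
    crossings = _attempt_crossings(pts, center, direction)
    if crossings is None and not params.random_cleavage:
        axis = longest_axis(mesh, cid, rng=rng)
        direction = np.array([-axis[1], axis[0]])
        crossings = _attempt_crossings(pts, center, direction)
    if crossings is None:
        # most distant pair of edge midpoints
        mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
        d2 = ((mids[:, None, :] - mids[None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        crossings = [(i, 0.5), (j, 0.5)]

    (i, ti), (j, tj) = sorted(crossings)
    p1 = pts[i] + ti * (pts[(i + 1) % len(cyc)] - pts[i])
    p2 = pts[j] + tj * (pts[(j + 1) % len(cyc)] - pts[j])
    w1 = mesh.add_vertex(p1)
    w2 = mesh.add_vertex(p2)

    # split the two crossed edges in the neighbor cells sharing them
    emap = mesh.edge_map()
    for (k, w) in ((i, w1), (j, w2)):
        a, b = cyc[k], cyc[(k + 1) % len(cyc)]
        key = (a, b) if a < b else (b, a)
        for other in emap.get(key, ()):  # type: ignore[union-attr]
            if other != cid:
                _insert_between(mesh, other, a, b, w)

    n = len(cyc)
    d1_cyc = [w1] + cyc[i + 1 : j + 1] + [w2]
    d2_cyc = [w2] + cyc[j + 1 :] + cyc[: i + 1] + [w1]
    mesh.remove_cell(cid)
    d1 = mesh.add_cell(d1_cyc)
    d2 = mesh.add_cell(d2_cyc)

    delta = p2 - p1
    ang = math.degrees(math.atan2(delta[1], delta[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    realized = mesh.time - clock.birth_time if clock is not None else math.nan
    record = DivisionRecord(
        time=mesh.time,
        mother=cid,
        daughters=(d1, d2),
        x=float(center[0]),
        y=float(center[1]),
        realized_duration=realized,
        angle_deg=ang,
        cell_type=cell_type,
    )
    return d1, d2, record


def _attempt_crossings(
    pts: np.ndarray, center: np.ndarray, direction: np.ndarray
) -> Optional[List[Tuple[int, float]]]:
    """Crossings of the division line, nudging the angle when a polygon
    vertex falls exactly on it; None when no clean 2-point crossing exists."""
    for attempt in range(6):
        if attempt:
            eps = 1e-6 * attempt
            c, s = math.cos(eps), math.sin(eps)
            direction = np.array(
                [c * direction[0] - s * direction[1], s * direction[0] + c * direction[1]]
            )
        crossings = _line_crossings(pts, center, direction)
        if len(crossings) == 2:
            return crossings
        if len(crossings) > 2:
            return None
    return None
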
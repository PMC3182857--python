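"""Tissue energy functional and analytic vertex forces.

The mechanical state of the apical network is described by the standard
vertex-model energy, extended with a local cable term:

    E = sum_cells [ K/2 (A - A0)^2 + Gamma/2 L^2 ]
      + sum_edges Lambda(class) * l
      + sum_{cable edges} Gamma_edge/2 * l^2

The quadratic area term is the cell's elastic response to deviations of its
actual apical area ``A`` from the preferred area ``A0(t)`` set by the cell
cycle; ``Gamma L^2`` models isotropic contraction of the actomyosin cortical
ring; ``Lambda * l`` is the line tension of each edge, combining cell-cell
adhesion and cortical tension and depending on the identities of the two
abutting cells; and the per-edge ``Gamma_edge/2 l^2`` term represents the
actomyosin cable that runs along the DV boundary (edges shared by organizer
cells of opposite compartments).

Everything is dimensionless: lengths in units of sqrt(A_ref), energies in
K*A_ref^2, time in mu/(K*A_ref).

Vertex dynamics is overdamped (see :mod:`notchfence.dynamics`); forces are
the exact analytic negative gradient of the energy, evaluated here in
vectorized form by :class:`ForceEngine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .identity import CellIdentity
from .mesh import EdgeKey, TissueMesh, edge_key

__all__ = [
    "MechanicsParams",
    "EDGE_CLASSES",
    "classify_edge",
    "total_energy",
    "vertex_forces",
    "ablate_edge",
    "ForceEngine",
]

EDGE_CLASSES = ("C-C", "O-O", "O-C", "boundary", "exterior")


@dataclass
class MechanicsParams:
    """Dimensionless mechanical coefficients.

    The defaults satisfy the affinity ordering
    ``Lambda(C-C) < Lambda(O-O) < Lambda(O-C)`` (bulk-bulk affinity maximal,
    organizer/bulk mixing least favorable), carry an extra line tension plus
    a cable contractility on DV-boundary edges, and a large exterior tension
    that keeps the free tissue boundary compact.  They are a calibration
    surface chosen to reproduce hexagon-dominated packing and a stable
    organizer, and are fully configurable.
    """

    k_elastic: float = 1.0  # area elasticity K, per cell
    gamma: float = 0.02  # perimeter contractility, per cell
    lambda_cc: float = 0.06  # line tension of bulk-bulk edges
    lambda_oo: float = 0.09  # organizer-organizer, same compartment
    lambda_oc: float = 0.15  # organizer-bulk
    lambda_boundary: float = 0.20  # DV-boundary edges (O-O, opposite sides)
    lambda_exterior: float = 0.30  # edges facing the exterior
    gamma_edge: float = 0.05  # cable contractility, DV-boundary edges only
    mu: float = 1.0  # mobility (drag); sets the relaxation time scale
    dt: float = 0.05  # integration step, must satisfy the stability bound
    # apply the cable also to O-C rim edges (ectopic organizers are
    # Notch-functional, so their rim carries the cable)
    ectopic_rim_cable: bool = False

    def validate(self) -> None:
        if self.k_elastic <= 0 or self.mu <= 0 or self.dt <= 0:
            raise ValueError("K, mu and dt must be positive")
        tensions = (
            self.lambda_cc,
            self.lambda_oo,
            self.lambda_oc,
            self.lambda_boundary,
            self.lambda_exterior,
        )
        if any(t < 0 for t in tensions) or self.gamma < 0 or self.gamma_edge < 0:
            raise ValueError("line tensions and contractilities must be >= 0")

    def line_tension(self, edge_class: str) -> float:
        return {
            "C-C": self.lambda_cc,
            "O-O": self.lambda_oo,
            "O-C": self.lambda_oc,
            "boundary": self.lambda_boundary,
            "exterior": self.lambda_exterior,
        }[edge_class]

    def cable_coefficient(self, edge_class: str) -> float:
        if edge_class == "boundary":
            return self.gamma_edge
        if edge_class == "O-C" and self.ectopic_rim_cable:
            return self.gamma_edge
        return 0.0

    def copy(self, **changes) -> "MechanicsParams":
        return replace(self, **changes)


def classify_edge(
    mesh: TissueMesh, identities: Mapping[int, CellIdentity], edge: EdgeKey
) -> str:
    """Class of an edge: 'C-C', 'O-O', 'O-C', 'boundary' or 'exterior'.

    The class is a function of the unordered pair of abutting cells.  An
    O-O edge is a DV-boundary edge iff its two organizer cells belong to
    opposite compartments.  Exterior edges are classed 'exterior' regardless
    of the cell identity.
    """
    cells = mesh.edge_map()[edge]
    if len(cells) == 1:
        return "exterior"
    a, b = (identities[c] for c in cells)
    chars = {a.character, b.character}
    if chars == {"O"}:
        return "boundary" if a.compartment != b.compartment else "O-O"
    if chars == {"O", "C"}:
        return "O-C"
    return "C-C"


def total_energy(
    mesh: TissueMesh,
    identities: Mapping[int, CellIdentity],
    params: MechanicsParams,
    preferred_areas: Mapping[int, float],
    ablated: FrozenSet[EdgeKey] = frozenset(),
) -> float:
    """Direct (non-vectorized) evaluation of the tissue energy.

    Serves as the readable reference; :class:`ForceEngine` computes the same
    quantity in vectorized form.  Ablated edges contribute no line tension
    or cable energy and their length is excluded from the perimeters of both
    adjacent cells (the elastic area term is unaffected).
    """
    pos = mesh.positions
    e = 0.0
    for cid, cyc in mesh.cells.items():
        if cid not in preferred_areas:
            raise KeyError(f"missing preferred area for cell {cid}")
        a = mesh.cell_area(cid)
        perim = 0.0
        n = len(cyc)
        for k in range(n):
            ek = edge_key(cyc[k], cyc[(k + 1) % n])
            if ek not in ablated:
                perim += float(np.linalg.norm(pos[ek[1]] - pos[ek[0]]))
        e += 0.5 * params.k_elastic * (a - preferred_areas[cid]) ** 2
        e += 0.5 * params.gamma * perim**2
    for ek in mesh.edge_map():
        if ek in ablated:
            continue
        cls = classify_edge(mesh, identities, ek)
        length = float(np.linalg.norm(pos[ek[1]] - pos[ek[0]]))
        e += params.line_tension(cls) * length
        e += 0.5 * params.cable_coefficient(cls) * length**2
    return e


def vertex_forces(
    mesh: TissueMesh,
    identities: Mapping[int, CellIdentity],
    params: MechanicsParams,
    preferred_areas: Mapping[int, float],
    ablated: FrozenSet[EdgeKey] = frozenset(),
) -> np.ndarray:
    """Analytic force F_i = -dE/dx_i on every vertex, shape (n_rows, 2).

    Rows of removed vertices are zero.  Assembled from the area, line
    tension, perimeter and cable terms of all incident cells and edges.
    """
    engine = ForceEngine(params)
    engine.compile(mesh, identities, ablated)
    a0 = engine.a0_array(preferred_areas)
    return engine.forces(mesh.positions, a0)


def ablate_edge(
    mesh: TissueMesh,
    ablated: FrozenSet[EdgeKey],
    edge: EdgeKey,
) -> Tuple[FrozenSet[EdgeKey], Tuple[int, int]]:
    """Mark an interior edge as ablated; returns (new set, endpoint vertices).

    Ablation suppresses every energetic contribution of the edge except the
    elastic area term of the two adjacent cells: its line tension and cable
    term are removed and its length no longer counts toward either cell's
    perimeter.  The two endpoint vertices are returned so that their recoil
    displacement can be recorded.
    """
    edge = edge_key(*edge)
    cells = mesh.edge_map().get(edge)
    if cells is None:
        raise KeyError(f"no such edge: {edge}")
    if len(cells) == 1:
        raise ValueError("cannot ablate an exterior edge")
    return ablated | {edge}, (edge[0], edge[1])


class ForceEngine:
    """Vectorized evaluation of energy and forces on a frozen topology.

    The engine compiles the mesh topology, edge classes and ablation state
    into flat index arrays once, then evaluates energy/forces with pure
    numpy.  It must be recompiled (cheap, and done lazily via the stored
    topology version) after any T1/T2, division, ablation or identity
    change.
    """

    def __init__(self, params: MechanicsParams) -> None:
        self.params = params
        self._version: Optional[int] = None
        self._ablated: FrozenSet[EdgeKey] = frozenset()
        self.cell_ids: list = []
        self.cell_slot: Dict[int, int] = {}

    # -- compilation -------------------------------------------------------

    def needs_compile(self, mesh: TissueMesh, ablated: FrozenSet[EdgeKey]) -> bool:
        return self._version != mesh.topology_version or self._ablated != ablated

    def compile(
        self,
        mesh: TissueMesh,
        identities: Mapping[int, CellIdentity],
        ablated: FrozenSet[EdgeKey] = frozenset(),
    ) -> None:
        self.cell_ids = list(mesh.cells.keys())
        self.cell_slot = {cid: s for s, cid in enumerate(self.cell_ids)}
        fc_cell, fc_v, fc_next, fc_prev, fc_perim = [], [], [], [], []
        for cid in self.cell_ids:
            cyc = mesh.cells[cid]
            n = len(cyc)
            s = self.cell_slot[cid]
            for k in range(n):
                v, nxt, prv = cyc[k], cyc[(k + 1) % n], cyc[k - 1]
                fc_cell.append(s)
                fc_v.append(v)
                fc_next.append(nxt)
                fc_prev.append(prv)
                fc_perim.append(edge_key(v, nxt) not in ablated)
        self.fc_cell = np.asarray(fc_cell, dtype=np.intp)
        self.fc_v = np.asarray(fc_v, dtype=np.intp)
        self.fc_next = np.asarray(fc_next, dtype=np.intp)
        self.fc_prev = np.asarray(fc_prev, dtype=np.intp)
        self.fc_perim = np.asarray(fc_perim, dtype=bool)

        emap = mesh.edge_map()
        e_i, e_j, lam, gam = [], [], [], []
        for ek in emap:
            e_i.append(ek[0])
            e_j.append(ek[1])
            if ek in ablated:
                lam.append(0.0)
                gam.append(0.0)
            else:
                cls = classify_edge(mesh, identities, ek)
                lam.append(self.params.line_tension(cls))
                gam.append(self.params.cable_coefficient(cls))
        self.e_i = np.asarray(e_i, dtype=np.intp)
        self.e_j = np.asarray(e_j, dtype=np.intp)
        self.e_lambda = np.asarray(lam)
        self.e_gamma = np.asarray(gam)
        self.edge_keys = list(emap.keys())

        self._version = mesh.topology_version
        self._ablated = frozenset(ablated)

    def a0_array(self, preferred_areas: Mapping[int, float]) -> np.ndarray:
        try:
            return np.array([preferred_areas[c] for c in self.cell_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"missing preferred area for cell {exc.args[0]}") from exc

    def a0_from_clocks(self, clocks) -> np.ndarray:
        """Preferred areas in compiled cell order, read from cycle clocks."""
        return np.array([clocks[c].preferred_area for c in self.cell_ids])

    # -- geometry ----------------------------------------------------------

    def cell_areas(self, pos: np.ndarray) -> np.ndarray:
        xv, yv = pos[self.fc_v, 0], pos[self.fc_v, 1]
        xn, yn = pos[self.fc_next, 0], pos[self.fc_next, 1]
        cross = xv * yn - xn * yv
        areas = np.zeros(len(self.cell_ids))
        np.add.at(areas, self.fc_cell, 0.5 * cross)
        return areas

    def cell_perimeters(self, pos: np.ndarray) -> np.ndarray:
        seg = pos[self.fc_next] - pos[self.fc_v]
        ln = np.linalg.norm(seg, axis=1) * self.fc_perim
        perims = np.zeros(len(self.cell_ids))
        np.add.at(perims, self.fc_cell, ln)
        return perims

    def edge_lengths(self, pos: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pos[self.e_j] - pos[self.e_i], axis=1)

    # -- energy and forces -------------------------------------------------

    def energy(self, pos: np.ndarray, a0: np.ndarray) -> float:
        p = self.params
        areas = self.cell_areas(pos)
        perims = self.cell_perimeters(pos)
        ln = self.edge_lengths(pos)
        e = 0.5 * p.k_elastic * np.sum((areas - a0) ** 2)
        e += 0.5 * p.gamma * np.sum(perims**2)
        e += np.sum(self.e_lambda * ln)
        e += 0.5 * np.sum(self.e_gamma * ln**2)
        return float(e)

    def forces(self, pos: np.ndarray, a0: np.ndarray) -> np.ndarray:
        p = self.params
        f = np.zeros_like(pos)

        # area elasticity: dA/dx_k = 0.5 (y_next - y_prev, x_prev - x_next)
        areas = self.cell_areas(pos)
        coef = -p.k_elastic * (areas - a0)
        grad = 0.5 * np.column_stack(
            [
                pos[self.fc_next, 1] - pos[self.fc_prev, 1],
                pos[self.fc_prev, 0] - pos[self.fc_next, 0],
            ]
        )
        contrib = coef[self.fc_cell][:, None] * grad
        np.add.at(f, self.fc_v, contrib)

        # perimeter contractility: dL/dx over each (non-ablated) cycle edge
        perims = self.cell_perimeters(pos)
        seg = pos[self.fc_next] - pos[self.fc_v]
        ln = np.maximum(np.linalg.norm(seg, axis=1), 1e-300)
        tang = seg / ln[:, None]
        w = (p.gamma * perims[self.fc_cell] * self.fc_perim)[:, None] * tang
        np.add.at(f, self.fc_v, w)
        np.subtract.at(f, self.fc_next, w)

        # line tension and cable on unique edges
        eseg = pos[self.e_j] - pos[self.e_i]
        eln = np.maximum(np.linalg.norm(eseg, axis=1), 1e-300)
        etang = eseg / eln[:, None]
        ew = (self.e_lambda + self.e_gamma * eln)[:, None] * etang
        np.add.at(f, self.e_i, ew)
        np.subtract.at(f, self.e_j, ew)
        return f
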
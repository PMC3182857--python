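"""Planar polygonal tissue mesh: geometry primitives and initial conditions.

The apical surface of the epithelium is a planar polygonal mesh.  Vertices
hold 2D positions (dimensionless, lengths in units of the square root of the
reference cell area); cells are counterclockwise vertex cycles; edges are
derived from the cell cycles, each interior edge bordering exactly two cells
and each exterior edge exactly one (free tissue boundary).

Conventions
-----------
* The dorsoventral (DV) axis is horizontal (x); the organizer stripe of the
  wild-type initial condition runs along it.
* Initial cells are regular hexagons with two vertical side edges ("pointy"
  top and bottom), so the interface between two hexagon rows is a zigzag of
  edges at +/-30 degrees from the DV axis.
* Vertex ids are stable and never reused; cell ids likewise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .identity import CellIdentity

__all__ = [
    "TissueMesh",
    "InitialConditionSpec",
    "MeshInvalidError",
    "build_hex_patch",
    "polygon_area",
    "polygon_perimeter",
    "cell_centroid",
    "rod_inertia_tensor",
    "rod_inertia_axes",
    "longest_axis",
    "cell_neighbors",
    "validate",
    "write_snapshot",
    "read_snapshot",
]

EdgeKey = Tuple[int, int]


class MeshInvalidError(ValueError):
    """Raised when a mesh violates a structural invariant."""


def edge_key(a: int, b: int) -> EdgeKey:
    return (a, b) if a < b else (b, a)


class TissueMesh:
    """Polygonal mesh of apical vertices with full cell/edge adjacency.

    Vertex positions live in one growing ``(n, 2)`` float64 array whose row
    index *is* the vertex id, which keeps force evaluation vectorizable.
    Cells are stored as counterclockwise vertex cycles.  The edge map and
    adjacency caches are invalidated whenever the topology changes.
    """

    def __init__(self) -> None:
        self._pos = np.empty((0, 2), dtype=float)
        self._active = np.empty(0, dtype=bool)
        self.cells: Dict[int, List[int]] = {}
        self.time: float = 0.0
        self._next_cell_id = 0
        self._topology_version = 0
        self._edge_cache: Optional[Dict[EdgeKey, Tuple[int, ...]]] = None
        self._adj_cache: Optional[Dict[int, Set[int]]] = None
        self._edge_arrays: Optional[Tuple[list, np.ndarray, np.ndarray]] = None

    # -- vertices ---------------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        """Full (n, 2) position array indexed by vertex id (stale rows for
        removed vertices; see :meth:`active_vertex_ids`)."""
        return self._pos

    def n_vertices(self) -> int:
        return int(self._active.sum())

    def active_vertex_ids(self) -> np.ndarray:
        return np.flatnonzero(self._active)

    def add_vertex(self, xy: Sequence[float]) -> int:
        vid = self._pos.shape[0]
        self._pos = np.vstack([self._pos, np.asarray(xy, dtype=float)])
        self._active = np.append(self._active, True)
        return vid

    def position(self, vid: int) -> np.ndarray:
        return self._pos[vid]

    def set_positions(self, pos: np.ndarray) -> None:
        if pos.shape != self._pos.shape:
            raise ValueError("position array shape mismatch")
        self._pos = np.asarray(pos, dtype=float)

    def _remove_vertex(self, vid: int) -> None:
        self._active[vid] = False

    # -- cells ------------------------------------------------------------

    def add_cell(self, cycle: Sequence[int]) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        self.cells[cid] = list(cycle)
        self.invalidate_topology()
        return cid

    def remove_cell(self, cid: int) -> None:
        del self.cells[cid]
        self.invalidate_topology()

    def cell_ids(self) -> List[int]:
        return list(self.cells.keys())

    def n_cells(self) -> int:
        return len(self.cells)

    def cell_vertices(self, cid: int) -> np.ndarray:
        """(k, 2) vertex coordinates of the cell's ccw cycle."""
        return self._pos[self.cells[cid]]

    def replace_cycle(self, cid: int, cycle: Sequence[int]) -> None:
        self.cells[cid] = list(cycle)
        self.invalidate_topology()

    def invalidate_topology(self) -> None:
        self._topology_version += 1
        self._edge_cache = None
        self._adj_cache = None
        self._edge_arrays = None

    @property
    def topology_version(self) -> int:
        return self._topology_version

    # -- edges and adjacency ----------------------------------------------

    def edge_map(self) -> Dict[EdgeKey, Tuple[int, ...]]:
        """Map (vmin, vmax) -> tuple of adjacent cell ids (1 = exterior)."""
        if self._edge_cache is None:
            emap: Dict[EdgeKey, List[int]] = {}
            for cid, cyc in self.cells.items():
                n = len(cyc)
                for k in range(n):
                    emap.setdefault(edge_key(cyc[k], cyc[(k + 1) % n]), []).append(cid)
            self._edge_cache = {e: tuple(cs) for e, cs in emap.items()}
        return self._edge_cache

    def edge_arrays(self) -> Tuple[list, np.ndarray, np.ndarray]:
        """Cached ``(edge keys, (E, 2) vertex-id array, interior mask)`` for
        vectorized per-step edge-length scans."""
        if self._edge_arrays is None:
            emap = self.edge_map()
            keys = list(emap.keys())
            pairs = (
                np.asarray(keys, dtype=np.intp)
                if keys
                else np.empty((0, 2), dtype=np.intp)
            )
            interior = np.array([len(emap[k]) == 2 for k in keys], dtype=bool)
            self._edge_arrays = (keys, pairs, interior)
        return self._edge_arrays

    def is_exterior_edge(self, edge: EdgeKey) -> bool:
        return len(self.edge_map()[edge]) == 1

    def exterior_vertices(self) -> Set[int]:
        out: Set[int] = set()
        for (a, b), cells in self.edge_map().items():
            if len(cells) == 1:
                out.add(a)
                out.add(b)
        return out

    def adjacency(self) -> Dict[int, Set[int]]:
        """Cell-adjacency graph: cells sharing an edge."""
        if self._adj_cache is None:
            adj: Dict[int, Set[int]] = {cid: set() for cid in self.cells}
            for cells in self.edge_map().values():
                if len(cells) == 2:
                    a, b = cells
                    adj[a].add(b)
                    adj[b].add(a)
            self._adj_cache = adj
        return self._adj_cache

    def cell_neighbors(self, cid: int, order: int = 1) -> Set[int]:
        """Order-1: edge-sharing neighbors.  Order-2: cells at graph
        distance exactly 2 in the cell-adjacency graph."""
        adj = self.adjacency()
        first = adj[cid]
        if order == 1:
            return set(first)
        if order == 2:
            second: Set[int] = set()
            for n in first:
                second |= adj[n]
            return second - first - {cid}
        raise ValueError("order must be 1 or 2")

    def cells_of_vertex(self, vid: int) -> List[int]:
        return [cid for cid, cyc in self.cells.items() if vid in cyc]

    # -- geometry ---------------------------------------------------------

    def cell_area(self, cid: int) -> float:
        return polygon_area(self, cid)

    def cell_perimeter(self, cid: int) -> float:
        return polygon_perimeter(self, cid)

    def total_area(self) -> float:
        return sum(polygon_area(self, c) for c in self.cells)

    def copy(self) -> "TissueMesh":
        m = TissueMesh()
        m._pos = self._pos.copy()
        m._active = self._active.copy()
        m.cells = {cid: list(cyc) for cid, cyc in self.cells.items()}
        m.time = self.time
        m._next_cell_id = self._next_cell_id
        m._topology_version = self._topology_version
        return m


# -- geometry primitives ----------------------------------------------------


def _cycle_coords(mesh: TissueMesh, cid: int) -> np.ndarray:
    if cid not in mesh.cells:
        raise KeyError(f"no such cell: {cid}")
    cyc = mesh.cells[cid]
    if len(cyc) < 3:
        raise MeshInvalidError(f"cell {cid} is degenerate (<3 vertices)")
    return mesh.positions[cyc]


def polygon_area(mesh: TissueMesh, cid: int) -> float:
    """Shoelace (signed) area of the cell's ccw vertex cycle; positive for
    a valid cell."""
    p = _cycle_coords(mesh, cid)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_perimeter(mesh: TissueMesh, cid: int) -> float:
    p = _cycle_coords(mesh, cid)
    return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())


def cell_centroid(mesh: TissueMesh, cid: int) -> np.ndarray:
    """Area centroid of the cell polygon."""
    p = _cycle_coords(mesh, cid)
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return p.mean(axis=0)
    cx = ((p[:, 0] + q[:, 0]) * cross).sum() / (6.0 * a)
    cy = ((p[:, 1] + q[:, 1]) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _rod_centroid(p: np.ndarray, q: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Mass-weighted centroid of a set of uniform-density rods p[k]->q[k]."""
    lengths = np.linalg.norm(q - p, axis=1)
    total = lengths.sum()
    c = ((p + q) / 2.0 * lengths[:, None]).sum(axis=0) / total
    return c, lengths


def rod_inertia_tensor(mesh: TissueMesh, cid: int) -> np.ndarray:
    """2x2 inertia tensor of the cell modeled as a closed set of rods.

    Each polygon edge is a rod of uniform line density; the tensor is taken
    about the centroid of the rod system (not the polygon-area centroid) and
    follows the planar convention ``I = trace(M) Id - M`` where ``M`` is the
    second-moment (covariance) matrix of the mass distribution.  The
    eigenvector of the *largest* principal moment is normal to the cell's
    longest axis.
    """
    pts = _cycle_coords(mesh, cid)
    p = pts
    q = np.roll(pts, -1, axis=0)
    c, lengths = _rod_centroid(p, q)
    a = p - c
    d = q - p
    # integral over each rod of (r)(r)^T, r = a + t d, t in [0, 1], mass l dt
    m = np.zeros((2, 2))
    for k in range(len(p)):
        aa = np.outer(a[k], a[k])
        ad = np.outer(a[k], d[k])
        dd = np.outer(d[k], d[k])
        m += lengths[k] * (aa + 0.5 * (ad + ad.T) + dd / 3.0)
    return np.trace(m) * np.eye(2) - m


def rod_inertia_axes(mesh: TissueMesh, cid: int) -> Tuple[np.ndarray, np.ndarray]:
    """Principal directions and moments of the rod inertia tensor.

    Returns ``(directions, moments)`` with moments sorted ascending and
    ``directions[:, k]`` the unit eigenvector of ``moments[k]``.
    """
    tensor = rod_inertia_tensor(mesh, cid)
    moments, directions = np.linalg.eigh(tensor)
    return directions, moments


def longest_axis(
    mesh: TissueMesh,
    cid: int,
    rng: Optional[np.random.Generator] = None,
    tie_tol: float = 1e-9,
) -> np.ndarray:
    """Unit vector along the cell's longest axis (orthogonal to the
    eigenvector of the largest principal moment).

    Nearly isotropic cells (relative moment gap below ``tie_tol``) have no
    meaningful longest axis; a uniformly random direction is returned then,
    mirroring the angular noise added at division anyway.
    """
    directions, moments = rod_inertia_axes(mesh, cid)
    scale = max(abs(moments[1]), 1e-300)
    if (moments[1] - moments[0]) / scale < tie_tol:
        rng = rng or np.random.default_rng()
        ang = rng.uniform(0.0, math.pi)
        return np.array([math.cos(ang), math.sin(ang)])
    normal = directions[:, 1]  # eigenvector of the largest moment
    axis = np.array([-normal[1], normal[0]])
    return axis / np.linalg.norm(axis)


def cell_neighbors(mesh: TissueMesh, cid: int, order: int = 1) -> Set[int]:
    return mesh.cell_neighbors(cid, order=order)


# -- validation --------------------------------------------------------------


def validate(mesh: TissueMesh) -> None:
    """Assert the structural invariants; raise :class:`MeshInvalidError`.

    Checks: every cell is a simple polygon with >= 3 distinct vertices and
    positive signed (ccw) area; every edge borders one or two cells; no
    vertex repeats within a cycle; referenced vertices are active.
    """
    from shapely.geometry import Polygon

    active = set(mesh.active_vertex_ids().tolist())
    for cid, cyc in mesh.cells.items():
        if len(cyc) < 3:
            raise MeshInvalidError(f"cell {cid} has fewer than 3 vertices")
        if len(set(cyc)) != len(cyc):
            raise MeshInvalidError(f"cell {cid} repeats a vertex in its cycle")
        if not set(cyc) <= active:
            raise MeshInvalidError(f"cell {cid} references an inactive vertex")
        area = polygon_area(mesh, cid)
        if area <= 0.0:
            raise MeshInvalidError(
                f"cell {cid} has non-positive signed area {area:.3e} (not ccw?)"
            )
        poly = Polygon(mesh.cell_vertices(cid))
        if not poly.is_valid:
            raise MeshInvalidError(f"cell {cid} is not a simple polygon")
    for edge, cells in mesh.edge_map().items():
        if len(cells) not in (1, 2):
            raise MeshInvalidError(
                f"edge {edge} borders {len(cells)} cells (must be 1 or 2)"
            )


# -- initial conditions ------------------------------------------------------


@dataclass
class InitialConditionSpec:
    """Specification of the starting tissue.

    The wild-type condition is a patch of ``nrows x ncols`` regular hexagons
    of area ``a_ref`` with a two-cell-wide organizer stripe (the fence)
    along the DV axis; the lower stripe row is ventral organizer, the upper
    dorsal.  ``stripe_rows=()`` builds a tissue without organizer cells.
    ``clone`` marks a disc of bulk cells (center row/col and radius in cell
    units) as a fast-cycling clone.  ``ectopic`` replaces the stripe by a
    figure-eight organizer patch inside one compartment, given as
    ((row1, col1), (row2, col2), radius) in cell-center distance units.
    """

    nrows: int = 14
    ncols: int = 14
    a_ref: float = 1.0
    stripe_rows: Optional[Tuple[int, ...]] = None  # None -> middle two rows
    clone: Optional[Tuple[int, int, float]] = None  # (row, col, radius)
    ectopic: Optional[Tuple[Tuple[int, int], Tuple[int, int], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("patch must contain at least one cell")
        if self.a_ref <= 0:
            raise ValueError("reference cell area must be positive")


def hexagon_side(area: float) -> float:
    """Side length of the regular hexagon with the given area."""
    return math.sqrt(2.0 * area / (3.0 * math.sqrt(3.0)))


def _hex_center(row: int, col: int, side: float) -> Tuple[float, float]:
    hx = math.sqrt(3.0) * side
    return (hx * (col + 0.5 * (row % 2)), 1.5 * side * row)


def build_hex_patch(
    spec: InitialConditionSpec,
) -> Tuple[TissueMesh, Dict[int, CellIdentity]]:
    """Build the initial tissue: a patch of regular hexagons plus identities.

    Returns the mesh and a per-cell :class:`CellIdentity` map.  With the
    default spec, every vertical transect across the central span of the
    stripe crosses exactly two organizer cells.
    """
    side = hexagon_side(spec.a_ref)
    # ccw vertex offsets of a "pointy-top" regular hexagon (two vertical
    # side edges; row interfaces zigzag at +/-30 degrees from the x axis)
    offs = [
        (math.cos(math.radians(a)) * side, math.sin(math.radians(a)) * side)
        for a in (30, 90, 150, 210, 270, 330)
    ]

    mesh = TissueMesh()
    vid_of: Dict[Tuple[int, int], int] = {}

    def vertex_at(x: float, y: float) -> int:
        key = (round(x / side * 1e6), round(y / side * 1e6))
        if key not in vid_of:
            vid_of[key] = mesh.add_vertex((x, y))
        return vid_of[key]

    if spec.stripe_rows is None:
        if spec.nrows >= 2:
            stripe = (spec.nrows // 2 - 1, spec.nrows // 2)
        else:
            stripe = (0,)
    else:
        stripe = tuple(spec.stripe_rows)
    midrow = spec.nrows / 2.0  # rows >= midrow are dorsal

    cell_rc: Dict[int, Tuple[int, int]] = {}
    identities: Dict[int, CellIdentity] = {}
    for r in range(spec.nrows):
        for c in range(spec.ncols):
            cx, cy = _hex_center(r, c, side)
            cyc = [vertex_at(cx + dx, cy + dy) for dx, dy in offs]
            cid = mesh.add_cell(cyc)
            cell_rc[cid] = (r, c)
            compartment = "D" if r >= midrow else "V"
            character = "O" if (r in stripe and spec.ectopic is None) else "C"
            identities[cid] = CellIdentity(character=character, compartment=compartment)

    if spec.clone is not None:
        r0, c0, radius = spec.clone
        x0, y0 = _hex_center(r0, c0, side)
        pitch = math.sqrt(3.0) * side
        for cid, (r, c) in cell_rc.items():
            if identities[cid].character == "O":
                continue
            x, y = _hex_center(r, c, side)
            if math.hypot(x - x0, y - y0) <= radius * pitch + 1e-9:
                identities[cid] = CellIdentity(
                    character="C",
                    compartment=identities[cid].compartment,
                    clone=True,
                )

    if spec.ectopic is not None:
        (r1, c1), (r2, c2), radius = spec.ectopic
        pitch = math.sqrt(3.0) * side
        centers = [_hex_center(r1, c1, side), _hex_center(r2, c2, side)]
        for cid, (r, c) in cell_rc.items():
            x, y = _hex_center(r, c, side)
            if any(
                math.hypot(x - xc, y - yc) <= radius * pitch + 1e-9
                for xc, yc in centers
            ):
                identities[cid] = CellIdentity(
                    character="O", compartment=identities[cid].compartment
                )

    return mesh, identities


# -- snapshot I/O ------------------------------------------------------------


def write_snapshot(path, mesh: TissueMesh, identities, clocks=None) -> None:
    """Write a JSON-lines snapshot: one meta record then one record per cell.

    Floats are serialized via ``repr`` (JSON default), so a read/write
    round-trip is bit-exact.
    """
    records = snapshot_records(mesh, identities, clocks)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def snapshot_records(mesh: TissueMesh, identities, clocks=None) -> List[dict]:
    vids = mesh.active_vertex_ids()
    meta = {
        "type": "meta",
        "time": mesh.time,
        "vertices": {int(v): [float(x) for x in mesh.position(v)] for v in vids},
    }
    records = [meta]
    for cid, cyc in mesh.cells.items():
        ident = identities[cid]
        rec = {
            "type": "cell",
            "id": int(cid),
            "vertices": [int(v) for v in cyc],
            "character": ident.character,
            "compartment": ident.compartment,
            "clone": bool(ident.clone),
        }
        if clocks is not None and cid in clocks:
            ck = clocks[cid]
            rec["clock"] = {
                "birth_time": ck.birth_time,
                "duration": ck.duration,
                "preferred_area": ck.preferred_area,
            }
        records.append(rec)
    return records


def write_vtk(path, mesh: TissueMesh, identities=None) -> None:
    """Legacy-ASCII VTK polydata export for visualization.

    Cells become VTK polygons; when identities are given, a per-cell scalar
    encodes the type (0 bulk, 1 organizer, 2 clone).
    """
    vids = mesh.active_vertex_ids()
    index = {int(v): k for k, v in enumerate(vids)}
    lines = [
        "# vtk DataFile Version 3.0",
        f"tissue t={mesh.time}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vids)} float",
    ]
    for v in vids:
        x, y = mesh.position(v)
        lines.append(f"{x} {y} 0.0")
    size = sum(len(cyc) + 1 for cyc in mesh.cells.values())
    lines.append(f"POLYGONS {mesh.n_cells()} {size}")
    for cyc in mesh.cells.values():
        lines.append(" ".join([str(len(cyc))] + [str(index[v]) for v in cyc]))
    if identities is not None:
        code = {"C": 0, "O": 1, "clone": 2}
        lines += [
            f"CELL_DATA {mesh.n_cells()}",
            "SCALARS cell_type int 1",
            "LOOKUP_TABLE default",
        ]
        for cid in mesh.cells:
            lines.append(str(code[identities[cid].cell_type]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_snapshot(path):
    """Inverse of :func:`write_snapshot`; returns (mesh, identities, clocks).

    ``clocks`` maps cell id to a ``(birth_time, duration, preferred_area)``
    dict when clock data were stored, else is empty.
    """
    mesh = TissueMesh()
    identities: Dict[int, CellIdentity] = {}
    clocks: Dict[int, dict] = {}
    vid_map: Dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["type"] == "meta":
                mesh.time = rec["time"]
                for vid_str, xy in rec["vertices"].items():
                    vid_map[int(vid_str)] = mesh.add_vertex(xy)
            else:
                cyc = [vid_map[v] for v in rec["vertices"]]
                cid = mesh.add_cell(cyc)
                identities[cid] = CellIdentity(
                    character=rec["character"],
                    compartment=rec["compartment"],
                    clone=rec["clone"],
                )
                if "clock" in rec:
                    clocks[cid] = rec["clock"]
    return mesh, identities, clocks
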
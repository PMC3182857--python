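"""Quantification of tissue structure, divisions, boundary shape and recoil.

All metrics operate on a mesh plus identity/clock maps or on event logs and
return plain numpy/pandas containers so they can be written as tidy tables.
Conventions: cleavage angles are measured against the axis perpendicular to
the DV boundary and folded into [0, 90] degrees (0 = cleaving orthogonally
to the boundary); boundary-edge angles are signed against the DV (x) axis in
[-90, 90] degrees.  Cells touching the exterior border are excluded from the
packing statistics, since the free-boundary condition makes peripheral cells
elongate perpendicularly to the border.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cycle import CellClock
from .identity import (
    CellIdentity,
    compartment_interface_edges,
    dv_boundary_edges,
    fence_breach_edges,
)
from .mesh import TissueMesh, polygon_area

__all__ = [
    "side_histogram",
    "area_by_sides",
    "cleavage_angle_stats",
    "boundary_angle_stats",
    "organizer_width",
    "mixing_index",
    "MixingIndex",
    "RelaxationFit",
    "fit_relaxation",
    "required_cycle_ratio",
    "phase_cluster_sizes",
    "interior_cells",
]


def interior_cells(mesh: TissueMesh) -> List[int]:
    """Cells with no exterior edge (packing statistics are taken on these)."""
    exterior_touching: Set[int] = set()
    for edge, cells in mesh.edge_map().items():
        if len(cells) == 1:
            exterior_touching.add(cells[0])
    return [c for c in mesh.cells if c not in exterior_touching]


def side_histogram(mesh: TissueMesh, cells: Optional[Sequence[int]] = None) -> pd.Series:
    """Probability of each polygon side count among interior cells."""
    if cells is None:
        cells = interior_cells(mesh)
    if not cells:
        raise ValueError("no cells selected for the side histogram")
    counts = Counter(len(mesh.cells[c]) for c in cells)
    total = sum(counts.values())
    sides = sorted(counts)
    return pd.Series(
        [counts[s] / total for s in sides], index=pd.Index(sides, name="sides")
    )


def area_by_sides(mesh: TissueMesh, cells: Optional[Sequence[int]] = None) -> pd.Series:
    """Mean cell area per side class divided by the overall mean cell area."""
    if cells is None:
        cells = interior_cells(mesh)
    if not cells:
        raise ValueError("no cells selected")
    df = pd.DataFrame(
        {
            "sides": [len(mesh.cells[c]) for c in cells],
            "area": [polygon_area(mesh, c) for c in cells],
        }
    )
    overall = df["area"].mean()
    out = df.groupby("sides")["area"].mean() / overall
    out.name = "normalized_area"
    return out


def cleavage_angle_stats(
    divisions: pd.DataFrame,
    cell_class: Optional[str] = None,
    bins: int = 6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of division angles against the DV-perpendicular axis.

    ``divisions`` is an event-log frame with ``angle_deg`` (cleavage edge
    angle vs the DV axis) and ``cell_type`` columns.  ``cell_class``
    filters by type ('O', 'C', 'clone'); None keeps everything.  Returns
    ``(bin_edges, probabilities)`` over [0, 90] degrees, where 0 means the
    cell cleaved orthogonally to the DV boundary.
    """
    df = divisions
    if cell_class is not None:
        df = df[df["cell_type"] == cell_class]
    if len(df) == 0:
        raise ValueError("no divisions in the selected class")
    theta = fold_to_perpendicular(df["angle_deg"].to_numpy(dtype=float))
    edges = np.linspace(0.0, 90.0, bins + 1)
    hist, _ = np.histogram(theta, bins=edges)
    return edges, hist / hist.sum()


def fold_to_perpendicular(angle_vs_dv_deg: np.ndarray) -> np.ndarray:
    """Map a cleavage-edge angle vs the DV axis to the acute angle vs the
    DV-perpendicular axis, folded into [0, 90] degrees."""
    a = np.abs(np.asarray(angle_vs_dv_deg, dtype=float))
    a = np.minimum(a % 180.0, 180.0 - (a % 180.0))
    return 90.0 - a


@dataclass
class BoundaryAngleStats:
    angles_deg: np.ndarray  # signed angle of each boundary edge vs DV axis
    lengths: np.ndarray
    correlation: float  # corr(theta, length)
    histogram: Tuple[np.ndarray, np.ndarray]  # (bin edges, probabilities)

    @property
    def dispersion(self) -> float:
        """Circular-free spread of the signed angles (degrees)."""
        return float(np.std(self.angles_deg))


def boundary_angle_stats(
    mesh: TissueMesh,
    identities: Mapping[int, CellIdentity],
    bins: int = 12,
) -> BoundaryAngleStats:
    """Signed angle vs the DV axis for every DV-boundary edge.

    A perfectly straight horizontal boundary gives all angles 0; the
    hexagon-dominated wild type organizes into a +/-30 degree zigzag.  The
    (theta, length) correlation is reported to verify the two are not
    coupled.
    """
    edges = dv_boundary_edges(mesh, identities)
    if not edges:
        raise ValueError("tissue has no DV boundary edges")
    pos = mesh.positions
    angles, lengths = [], []
    for a, b in edges:
        d = pos[b] - pos[a]
        ang = math.degrees(math.atan2(d[1], d[0]))
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        angles.append(ang)
        lengths.append(float(np.hypot(d[0], d[1])))
    angles_arr = np.asarray(angles)
    lengths_arr = np.asarray(lengths)
    if len(angles_arr) > 1 and angles_arr.std() > 0 and lengths_arr.std() > 0:
        corr = float(np.corrcoef(angles_arr, lengths_arr)[0, 1])
    else:
        corr = 0.0
    bin_edges = np.linspace(-90.0, 90.0, bins + 1)
    hist, _ = np.histogram(angles_arr, bins=bin_edges)
    return BoundaryAngleStats(
        angles_deg=angles_arr,
        lengths=lengths_arr,
        correlation=corr,
        histogram=(bin_edges, hist / hist.sum()),
    )


def organizer_width(
    mesh: TissueMesh,
    identities: Mapping[int, CellIdentity],
    n_transects: int = 50,
    trim: float = 0.10,
) -> pd.DataFrame:
    """Organizer cell count along evenly spaced vertical transects.

    The outer ``trim`` fraction of the tissue x-span is excluded on each
    side (the free boundary pinches the stripe ends).  Returns one row per
    transect with columns ``x`` and ``width``; a tissue without organizer
    cells yields all-zero widths.
    """
    o_cells = [c for c, i in identities.items() if i.character == "O" and c in mesh.cells]
    vids = mesh.active_vertex_ids()
    xs = mesh.positions[vids, 0]
    lo, hi = xs.min(), xs.max()
    span = hi - lo
    lo += trim * span
    hi -= trim * span
    transects = np.linspace(lo, hi, n_transects)
    ranges = []
    for c in o_cells:
        cx = mesh.cell_vertices(c)[:, 0]
        ranges.append((cx.min(), cx.max()))
    widths = [
        sum(1 for xmin, xmax in ranges if xmin <= x0 <= xmax) for x0 in transects
    ]
    return pd.DataFrame({"x": transects, "width": widths})


@dataclass
class MixingIndex:
    heterotypic_contacts: int  # C(D)-C(V) shared edges: fence breaches
    interface_length: float  # total length of the D/V interface
    roughness: float  # interface length / end-to-end distance


def mixing_index(
    mesh: TissueMesh, identities: Mapping[int, CellIdentity]
) -> MixingIndex:
    """Fence-breach count and geometric roughness of the D/V interface."""
    breaches = fence_breach_edges(mesh, identities)
    interface = compartment_interface_edges(mesh, identities)
    pos = mesh.positions
    if not interface:
        return MixingIndex(0, 0.0, math.nan)
    total = sum(float(np.linalg.norm(pos[b] - pos[a])) for a, b in interface)
    verts = sorted({v for e in interface for v in e}, key=lambda v: pos[v, 0])
    end_to_end = float(np.linalg.norm(pos[verts[-1]] - pos[verts[0]]))
    rough = total / end_to_end if end_to_end > 0 else math.inf
    return MixingIndex(len(breaches), total, rough)


@dataclass
class RelaxationFit:
    d0: float
    d_inf: float
    tau: float
    v0: float  # initial recoil velocity (d_inf - d0) / tau
    r_squared: float


def fit_relaxation(t: np.ndarray, d: np.ndarray) -> RelaxationFit:
    """Least-squares fit of the recoil trace d(t) = d_inf - (d_inf-d0) e^(-t/tau).

    ``t`` is time since ablation, ``d`` the separation of the two wound
    vertices.  Raises ``RuntimeError`` with diagnostics when the fit does
    not converge.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if t.shape != d.shape or len(t) < 4:
        raise ValueError("need matching t/d arrays with at least 4 samples")

    def model(tt, d0, d_inf, tau):
        return d_inf - (d_inf - d0) * np.exp(-tt / tau)

    span = max(t[-1] - t[0], 1e-12)
    p0 = (d[0], d[-1], span / 3.0)
    try:
        popt, _ = curve_fit(model, t, d, p0=p0, maxfev=20000)
    except Exception as exc:
        raise RuntimeError(f"relaxation fit failed to converge: {exc}") from exc
    d0, d_inf, tau = popt
    tau = abs(float(tau))
    resid = d - model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    v0 = (d_inf - d0) / tau if tau > 0 else math.inf
    return RelaxationFit(
        d0=float(d0), d_inf=float(d_inf), tau=tau, v0=float(v0), r_squared=r2
    )


def required_cycle_ratio(structure_dims: int, tissue_dims: int) -> float:
    """Cycle-duration ratio needed for a structure growing in
    ``structure_dims`` dimensions to keep pace with a tissue growing in
    ``tissue_dims`` dimensions.

    With exponential proliferation N ~ 2^(t/T), the linear size of an
    n-dimensional isotropically growing region scales as 2^(t/(nT)).
    Matching the structure's length growth to the tissue's radius growth
    requires T_structure = (tissue_dims / structure_dims) * T_tissue: a
    one-dimensional stripe inside a two-dimensional disc must cycle twice
    as slowly as the bulk.
    """
    if structure_dims not in (1, 2) or tissue_dims not in (1, 2):
        raise ValueError("growth dimensions must be 1 or 2")
    return tissue_dims / structure_dims


def phase_cluster_sizes(
    mesh: TissueMesh,
    clocks: Mapping[int, CellClock],
    phase_window: Tuple[float, float],
    t: Optional[float] = None,
) -> Counter:
    """Size distribution of connected clusters of cycle-phase-similar cells.

    Phase is the elapsed fraction of the intended duration; cells whose
    phase lies in ``phase_window`` are selected and their connected
    components on the cell-adjacency graph are counted.  Sibling cells share
    their birth time, so clustering develops from the division process.
    """
    if t is None:
        t = mesh.time
    lo, hi = phase_window
    selected = {
        cid
        for cid, ck in clocks.items()
        if cid in mesh.cells and lo <= ck.elapsed(t) / ck.duration <= hi
    }
    adj = mesh.adjacency()
    seen: Set[int] = set()
    sizes: Counter = Counter()
    for cid in selected:
        if cid in seen:
            continue
        stack, comp = [cid], 0
        seen.add(cid)
        while stack:
            cur = stack.pop()
            comp += 1
            for nb in adj[cur]:
                if nb in selected and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        sizes[comp] += 1
    return sizes
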
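"""Cell identities and the Notch-fence character-maintenance rule.

A cell carries a *character* — organizer ``O`` (Notch-active) or compartment
bulk ``C`` — and an immutable *compartment* label, dorsal ``D`` or ventral
``V``.  Organizer cells straddle the DV interface and act as a physical
fence between the two lineages.  Notch activity at an organizer cell is
sustained by ligands presented by nearby bulk cells (directly or through
filipodia that reach next-nearest neighbors); an O cell that loses every
bulk cell from its first- and second-order neighborhood therefore loses its
character and reverts to C.  The reverse step never happens: a bulk cell
cannot acquire the organizer character during the developmental window
modeled here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Dict, List, Set, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .mesh import TissueMesh

__all__ = [
    "CellIdentity",
    "update_characters",
    "inherit_identity",
    "dv_boundary_edges",
    "boundary_paths",
    "compartment_interface_edges",
    "fence_breach_edges",
]


@dataclass(frozen=True)
class CellIdentity:
    """Identity of one cell.

    character : 'O' (DV organizer, Notch-active) or 'C' (compartment bulk).
    compartment : 'D' (dorsal) or 'V' (ventral); immutable along a lineage.
    clone : fast-cycling clone flag; clone cells keep bulk mechanics.
    """

    character: str = "C"
    compartment: str = "D"
    clone: bool = False

    def __post_init__(self) -> None:
        if self.character not in ("O", "C"):
            raise ValueError(f"character must be 'O' or 'C', got {self.character!r}")
        if self.compartment not in ("D", "V"):
            raise ValueError(f"compartment must be 'D' or 'V', got {self.compartment!r}")

    @property
    def cell_type(self) -> str:
        """Mechanical/cycle type: 'O', 'clone' or 'C'."""
        if self.character == "O":
            return "O"
        return "clone" if self.clone else "C"


def update_characters(
    mesh: "TissueMesh",
    identities: Dict[int, CellIdentity],
    neighbor_order: int = 2,
) -> Tuple[Dict[int, CellIdentity], List[int]]:
    """Apply the character-maintenance rule; return (identities, switched ids).

    An O cell keeps its character iff at least one cell of character C lies
    within its order-1 or order-2 neighborhood (graph distance on the
    cell-adjacency graph, up to ``neighbor_order``).  All switches are
    computed synchronously from the pre-update state, so the outcome does
    not depend on scan order.  C cells never switch.
    """
    switched: List[int] = []
    new = dict(identities)
    for cid, ident in identities.items():
        if ident.character != "O":
            continue
        neigh: Set[int] = mesh.cell_neighbors(cid, order=1)
        if neighbor_order >= 2:
            neigh = neigh | mesh.cell_neighbors(cid, order=2)
        if not any(identities[n].character == "C" for n in neigh):
            new[cid] = replace(ident, character="C")
            switched.append(cid)
    return new, switched


def inherit_identity(mother: CellIdentity) -> Tuple[CellIdentity, CellIdentity]:
    """Both daughters copy the mother's full identity at division."""
    return mother, mother


def dv_boundary_edges(
    mesh: "TissueMesh", identities: Dict[int, CellIdentity]
) -> Set[Tuple[int, int]]:
    """Edges of the DV boundary.

    With organizer cells present these are the edges shared by O cells of
    opposite compartments (the actomyosin-cable edges).  In a tissue with no
    O cells at all, the D/V interface is instead the set of heterotypic
    C(D)-C(V) edges.
    """
    has_organizer = any(i.character == "O" for i in identities.values())
    out: Set[Tuple[int, int]] = set()
    for edge, cells in mesh.edge_map().items():
        if len(cells) != 2:
            continue
        a, b = (identities[c] for c in cells)
        if a.compartment == b.compartment:
            continue
        if has_organizer:
            if a.character == "O" and b.character == "O":
                out.add(edge)
        else:
            out.add(edge)
    return out


def boundary_paths(
    mesh: "TissueMesh", identities: Dict[int, CellIdentity]
) -> List[List[int]]:
    """Ordered vertex paths of the DV boundary (several if it is broken).

    Each path is a sequence of vertex ids walking along consecutive
    boundary edges; an intact organizer yields one path spanning the
    tissue.
    """
    import networkx as nx

    edges = dv_boundary_edges(mesh, identities)
    if not edges:
        return []
    g = nx.Graph(list(edges))
    paths: List[List[int]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [v for v in sub if sub.degree(v) == 1]
        if ends:
            start = min(ends, key=lambda v: mesh.position(v)[0])
        else:  # a closed loop
            start = next(iter(comp))
        order = list(nx.dfs_preorder_nodes(sub, source=start))
        paths.append(order)
    paths.sort(key=lambda p: mesh.position(p[0])[0])
    return paths


def compartment_interface_edges(
    mesh: "TissueMesh", identities: Dict[int, CellIdentity]
) -> Set[Tuple[int, int]]:
    """All interior edges whose two cells carry opposite compartment labels."""
    out = set()
    for edge, cells in mesh.edge_map().items():
        if len(cells) == 2:
            a, b = (identities[c] for c in cells)
            if a.compartment != b.compartment:
                out.add(edge)
    return out


def fence_breach_edges(
    mesh: "TissueMesh", identities: Dict[int, CellIdentity]
) -> Set[Tuple[int, int]]:
    """Heterotypic C(D)-C(V) contacts: violations of the fence property.

    A functional organizer keeps this set empty; any such edge means cells
    of opposite compartments touch without an intervening organizer cell.
    """
    out = set()
    for edge, cells in mesh.edge_map().items():
        if len(cells) == 2:
            a, b = (identities[c] for c in cells)
            if (
                a.character == "C"
                and b.character == "C"
                and a.compartment != b.compartment
            ):
                out.add(edge)
    return out
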
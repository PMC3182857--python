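"""Mesh construction, geometry primitives and adjacency queries."""

import json
import math

import numpy as np
import pytest

import notchfence as nf
from notchfence.mesh import (
    InitialConditionSpec,
    MeshInvalidError,
    build_hex_patch,
    cell_centroid,
    hexagon_side,
    longest_axis,
    polygon_area,
    polygon_perimeter,
    read_snapshot,
    rod_inertia_axes,
    rod_inertia_tensor,
    snapshot_records,
    validate,
    write_snapshot,
)
from notchfence import metrics as mt

from conftest import random_tissue, rectangle_cell_mesh, square_cell_mesh

HEX_SIDE = hexagon_side(1.0)


class TestBuildHexPatch:
    def test_single_hexagon(self):
        mesh, idents = build_hex_patch(InitialConditionSpec(nrows=1, ncols=1))
        assert mesh.n_cells() == 1
        assert mesh.n_vertices() == 6
        assert all(len(cells) == 1 for cells in mesh.edge_map().values())
        assert len(mesh.edge_map()) == 6

    def test_all_cells_regular_hexagons_of_a_ref(self):
        a_ref = 2.5
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=5, ncols=4, a_ref=a_ref))
        for cid in mesh.cells:
            assert polygon_area(mesh, cid) == pytest.approx(a_ref, rel=1e-9)
            assert polygon_perimeter(mesh, cid) == pytest.approx(
                6 * hexagon_side(a_ref), rel=1e-9
            )

    def test_stripe_is_two_cells_wide_on_every_transect(self, hex_mesh):
        mesh, idents = hex_mesh
        widths = mt.organizer_width(mesh, idents, n_transects=25)
        assert (widths["width"] == 2).all()

    def test_compartments_split_by_midline(self, hex_mesh):
        mesh, idents = hex_mesh
        for cid, ident in idents.items():
            y = cell_centroid(mesh, cid)[1]
            mid = 1.5 * HEX_SIDE * 5.5 / 2  # between rows 2 and 3 of 6
            assert (ident.compartment == "D") == (y > mid)

    def test_organizer_rows_split_into_d_and_v(self, hex_mesh):
        _, idents = hex_mesh
        comps = {i.compartment for i in idents.values() if i.character == "O"}
        assert comps == {"D", "V"}

    def test_edge_counts_match_bruteforce_recount(self):
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=4, ncols=5))
        # brute-force recount from the cell cycles
        seen = {}
        for cid, cyc in mesh.cells.items():
            assert len(cyc) == len(set(cyc))  # cell edge count == vertex count
            for k in range(len(cyc)):
                e = tuple(sorted((cyc[k], cyc[(k + 1) % len(cyc)])))
                seen.setdefault(e, []).append(cid)
        emap = mesh.edge_map()
        assert set(emap) == set(seen)
        for e, cells in seen.items():
            assert sorted(emap[e]) == sorted(cells)
        n_int = sum(1 for c in seen.values() if len(c) == 2)
        n_ext = sum(1 for c in seen.values() if len(c) == 1)
        assert n_int + n_ext == len(emap)
        validate(mesh)

    def test_rejects_bad_spec(self):
        with pytest.raises(ValueError):
            InitialConditionSpec(nrows=0, ncols=3)
        with pytest.raises(ValueError):
            InitialConditionSpec(a_ref=-1.0)


class TestGeometry:
    def test_hexagon_area_closed_form(self):
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=1, ncols=1, a_ref=1.0))
        (cid,) = mesh.cells
        # regular hexagon of side s has area 3*sqrt(3)/2 s^2
        s = HEX_SIDE
        assert polygon_area(mesh, cid) == pytest.approx(1.5 * math.sqrt(3) * s * s)

    def test_unit_square(self, square_mesh):
        assert polygon_area(square_mesh, 0) == pytest.approx(1.0)
        assert polygon_perimeter(square_mesh, 0) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_polygons_match_independent_oracles(self, seed):
        from shapely.geometry import Polygon

        r = np.random.default_rng(seed)
        for _ in range(10):
            n = int(r.integers(3, 11))
            angles = np.sort(r.uniform(0, 2 * np.pi, n))
            radii = r.uniform(0.5, 2.0, n)
            pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
            x, y = pts[:, 0], pts[:, 1]
            if np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) < 0:
                pts = pts[::-1]  # enforce the ccw storage convention
            m = nf.TissueMesh()
            cyc = [m.add_vertex(p) for p in pts]
            m.add_cell(cyc)
            assert polygon_area(m, 0) == pytest.approx(Polygon(pts).area, rel=1e-12)
            # pairwise-distance-sum oracle
            per = sum(
                float(np.linalg.norm(pts[(k + 1) % n] - pts[k])) for k in range(n)
            )
            assert polygon_perimeter(m, 0) == pytest.approx(per, rel=1e-12)

    def test_translation_rotation_invariance(self):
        mesh, _ = random_tissue(7)
        cid = next(iter(mesh.cells))
        a0, p0 = polygon_area(mesh, cid), polygon_perimeter(mesh, cid)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mesh.positions[:] = mesh.positions @ rot.T + np.array([3.3, -1.7])
        assert polygon_area(mesh, cid) == pytest.approx(a0, rel=1e-12)
        assert polygon_perimeter(mesh, cid) == pytest.approx(p0, rel=1e-12)

    def test_degenerate_cell_rejected(self):
        m = nf.TissueMesh()
        v = [m.add_vertex(p) for p in [(0, 0), (1, 0)]]
        m.add_cell(v)
        with pytest.raises(MeshInvalidError):
            polygon_area(m, 0)


class TestRodInertia:
    def test_rectangle_longest_axis(self):
        m = rectangle_cell_mesh(2.0, 1.0)
        axis = longest_axis(m, 0)
        assert abs(axis[0]) == pytest.approx(1.0, abs=1e-9)

    def test_regular_hexagon_isotropic(self):
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=1, ncols=1))
        _, moments = rod_inertia_axes(mesh, 0)
        assert moments[1] - moments[0] == pytest.approx(0.0, abs=1e-9 * moments[1])

    def test_eigenvectors_orthogonal_moments_nonnegative(self):
        mesh, _ = random_tissue(3)
        for cid in list(mesh.cells)[:6]:
            directions, moments = rod_inertia_axes(mesh, cid)
            assert moments[0] >= 0
            assert abs(np.dot(directions[:, 0], directions[:, 1])) < 1e-12

    def test_tensor_matches_rod_sampling_oracle(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.1], [2.3, 1.4], [0.7, 1.9], [-0.4, 1.0]])
        m = nf.TissueMesh()
        m.add_cell([m.add_vertex(p) for p in pts])
        tensor = rod_inertia_tensor(m, 0)
        # dense sampling of each edge with uniform line density
        nsamp = 10_000
        samples, weights = [], []
        for k in range(len(pts)):
            p, q = pts[k], pts[(k + 1) % len(pts)]
            t = (np.arange(nsamp) + 0.5) / nsamp
            seg = p[None, :] + t[:, None] * (q - p)[None, :]
            w = np.full(nsamp, np.linalg.norm(q - p) / nsamp)
            samples.append(seg)
            weights.append(w)
        samples = np.vstack(samples)
        weights = np.concatenate(weights)
        com = (samples * weights[:, None]).sum(axis=0) / weights.sum()
        rel = samples - com
        m2 = np.einsum("i,ij,ik->jk", weights, rel, rel)
        oracle = np.trace(m2) * np.eye(2) - m2
        assert np.allclose(tensor, oracle, rtol=1e-6, atol=1e-8)


class TestNeighbors:
    def test_honeycomb_coordination(self):
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=7, ncols=7))
        # pick the central cell: closest centroid to patch center
        centers = {c: cell_centroid(mesh, c) for c in mesh.cells}
        mid = np.mean(list(centers.values()), axis=0)
        cid = min(centers, key=lambda c: np.linalg.norm(centers[c] - mid))
        assert len(mesh.cell_neighbors(cid, order=1)) == 6
        assert len(mesh.cell_neighbors(cid, order=2)) == 12

    def test_corner_cell_fewer_neighbors(self):
        mesh, _ = build_hex_patch(InitialConditionSpec(nrows=3, ncols=3))
        corner = min(
            mesh.cells, key=lambda c: tuple(cell_centroid(mesh, c))
        )
        assert 0 < len(mesh.cell_neighbors(corner, order=1)) < 6

    def test_symmetry_and_bruteforce_scan(self):
        mesh, _ = random_tissue(9, nrows=4, ncols=4)
        # brute-force shared-edge scan
        cells = list(mesh.cells)
        edges_of = {
            c: {
                tuple(sorted((cyc[k], cyc[(k + 1) % len(cyc)])))
                for k in range(len(cyc))
            }
            for c, cyc in mesh.cells.items()
        }
        for a in cells:
            for b in cells:
                if a >= b:
                    continue
                shared = bool(edges_of[a] & edges_of[b])
                assert (b in mesh.cell_neighbors(a, 1)) == shared
                assert (a in mesh.cell_neighbors(b, 1)) == shared


class TestGeometryProperties:
    """Property-based invariance checks on random star-shaped polygons."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _polygon(seed: int, n: int) -> np.ndarray:
        r = np.random.default_rng(seed)
        angles = np.sort(r.uniform(0, 2 * np.pi, n))
        radii = r.uniform(0.5, 2.0, n)
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        x, y = pts[:, 0], pts[:, 1]
        if np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) < 0:
            pts = pts[::-1]
        return pts

    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(3, 12),
        theta=st.floats(-np.pi, np.pi),
        tx=st.floats(-5, 5),
        ty=st.floats(-5, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rigid_motion_invariance_and_inertia_axes(self, seed, n, theta, tx, ty):
        pts = self._polygon(seed, n)
        m = nf.TissueMesh()
        m.add_cell([m.add_vertex(p) for p in pts])
        a0, p0 = polygon_area(m, 0), polygon_perimeter(m, 0)
        _, mom0 = rod_inertia_axes(m, 0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        m.positions[:] = m.positions @ rot.T + np.array([tx, ty])
        assert polygon_area(m, 0) == pytest.approx(a0, rel=1e-10)
        assert polygon_perimeter(m, 0) == pytest.approx(p0, rel=1e-10)
        directions, moments = rod_inertia_axes(m, 0)
        assert moments[0] >= -1e-12
        assert abs(np.dot(directions[:, 0], directions[:, 1])) < 1e-10
        # principal moments are rotation invariant
        assert np.allclose(moments, mom0, rtol=1e-9, atol=1e-12)


class TestSnapshotIO:
    def test_bit_exact_round_trip(self, tmp_path, hex_mesh):
        mesh, idents = hex_mesh
        mesh.positions[:] += np.random.default_rng(0).normal(0, 0.01, mesh.positions.shape)
        mesh.time = 12.3456789012345
        path = tmp_path / "snap.jsonl"
        write_snapshot(path, mesh, idents)
        mesh2, idents2, _ = read_snapshot(path)
        assert mesh2.time == mesh.time
        assert mesh2.n_cells() == mesh.n_cells()
        # bit-exact positions, same identity multiset
        old = {tuple(mesh.positions[v]) for v in mesh.active_vertex_ids()}
        new = {tuple(mesh2.positions[v]) for v in mesh2.active_vertex_ids()}
        assert old == new
        assert sorted(
            (i.character, i.compartment, i.clone) for i in idents.values()
        ) == sorted((i.character, i.compartment, i.clone) for i in idents2.values())

    def test_records_are_json_serializable(self, hex_mesh):
        mesh, idents = hex_mesh
        for rec in snapshot_records(mesh, idents):
            json.dumps(rec)

    def test_vtk_export_structure(self, tmp_path, hex_mesh):
        from notchfence.mesh import write_vtk

        mesh, idents = hex_mesh
        path = tmp_path / "t.vtk"
        write_vtk(path, mesh, idents)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        points_line = next(l for l in text if l.startswith("POINTS"))
        assert int(points_line.split()[1]) == mesh.n_vertices()
        poly_line = next(l for l in text if l.startswith("POLYGONS"))
        assert int(poly_line.split()[1]) == mesh.n_cells()
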
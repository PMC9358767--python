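import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from scutegrow.grid import LabelField
from scutegrow.mesh import SurfaceMesh, icosphere
from scutegrow.morpho import (PBA_SENTINEL, bounding_cuboid_dims,
                              carapace_surface_area, compute_scute_stats,
                              local_curvature, neighbor_counts,
                              normalize_stats, plane_based_area,
                              scute_volumes)
from scutegrow.segment import RegionAdjacencyGraph, build_rag


# ----------------------------------------------------- analytic meshes


def graph_mesh(height_fn, extent=2.0, n=41):
    """Triangulated height-field z = f(x, y) with +z-oriented normals."""
    u, v = np.meshgrid(np.linspace(-extent, extent, n),
                       np.linspace(-extent, extent, n))
    pts = np.column_stack([u.ravel(), v.ravel(),
                           height_fn(u.ravel(), v.ravel())])
    tri = Delaunay(pts[:, :2])
    mesh = SurfaceMesh(pts, tri.simplices)
    flip = mesh.face_normals()[:, 2] < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    mesh.faces = faces
    return mesh


def cylinder_mesh(radius=4.0, n_theta=120, n_z=40):
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-radius, radius, n_z)
    T, Z = np.meshgrid(th, z)
    pts = np.column_stack([radius * np.cos(T).ravel(),
                           radius * np.sin(T).ravel(), Z.ravel()])
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces += [[a, b, c], [b, d, c]]
    mesh = SurfaceMesh(pts, np.array(faces))
    cen = mesh.face_centroids()
    radial = np.column_stack([cen[:, 0], cen[:, 1], np.zeros(len(cen))])
    flip = np.einsum("ij,ij->i", mesh.face_normals(), radial) < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    mesh.faces = faces
    return mesh


def hexagon_rag(pitch=1.0):
    """Scute 1 at origin surrounded by 6 neighbors at unit pitch."""
    g = nx.Graph()
    g.add_node(1, center_mm=np.zeros(3))
    for k in range(6):
        ang = k * np.pi / 3
        g.add_node(2 + k, center_mm=pitch * np.array(
            [np.cos(ang), np.sin(ang), 0.0]))
        g.add_edge(1, 2 + k)
    for k in range(6):
        g.add_edge(2 + k, 2 + (k + 1) % 6)
    return RegionAdjacencyGraph(g)


BELOW = np.array([0.0, 0.0, -10.0])  # inward reference under the z=0 plane


class TestSurfaceArea:
    def test_unit_cube(self):
        v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                      for z in (0, 1)], float)
        f = np.array([[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
                      [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
                      [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6]])
        assert carapace_surface_area(SurfaceMesh(v, f)) == pytest.approx(6.0)

    def test_sphere_r3(self):
        m = icosphere(5)
        m = SurfaceMesh(m.vertices * 3, m.faces)
        assert carapace_surface_area(m) == pytest.approx(36 * np.pi, rel=0.01)

    def test_isometric_scaling_exact(self, shell_mesh):
        assert (carapace_surface_area(shell_mesh.scaled(2.0))
                == pytest.approx(4 * carapace_surface_area(shell_mesh)))


class TestNeighborCounts:
    def test_cube_all_four(self, cube_phantom):
        _, labels, _ = cube_phantom
        deg, freq = neighbor_counts(build_rag(labels))
        assert (deg == 4).all()
        assert freq.loc[4] == 1.0

    def test_modal_six_ordering(self, segmented_phantom):
        _, rag, _ = segmented_phantom
        _, freq = neighbor_counts(rag)
        assert freq.idxmax() == 6
        assert freq.loc[6] > freq.loc[5] > freq.loc[7]

    def test_handshake_lemma(self, segmented_phantom):
        _, rag, _ = segmented_phantom
        deg, _ = neighbor_counts(rag)
        assert deg.sum() == 2 * rag.graph.number_of_edges()


class TestScuteVolumes:
    def test_eight_voxels_at_half_mm(self):
        arr = np.zeros((4, 4, 4), dtype=np.int32)
        arr[1:3, 1:3, 1:3] = 5
        lf = LabelField(arr, [0.5, 0.5, 0.5], [0, 0, 0])
        assert scute_volumes(lf).loc[5] == pytest.approx(1.0)

    def test_partition(self, phantom_valley):
        _, labels, _ = phantom_valley
        total = scute_volumes(labels).sum()
        fg = int((labels.array > 0).sum())
        assert total == pytest.approx(fg * labels.voxel_volume_mm3)


class TestPlaneBasedArea:
    def test_regular_hexagon(self):
        # hand-computed: triangle centroids of consecutive unit vectors
        # lie at radius 1/sqrt(3); regular hexagon area = sqrt(3)/2
        pba = plane_based_area(hexagon_rag(), 1, inward_reference=BELOW)
        assert pba == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_pitch_scaling(self):
        pba = plane_based_area(hexagon_rag(2.0), 1, inward_reference=BELOW)
        assert pba == pytest.approx(4 * np.sqrt(3) / 2, abs=1e-12)

    def test_incomplete_fan_sentinel(self):
        rag = hexagon_rag()
        rag.graph.remove_edge(2, 3)  # break the ring; no bridging quad
        assert plane_based_area(rag, 1, inward_reference=BELOW) == PBA_SENTINEL

    def test_fewer_than_three_neighbors_sentinel(self):
        g = nx.Graph()
        g.add_node(1, center_mm=np.zeros(3))
        g.add_node(2, center_mm=np.array([1.0, 0, 0]))
        g.add_edge(1, 2)
        assert plane_based_area(RegionAdjacencyGraph(g), 1,
                                inward_reference=BELOW) == PBA_SENTINEL

    def test_quad_fan_element(self):
        # remove one ring edge but add a bridging scute adjacent to both:
        # fan completes with a quad instead of a triangle
        rag = hexagon_rag()
        rag.graph.remove_edge(2, 3)
        rag.graph.add_node(10, center_mm=np.array([1.2, 0.7, 0.0]))
        rag.graph.add_edge(2, 10)
        rag.graph.add_edge(3, 10)
        pba = plane_based_area(rag, 1, inward_reference=BELOW)
        assert pba > 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(R) < 0:
            R[:, 0] = -R[:, 0]
        t = np.array([3.0, -2.0, 5.0])
        rag = hexagon_rag()
        moved = hexagon_rag()
        for n in moved.graph.nodes:
            moved.graph.nodes[n]["center_mm"] = (
                R @ moved.graph.nodes[n]["center_mm"] + t)
        a = plane_based_area(rag, 1, inward_reference=BELOW)
        b = plane_based_area(moved, 1, inward_reference=R @ BELOW + t)
        assert a == pytest.approx(b, abs=1e-9)

    def test_partition_approximates_sa(self, segmented_phantom):
        # fan polygons tile the dual surface: sum of PBAs ~ mesh SA
        pred, rag, surface = segmented_phantom
        pbas = [plane_based_area(rag, l) for l in rag.node_ids]
        valid = [p for p in pbas if p != PBA_SENTINEL]
        assert sum(valid) == pytest.approx(surface.area(), rel=0.10)


class TestBoundingCuboid:
    def test_axis_aligned_slab(self):
        arr = np.zeros((12, 6, 3), dtype=np.int32)
        arr[1:11, 1:5, 1] = 7
        lf = LabelField(arr, [1, 1, 1], [0, 0, 0])
        thickness, width = bounding_cuboid_dims(lf, 7)
        assert thickness == pytest.approx(1.0)
        assert width == pytest.approx(10.0)

    def test_rotated_slab_fine_voxels(self):
        # exact rotated-box oracle: 10 x 4 x 1 mm box rotated 45 deg
        # about z, re-voxelized at 0.1 mm
        ang = np.pi / 4
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        sp = 0.1
        n = int(12 / sp)
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        world = (np.stack([ii, jj, kk], -1) + 0.5) * sp - 6.0
        local = world.reshape(-1, 3) @ R  # rotate back into box frame
        inside = (np.abs(local[:, 0]) <= 5.0) & (np.abs(local[:, 1]) <= 2.0) \
            & (np.abs(local[:, 2]) <= 0.5)
        arr = inside.reshape(n, n, n).astype(np.int32)
        lf = LabelField(arr, [sp] * 3, [-6.0] * 3)
        thickness, width = bounding_cuboid_dims(lf, 1)
        assert thickness == pytest.approx(1.0, rel=0.10)
        assert width == pytest.approx(10.0, rel=0.10)

    def test_thickness_never_exceeds_width(self, phantom_valley):
        _, labels, _ = phantom_valley
        for lbl in list(labels.voxel_counts())[:40]:
            thickness, width = bounding_cuboid_dims(labels, lbl)
            assert thickness <= width

    def test_single_voxel_warns(self):
        arr = np.zeros((3, 3, 3), dtype=np.int32)
        arr[1, 1, 1] = 1
        lf = LabelField(arr, [0.5, 0.5, 0.5], [0, 0, 0])
        with pytest.warns(UserWarning, match="single voxel"):
            thickness, width = bounding_cuboid_dims(lf, 1)
        assert thickness == pytest.approx(0.5)

    def test_missing_label_raises(self):
        lf = LabelField(np.ones((2, 2, 2), np.int32), [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError, match="not present"):
            bounding_cuboid_dims(lf, 9)


class TestCurvature:
    def test_plane_zero(self):
        mesh = graph_mesh(lambda x, y: np.zeros_like(x))
        K, H = local_curvature(mesh, [0, 0, 0], 1.0)
        assert abs(K) < 1e-3
        assert abs(H) < 1e-3

    def test_sphere_r5(self):
        m = icosphere(5)
        mesh = SurfaceMesh(m.vertices * 5, m.faces)
        K, H = local_curvature(mesh, [0, 0, 5.0], 1.0)
        assert K == pytest.approx(0.04, rel=0.05)
        assert H == pytest.approx(0.2, rel=0.05)

    def test_cylinder_r4(self):
        K, H = local_curvature(cylinder_mesh(4.0), [4.0, 0, 0], 1.2)
        assert abs(K) < 0.01
        assert H == pytest.approx(0.125, rel=0.05)

    def test_saddle_negative_gauss(self):
        mesh = graph_mesh(lambda x, y: (x**2 - y**2) / 4.0)
        K, H = local_curvature(mesh, [0, 0, 0], 1.0)
        assert K < 0

    def test_concave_bowl_negative_mean(self):
        # concave (bowl up, normals up): H < 0 under the outward-positive
        # convention
        mesh = graph_mesh(lambda x, y: (x**2 + y**2) / 8.0)
        K, H = local_curvature(mesh, [0, 0, 0], 1.0)
        assert H < 0
        assert K > 0

    def test_insufficient_support_raises(self):
        mesh = graph_mesh(lambda x, y: np.zeros_like(x), n=5)
        with pytest.raises(ValueError, match="insufficient support"):
            local_curvature(mesh, [0, 0, 0], 0.01)


class TestScuteStats:
    def test_cube_rows(self, cube_phantom):
        _, labels, _ = cube_phantom
        from scutegrow.segment import extract_surface
        rag = build_rag(labels)
        mesh = extract_surface(labels)
        stats = compute_scute_stats(labels, rag, mesh)
        assert len(stats) == 6
        assert (stats["n_neighbors"] == 4).all()
        # face-center scutes of a near-cube are flat
        assert (stats["gaussK_per_mm2"].abs() < 0.02).all()

    def test_row_count_after_exclusion(self, segmented_phantom):
        pred, rag, surface = segmented_phantom
        drop = tuple(rag.node_ids[:5])
        stats = compute_scute_stats(pred, rag, surface, exclude_labels=drop)
        assert len(stats) == len(rag.node_ids) - 5
        assert not set(drop) & set(stats["scute_id"])

    def test_pba_contract(self, segmented_phantom):
        pred, rag, surface = segmented_phantom
        stats = compute_scute_stats(pred, rag, surface)
        pba = stats["pba_mm2"]
        assert ((pba > 0) | (pba == PBA_SENTINEL)).all()

    def test_am_gm_inequality(self, segmented_phantom):
        pred, rag, surface = segmented_phantom
        stats = compute_scute_stats(pred, rag, surface)
        ok = stats.dropna(subset=["gaussK_per_mm2", "meanH_per_mm"])
        assert (ok["gaussK_per_mm2"]
                <= ok["meanH_per_mm"] ** 2 + 1e-9).all()


class TestNormalize:
    def test_arithmetic(self):
        stats = pd.DataFrame(
            {"volume_mm3": [8.0], "pba_mm2": [2.0], "thickness_mm": [1.0],
             "width_mm": [2.0], "gaussK_per_mm2": [0.5],
             "meanH_per_mm": [0.25]}
        )
        out = normalize_stats(stats, 4.0)
        assert out["volume_norm"].iloc[0] == pytest.approx(1.0)
        assert out["pba_norm"].iloc[0] == pytest.approx(0.5)
        assert out["thickness_norm"].iloc[0] == pytest.approx(0.5)
        assert out["width_norm"].iloc[0] == pytest.approx(1.0)
        assert out["gaussK_norm"].iloc[0] == pytest.approx(2.0)
        assert out["meanH_norm"].iloc[0] == pytest.approx(0.5)

    def test_isometric_pair_invariance(self):
        rng = np.random.default_rng(0)
        n = 50
        base = pd.DataFrame(
            {"volume_mm3": rng.uniform(1, 2, n),
             "pba_mm2": rng.uniform(1, 3, n),
             "thickness_mm": rng.uniform(0.2, 0.5, n),
             "width_mm": rng.uniform(1, 2, n),
             "gaussK_per_mm2": rng.normal(0, 0.01, n),
             "meanH_per_mm": rng.normal(0.1, 0.02, n)}
        )
        s = 3.0
        scaled = base.copy()
        scaled["volume_mm3"] *= s**3
        scaled["pba_mm2"] *= s**2
        scaled["thickness_mm"] *= s
        scaled["width_mm"] *= s
        scaled["gaussK_per_mm2"] /= s**2
        scaled["meanH_per_mm"] /= s
        a = normalize_stats(base, 10.0)
        b = normalize_stats(scaled, 10.0 * s**2)
        for col in ["volume_norm", "pba_norm", "thickness_norm",
                    "width_norm", "gaussK_norm", "meanH_norm"]:
            assert np.allclose(a[col], b[col], atol=1e-9), col

    def test_sentinel_rows_excluded(self):
        stats = pd.DataFrame(
            {"volume_mm3": [1.0, 1.0], "pba_mm2": [2.0, PBA_SENTINEL],
             "thickness_mm": [1, 1], "width_mm": [2, 2],
             "gaussK_per_mm2": [0, 0], "meanH_per_mm": [0, 0]}
        )
        out = normalize_stats(stats, 4.0)
        assert np.isnan(out["pba_norm"].iloc[1])

    def test_nonpositive_sa_raises(self):
        with pytest.raises(ValueError):
            normalize_stats(pd.DataFrame(), 0.0)
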
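"""Per-scute morphometrics of a segmented carapace.

Seven variables per scute: neighbor count (RAG degree), voxel volume,
plane-based area (PBA) from the triangle/quad fan around the scute's
RAG node, enclosing-cuboid thickness and width, and local Gaussian and
mean surface curvature from a quadric fit.  Plane-based measures of
scutes with incomplete fans (at carapace openings) are set to the
sentinel -1000.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import LabelField
from .mesh import SurfaceMesh
from .segment import RegionAdjacencyGraph

PBA_SENTINEL = -1000.0


def carapace_surface_area(mesh: SurfaceMesh) -> float:
    """Total area of the outer surface mesh (mm^2)."""
    return mesh.area()


def neighbor_counts(rag: RegionAdjacencyGraph):
    """Per-scute neighbor counts and their relative-frequency table.

    Returns (Series indexed by scute id, Series indexed by count).
    """
    deg = pd.Series(
        {lbl: rag.degree(lbl) for lbl in rag.node_ids}, name="n_neighbors"
    ).sort_index()
    freq = deg.value_counts(normalize=True).sort_index()
    freq.name = "relative_frequency"
    return deg, freq


def scute_volumes(labels: LabelField) -> pd.Series:
    """Voxel count x voxel volume per scute (mm^3)."""
    counts = labels.voxel_counts()
    vv = labels.voxel_volume_mm3
    return pd.Series(
        {lbl: n * vv for lbl, n in counts.items()}, name="volume_mm3"
    ).sort_index()


# ----------------------------------------------------------------- PBA


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: (point on plane, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[-1]


def _local_outward(center: np.ndarray, neighbor_centers: np.ndarray,
                   inward_reference: np.ndarray) -> np.ndarray:
    """Unit normal of the neighborhood plane, oriented away from the
    carapace interior (``inward_reference`` = e.g. mean of all centers)."""
    pts = np.vstack([center[None, :], neighbor_centers])
    _, n = _tls_plane(pts)
    if np.dot(n, center - inward_reference) < 0:
        n = -n
    return n


def _angular_order(center, normal, points) -> np.ndarray:
    """Indices of ``points`` sorted by angle about ``center`` in the
    plane orthogonal to ``normal``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = points - center
    ang = np.arctan2(rel @ e2, rel @ e1)
    return np.argsort(ang, kind="stable")


def _fan_nodes(rag: RegionAdjacencyGraph, scute_id: int,
               inward_reference: np.ndarray):
    """Centers of the triangle/quad fan elements around a scute node.

    Returns (nodes array, outward normal) or None if the fan is
    incomplete (scute borders an opening or has < 3 neighbors).
    """
    nbrs = rag.neighbors(scute_id)
    if len(nbrs) < 3:
        return None
    s = rag.center(scute_id)
    ncen = np.array([rag.center(n) for n in nbrs])
    normal = _local_outward(s, ncen, inward_reference)
    order = _angular_order(s, normal, ncen)
    ring = [nbrs[i] for i in order]
    nbr_set = set(nbrs)

    nodes = []
    for i in range(len(ring)):
        a, b = ring[i], ring[(i + 1) % len(ring)]
        if rag.adjacent(a, b):
            nodes.append((s + rag.center(a) + rag.center(b)) / 3.0)
            continue
        # quad: unique common neighbor bridging the gap, itself not a
        # neighbor of the scute (else it would sit inside the ring)
        common = (set(rag.neighbors(a)) & set(rag.neighbors(b))) - {scute_id}
        common -= nbr_set
        if len(common) != 1:
            return None
        m = common.pop()
        nodes.append((s + rag.center(a) + rag.center(m) + rag.center(b)) / 4.0)
    return np.array(nodes), normal


def plane_based_area(
    rag: RegionAdjacencyGraph, scute_id: int,
    inward_reference: np.ndarray | None = None,
) -> float:
    """Projected polygon area of the fan around a scute, or -1000.

    The fan nodes are fitted with a total-least-squares plane, the
    plane is translated to contain the scute center, the nodes are
    projected onto it, ordered by angle about the projected center, and
    the shoelace area of that polygon is returned.  Scutes whose node
    is not completely surrounded by triangles/quads get the sentinel.
    """
    if inward_reference is None:
        inward_reference = np.mean([rag.center(l) for l in rag.node_ids], axis=0)
    fan = _fan_nodes(rag, scute_id, inward_reference)
    if fan is None:
        return PBA_SENTINEL
    nodes, outward = fan
    s = rag.center(scute_id)
    _, normal = _tls_plane(nodes)
    if np.dot(normal, outward) < 0:
        normal = -normal
    # plane translated to contain the scute center
    proj = nodes - np.outer((nodes - s) @ normal, normal)
    # 2D coordinates in the plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = proj - s
    uv = np.column_stack([rel @ e1, rel @ e2])
    ctr = uv.mean(axis=0)
    order = np.argsort(np.arctan2(uv[:, 1] - ctr[1], uv[:, 0] - ctr[0]))
    poly = uv[order]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area)


# -------------------------------------------------------------- cuboid


def bounding_cuboid_dims(labels: LabelField, scute_id: int) -> tuple[float, float]:
    """(thickness, width) of the principal-axis cuboid enclosing a scute.

    Axes come from the covariance of the scute's voxel-center world
    coordinates; the extent along each axis is (max - min projection)
    plus the projected voxel footprint (support correction).  Thickness
    is the smallest extent, width the largest.
    """
    idx = np.argwhere(labels.array == scute_id)
    if len(idx) == 0:
        raise ValueError(f"label {scute_id} not present")
    pts = labels.world_coords(idx)
    return _cuboid_from_points(pts, labels.voxel_spacing_mm, scute_id)


def _cuboid_from_points(pts: np.ndarray, sp: np.ndarray, scute_id) -> tuple[float, float]:
    if len(pts) == 1:
        warnings.warn(f"scute {scute_id} is a single voxel; degenerate cuboid")
        return float(sp.min()), float(sp.max())
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs.T  # rows are unit axes
    extents = []
    for a in axes:
        proj = pts @ a
        support = float(np.abs(a) @ sp)  # voxel box projected on the axis
        extents.append(float(proj.max() - proj.min()) + support)
    extents = sorted(extents)
    return extents[0], extents[-1]


def _points_by_label(labels: LabelField) -> dict[int, np.ndarray]:
    """World coordinates of each label's voxels, one array pass."""
    idx = np.argwhere(labels.array > 0)
    vals = labels.array[labels.array > 0]
    world = labels.world_coords(idx)
    order = np.argsort(vals, kind="stable")
    vals_s = vals[order]
    world_s = world[order]
    bounds = np.searchsorted(vals_s, np.unique(vals_s))
    out = {}
    uniq = np.unique(vals_s)
    for i, lbl in enumerate(uniq):
        hi = bounds[i + 1] if i + 1 < len(uniq) else len(vals_s)
        out[int(lbl)] = world_s[bounds[i]:hi]
    return out


# ----------------------------------------------------------- curvature


def local_curvature(
    mesh: SurfaceMesh, center_mm, radius_mm: float,
    _tree: cKDTree | None = None, _vnormals: np.ndarray | None = None,
) -> tuple[float, float]:
    """(Gaussian K, mean H) of the surface near a point via quadric fit.

    Mesh vertices within ``radius_mm`` of the center are expressed in a
    tangent frame built from their area-weighted average outward
    normal, a quadric height function is fitted by least squares, and
    the principal curvatures are the eigenvalues of the shape operator
    at the origin.  Outward normals with a locally convex (outward
    bulging) surface give H > 0.
    """
    center = np.asarray(center_mm, dtype=float).reshape(3)
    tree = _tree if _tree is not None else cKDTree(mesh.vertices)
    idx = tree.query_ball_point(center, r=float(radius_mm))
    if len(idx) < 6:
        raise ValueError(
            f"insufficient support: {len(idx)} vertices within "
            f"{radius_mm} mm of {tuple(center)}"
        )
    pts = mesh.vertices[idx]
    vn = _vnormals if _vnormals is not None else mesh.vertex_normals()
    normal = vn[idx].mean(axis=0)
    normal /= np.linalg.norm(normal)

    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    rel = pts - center
    u = rel @ e1
    v = rel @ e2
    h = rel @ normal
    # h(u,v) = 1/2 (a u^2 + 2b uv + c v^2) + d u + e v + f
    A = np.column_stack([0.5 * u**2, u * v, 0.5 * v**2, u, v, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(A, h, rcond=None)
    a, b, c, d, e, _f = coef
    # first/second fundamental forms of the graph (u, v, h(u,v))
    W = np.sqrt(1.0 + d**2 + e**2)
    I = np.array([[1 + d**2, d * e], [d * e, 1 + e**2]])
    II = np.array([[a, b], [b, c]]) / W
    S = np.linalg.solve(I, II)
    # height measured along the outward normal: convex caps curve away
    # from it, so negate to get the outward-positive convention
    k1, k2 = -np.linalg.eigvals(S).real
    return float(k1 * k2), float((k1 + k2) / 2.0)


# ------------------------------------------------------------ assembly


def compute_scute_stats(
    labels: LabelField,
    rag: RegionAdjacencyGraph,
    mesh: SurfaceMesh,
    exclude_labels: tuple[int, ...] = (),
    curvature_radius_multiplier: float = 0.75,
) -> pd.DataFrame:
    """One row per scute with the seven morphometric variables.

    The scute center is the voxel centroid projected to the nearest
    point of the outer mesh; the curvature neighborhood radius is
    ``multiplier * sqrt(median PBA of non-border scutes)``, which keeps
    K*SA and H*sqrt(SA) size-free.  ``exclude_labels`` (e.g. horns) are
    dropped before any computation.
    """
    keep = [l for l in rag.node_ids if l not in set(exclude_labels)]
    inward_ref = np.mean([rag.center(l) for l in keep], axis=0)

    pbas = {l: plane_based_area(rag, l, inward_ref) for l in keep}
    valid = [p for p in pbas.values() if p != PBA_SENTINEL]
    if not valid:
        raise ValueError("no scute has a complete fan; cannot set curvature scale")
    radius = curvature_radius_multiplier * float(np.sqrt(np.median(valid)))

    vols = scute_volumes(labels)
    vtree = cKDTree(mesh.vertices)
    vnormals = mesh.vertex_normals()
    pts_by_label = _points_by_label(labels)
    sp = labels.voxel_spacing_mm

    rows = []
    for lbl in keep:
        pts = pts_by_label[lbl]
        centroid = pts.mean(axis=0)
        _, vi = vtree.query(centroid)
        center = mesh.vertices[vi]
        thickness, width = _cuboid_from_points(pts, sp, lbl)
        try:
            K, H = local_curvature(mesh, center, radius, _tree=vtree,
                                   _vnormals=vnormals)
        except ValueError:
            K, H = np.nan, np.nan
        rows.append(
            {
                "scute_id": lbl,
                "n_neighbors": rag.degree(lbl),
                "volume_mm3": float(vols.get(lbl, 0.0)),
                "pba_mm2": pbas[lbl],
                "thickness_mm": thickness,
                "width_mm": width,
                "gaussK_per_mm2": K,
                "meanH_per_mm": H,
                "center_x_mm": center[0],
                "center_y_mm": center[1],
                "center_z_mm": center[2],
                "border": pbas[lbl] == PBA_SENTINEL,
            }
        )
    return pd.DataFrame(rows)


def normalize_stats(stats: pd.DataFrame, sa_mm2: float) -> pd.DataFrame:
    """Add dimensionless columns: volume/SA^{3/2}, pba/SA,
    thickness/SA^{1/2}, width/SA^{1/2}, K*SA, H*SA^{1/2}.

    Sentinel PBA rows get NaN in the normalized PBA column so they drop
    out of downstream summaries.
    """
    if sa_mm2 <= 0:
        raise ValueError("SA must be positive")
    out = stats.copy()
    rt = np.sqrt(sa_mm2)
    out["volume_norm"] = out["volume_mm3"] / sa_mm2**1.5
    pba = out["pba_mm2"].where(out["pba_mm2"] != PBA_SENTINEL)
    out["pba_norm"] = pba / sa_mm2
    out["thickness_norm"] = out["thickness_mm"] / rt
    out["width_norm"] = out["width_mm"] / rt
    out["gaussK_norm"] = out["gaussK_per_mm2"] * sa_mm2
    out["meanH_norm"] = out["meanH_per_mm"] * rt
    return out
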
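"""Seed-based scute segmentation of intensity volumes.

Workflow: threshold -> multi-source best-first contour propagation from
per-scute seed landmarks (optionally dividing intensity by the distance
to the seed), region adjacency graph, and batch split/merge editing.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .grid import IntensityVolume, LabelField
from .mesh import SurfaceMesh

__all__ = [
    "SeedSet", "RegionAdjacencyGraph", "threshold_segment",
    "propagate_contours", "build_rag", "merge_labels", "split_label",
    "extract_surface",
]


@dataclass
class SeedSet:
    """One (label id, world position mm) landmark per intended scute."""

    seeds: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        ids = [lbl for lbl, _ in self.seeds]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seed labels: {dup}")
        self.seeds = [(int(lbl), np.asarray(p, dtype=float).reshape(3))
                      for lbl, p in self.seeds]

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)


@dataclass
class RegionAdjacencyGraph:
    """Undirected region adjacency graph over scute labels.

    Nodes carry ``center_mm`` (voxel centroid, world coords) and
    ``n_voxels``; edges carry ``contact_faces`` (count of 6-adjacent
    voxel pairs with the two labels).
    """

    graph: nx.Graph

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    def center(self, label: int) -> np.ndarray:
        return self.graph.nodes[label]["center_mm"]

    def neighbors(self, label: int) -> list[int]:
        return sorted(self.graph.neighbors(label))

    def degree(self, label: int) -> int:
        return self.graph.degree[label]

    def adjacent(self, a: int, b: int) -> bool:
        return self.graph.has_edge(a, b)


# ----------------------------------------------------------- threshold


def threshold_segment(
    volume: IntensityVolume, tau: float, largest_component: bool = False
) -> np.ndarray:
    """Binary foreground mask ``intensity >= tau``.

    With ``largest_component`` only the biggest 6-connected component is
    kept (batch stand-in for manual removal of stray structures).
    """
    mask = volume.array >= tau
    if not mask.any():
        raise ValueError(f"empty foreground at tau={tau}")
    if largest_component:
        lab, n = ndimage.label(mask, structure=_FACE_STRUCT)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


# --------------------------------------------------------- propagation


def propagate_contours(
    volume: IntensityVolume,
    mask: np.ndarray,
    seeds: SeedSet,
    mode: str = "distance_modified",
    distance_reference: str = "own_landmark",
) -> LabelField:
    """Multi-source best-first region growing over the masked voxels.

    Each region starts at its seed voxel; a single global max-priority
    queue holds frontier voxels (6-connected neighbors of labeled
    voxels inside the mask).  Priority is the voxel intensity in
    ``plain`` mode; in ``distance_modified`` mode the intensity is
    divided by the Euclidean world distance between the voxel and the
    candidate region's seed landmark (floored at the smallest voxel
    spacing).  Ties break on (lower candidate label, lexicographic voxel
    index), so the output is deterministic.

    ``distance_reference='nearest_landmark'`` divides by the distance to
    the nearest of all landmarks instead of the candidate's own.
    """
    if mode not in ("plain", "distance_modified"):
        raise ValueError(f"unknown mode: {mode}")
    if distance_reference not in ("own_landmark", "nearest_landmark"):
        raise ValueError(f"unknown distance_reference: {distance_reference}")

    shape = volume.shape
    intens = volume.array.astype(np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")

    seed_pos: dict[int, np.ndarray] = {}
    seed_idx: dict[int, tuple[int, int, int]] = {}
    for lbl, p in seeds:
        idx = volume.index_of(p)
        if not mask[idx]:
            raise ValueError(f"seed {lbl} at {tuple(p)} lies outside the mask")
        seed_pos[lbl] = p
        seed_idx[lbl] = idx

    if distance_reference == "nearest_landmark":
        landmark_tree = cKDTree(np.array([p for p in seed_pos.values()]))

    spacing = volume.voxel_spacing_mm
    origin = volume.origin_mm
    dist_floor = float(spacing.min())
    strides = np.array(
        [shape[1] * shape[2], shape[2], 1], dtype=np.int64
    )  # C-order flat index = lexicographic (i, j, k)

    def world(idx):
        return origin + (np.asarray(idx, dtype=float) + 0.5) * spacing

    def priority(idx, lbl) -> float:
        inten = intens[idx]
        if mode == "plain":
            return inten
        if distance_reference == "own_landmark":
            d = float(np.linalg.norm(world(idx) - seed_pos[lbl]))
        else:
            d, _ = landmark_tree.query(world(idx))
            d = float(d)
        return inten / max(d, dist_floor)

    labels = np.zeros(shape, dtype=np.int32)
    heap: list[tuple[float, int, int]] = []  # (-priority, label, flat index)

    neighbor_offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
                        (0, 0, -1), (0, 0, 1)]

    def push_neighbors(idx, lbl):
        i, j, k = idx
        for di, dj, dk in neighbor_offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if labels[ni, nj, nk] or not mask[ni, nj, nk]:
                continue
            flat = int(ni * strides[0] + nj * strides[1] + nk)
            heapq.heappush(heap, (-priority((ni, nj, nk), lbl), lbl, flat))

    for lbl in sorted(seed_idx):
        idx = seed_idx[lbl]
        if labels[idx]:
            raise ValueError(f"seeds {labels[idx]} and {lbl} share voxel {idx}")
        labels[idx] = lbl
    for lbl in sorted(seed_idx):
        push_neighbors(seed_idx[lbl], lbl)

    while heap:
        _, lbl, flat = heapq.heappop(heap)
        idx = (flat // strides[0], (flat // strides[1]) % shape[1], flat % shape[2])
        if labels[idx]:
            continue
        labels[idx] = lbl
        push_neighbors(idx, lbl)

    return LabelField(labels, volume.voxel_spacing_mm, volume.origin_mm)


# ----------------------------------------------------------------- RAG


def build_rag(labels: LabelField, min_contact_faces: int = 1) -> RegionAdjacencyGraph:
    """RAG with an edge wherever two labels touch across >= N voxel faces."""
    arr = labels.array
    pair_counts: dict[tuple[int, int], int] = {}
    for ax in range(3):
        a = np.take(arr, np.arange(arr.shape[ax] - 1), axis=ax).ravel()
        b = np.take(arr, np.arange(1, arr.shape[ax]), axis=ax).ravel()
        m = (a != b) & (a > 0) & (b > 0)
        if not m.any():
            continue
        lo = np.minimum(a[m], b[m]).astype(np.int64)
        hi = np.maximum(a[m], b[m]).astype(np.int64)
        key = lo * (int(arr.max()) + 1) + hi
        uniq, counts = np.unique(key, return_counts=True)
        base = int(arr.max()) + 1
        for k, c in zip(uniq, counts):
            pair = (int(k // base), int(k % base))
            pair_counts[pair] = pair_counts.get(pair, 0) + int(c)

    g = nx.Graph()
    idx = np.argwhere(arr > 0)
    vals = arr[arr > 0]
    world = labels.world_coords(idx)
    for lbl in np.unique(vals):
        m = vals == lbl
        g.add_node(
            int(lbl),
            center_mm=world[m].mean(axis=0),
            n_voxels=int(m.sum()),
        )
    for (a, b), c in pair_counts.items():
        if c >= min_contact_faces:
            g.add_edge(a, b, contact_faces=c)
    return RegionAdjacencyGraph(g)


# --------------------------------------------------------- split/merge


def merge_labels(
    labels: LabelField, rag: RegionAdjacencyGraph, groups: list[set[int]]
) -> tuple[LabelField, RegionAdjacencyGraph]:
    """Merge each RAG-connected group into its smallest label id.

    Label ids are compacted to 1..N afterwards and the RAG recomputed.
    """
    for grp in groups:
        grp = set(grp)
        missing = grp - set(rag.graph.nodes)
        if missing:
            raise ValueError(f"unknown labels in group: {sorted(missing)}")
        sub = rag.graph.subgraph(grp)
        if len(grp) > 1 and not nx.is_connected(sub):
            comps = [sorted(c) for c in nx.connected_components(sub)]
            raise ValueError(f"group {sorted(grp)} not connected; components {comps}")
    arr = labels.array.copy()
    for grp in groups:
        target = min(grp)
        for lbl in grp:
            arr[arr == lbl] = target
    merged = LabelField(arr, labels.voxel_spacing_mm, labels.origin_mm).compacted()
    return merged, build_rag(merged)


def split_label(
    volume: IntensityVolume,
    labels: LabelField,
    target_id: int,
    two_seeds: SeedSet,
    mode: str = "distance_modified",
) -> LabelField:
    """Re-segment one label with two seeds; the first keeps target_id."""
    if len(two_seeds) != 2:
        raise ValueError("split requires exactly two seeds")
    arr = labels.array
    if not (arr == target_id).any():
        raise ValueError(f"label {target_id} not present")
    region = arr == target_id
    idxs = [volume.index_of(p) for _, p in two_seeds]
    for (lbl, p), idx in zip(two_seeds, idxs):
        if not region[idx]:
            raise ValueError(f"seed {lbl} lies outside label {target_id}")
    if idxs[0] == idxs[1]:
        raise ValueError("the two split seeds fall in the same voxel")

    fresh = int(arr.max()) + 1
    local_seeds = SeedSet([(target_id, two_seeds.seeds[0][1]),
                           (fresh, two_seeds.seeds[1][1])])
    sub = propagate_contours(volume, region, local_seeds, mode=mode)
    out = arr.copy()
    out[region] = sub.array[region]
    return LabelField(out, labels.voxel_spacing_mm, labels.origin_mm)


# ------------------------------------------------------------- surface


def extract_surface(
    labels_or_mask, spacing=None, origin=None, smoothing_sigma: float = 1.0
) -> SurfaceMesh:
    """Triangulated outer isosurface of the foreground, outward normals.

    Accepts a LabelField (faces get the label of the nearest foreground
    voxel) or a bare boolean mask plus spacing/origin.  The binary field
    is Gaussian-smoothed (``smoothing_sigma`` voxels) before marching
    cubes to suppress the staircase area inflation of binary
    isosurfaces; only the largest closed component by area is kept,
    dropping internal cavity walls.
    """
    if isinstance(labels_or_mask, LabelField):
        label_arr = labels_or_mask.array
        fg = label_arr > 0
        spacing = labels_or_mask.voxel_spacing_mm
        origin = labels_or_mask.origin_mm
    else:
        fg = np.asarray(labels_or_mask, dtype=bool)
        label_arr = None
        if spacing is None:
            spacing = np.ones(3)
        if origin is None:
            origin = np.zeros(3)
        spacing = np.asarray(spacing, dtype=float)
        origin = np.asarray(origin, dtype=float)
    if not fg.any():
        raise ValueError("empty foreground")

    padded = np.pad(fg.astype(np.float32), 2)
    if smoothing_sigma > 0:
        padded = ndimage.gaussian_filter(padded, sigma=smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 2.0 + 0.5) * spacing + origin  # voxel-center frame
    mesh = SurfaceMesh(verts, faces)

    comps = mesh.split_components()
    best = None
    best_area = -1.0
    for comp in comps:
        sub = mesh.submesh(comp)
        if not sub.is_closed_manifold():
            continue
        a = sub.area()
        if a > best_area:
            best, best_area = sub, a
    if best is None:
        raise ValueError("foreground has no closed surface component")
    if best.signed_volume() < 0:  # enforce outward orientation
        best.faces = best.faces[:, ::-1]

    if label_arr is not None:
        fg_idx = np.argwhere(fg)
        fg_world = origin + (fg_idx + 0.5) * spacing
        tree = cKDTree(fg_world)
        _, nearest = tree.query(best.face_centroids())
        best.face_labels = label_arr[fg][nearest].astype(np.int64)
    return best


# ------------------------------------------------------------- scoring


def voxel_agreement(pred: LabelField, truth: LabelField) -> float:
    """Fraction of true-foreground voxels with the correct label."""
    t = truth.array
    fg = t > 0
    return float((pred.array[fg] == t[fg]).mean())


def dice_per_label(pred: LabelField, truth: LabelField) -> dict[int, float]:
    out = {}
    p, t = pred.array, truth.array
    for lbl in truth.labels():
        a = p == lbl
        b = t == lbl
        denom = int(a.sum()) + int(b.sum())
        out[int(lbl)] = 2.0 * int((a & b).sum()) / denom if denom else 0.0
    return out
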
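"""Synthetic tessellated shells: superellipsoid carapace phantoms with
full ground truth.

A shell is the outer surface of a superellipsoid
``|x/a|^p + |y/b|^p + |z/c|^p = 1`` (p=2 ellipsoid, large p box-like),
tiled into polygonal scutes by a Lloyd-relaxed surface Voronoi
tessellation, and optionally rendered as a labeled voxel volume with a
configurable intensity "valley" along scute boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import IntensityVolume, LabelField
from .mesh import SurfaceMesh, icosphere

PLATEAU = 200.0  # default in-scute intensity


@dataclass
class Opening:
    """Angular hole in the shell (mouth/eye/fin-insertion stand-in)."""

    center_direction: np.ndarray  # unit 3-vector
    angular_radius: float  # radians

    def __post_init__(self) -> None:
        d = np.asarray(self.center_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("opening direction must be nonzero")
        self.center_direction = d / n
        if not 0 < self.angular_radius < np.pi:
            raise ValueError("angular_radius must be in (0, pi)")


@dataclass
class ShellSpec:
    """Parameters of one synthetic carapace."""

    length_mm: float
    height_mm: float
    width_mm: float
    boxiness: float = 4.0  # superellipsoid exponent p, >= 2
    shell_thickness_mm: float = 0.6
    n_scutes: int = 370
    openings: list[Opening] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_mm", "height_mm", "width_mm", "shell_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.boxiness < 2:
            raise ValueError("boxiness must be >= 2")
        if self.n_scutes < 12:
            raise ValueError("n_scutes must be >= 12")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.length_mm, self.height_mm, self.width_mm]) / 2.0


@dataclass
class GroundTruth:
    """Per-scute and specimen-level truth for a tessellated shell."""

    centers_mm: dict[int, np.ndarray]
    patch_areas_mm2: dict[int, float]
    volumes_mm3: dict[int, float]
    neighbors: dict[int, set[int]]
    total_area_mm2: float
    dims_mm: Optional[tuple[float, float, float]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in sorted(self.centers_mm):
            c = self.centers_mm[lbl]
            rows.append(
                {
                    "scute_id": lbl,
                    "center_x_mm": c[0], "center_y_mm": c[1], "center_z_mm": c[2],
                    "patch_area_mm2": self.patch_areas_mm2[lbl],
                    "volume_mm3": self.volumes_mm3.get(lbl, np.nan),
                    "n_neighbors": len(self.neighbors[lbl]),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SeriesSpec:
    """Design of a synthetic ontogenetic series."""

    n_specimens: int = 13
    mode: str = "isometric"  # isometric | allometric | table_only
    scale_factors: Optional[np.ndarray] = None  # linear scale per specimen
    sa_values: Optional[np.ndarray] = None  # mm^2, table_only
    exponents: dict = field(default_factory=dict)  # b_* vs SA
    coefficients: dict = field(default_factory=dict)
    base_shell: Optional[ShellSpec] = None
    noise_sd: float = 0.0  # lognormal sigma on table rows
    n_scutes: int = 370
    relax_iters: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("isometric", "allometric", "table_only"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.scale_factors is not None:
            self.scale_factors = np.asarray(self.scale_factors, dtype=float)
            if np.any(np.diff(self.scale_factors) <= 0):
                raise ValueError("scale factors must be strictly increasing")
            self.n_specimens = len(self.scale_factors)
        if self.sa_values is not None:
            self.sa_values = np.asarray(self.sa_values, dtype=float)
            self.n_specimens = len(self.sa_values)


# -------------------------------------------------------------- shells


def superellipsoid_radius(directions: np.ndarray, semi_axes, p: float) -> np.ndarray:
    """Radius r(u) with r*u on the superellipsoid, u unit directions."""
    u = np.atleast_2d(directions)
    t = np.abs(u / np.asarray(semi_axes)) ** p
    return t.sum(axis=1) ** (-1.0 / p)


def superellipsoid_level(points: np.ndarray, semi_axes, p: float) -> np.ndarray:
    """Implicit level f(q) = (sum |q_i/a_i|^p)^(1/p); surface at f=1."""
    q = np.atleast_2d(points)
    return (np.abs(q / np.asarray(semi_axes)) ** p).sum(axis=1) ** (1.0 / p)


def superellipsoid_depth(points: np.ndarray, semi_axes, p: float) -> np.ndarray:
    """First-order Euclidean depth below the surface, (1 - F)/|grad F|.

    Exact for spheres and flat superellipsoid faces; points outside the
    surface get negative depth.
    """
    q = np.atleast_2d(points)
    a = np.asarray(semi_axes, dtype=float)
    F = superellipsoid_level(q, a, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = (
            F[:, None] ** (1.0 - p)
            * np.abs(q / a) ** (p - 1.0)
            * np.sign(q)
            / a
        )
    gnorm = np.linalg.norm(grad, axis=1)
    ok = (F > 0) & (gnorm > 0)
    out = np.full(len(q), -np.inf)
    out[ok] = (1.0 - F[ok]) / gnorm[ok]
    return out


def make_shell_mesh(spec: ShellSpec, subdivisions: int = 5) -> SurfaceMesh:
    """Closed genus-0 triangle mesh of the outer superellipsoid surface.

    An icosphere is mapped radially onto the superellipsoid, preserving
    the manifold connectivity; winding is outward.
    """
    sphere = icosphere(subdivisions)
    r = superellipsoid_radius(sphere.vertices, spec.semi_axes, spec.boxiness)
    mesh = SurfaceMesh(sphere.vertices * r[:, None], sphere.faces)
    if not mesh.is_closed_manifold():
        raise RuntimeError("shell mesh is not a closed manifold")
    return mesh


def _cut_openings(face_labels: np.ndarray, mesh: SurfaceMesh,
                  openings: list[Opening]) -> np.ndarray:
    """Set faces inside any opening cone to label 0 (hole)."""
    if not openings:
        return face_labels
    cen = mesh.face_centroids()
    u = cen / np.linalg.norm(cen, axis=1, keepdims=True)
    out = face_labels.copy()
    for op in openings:
        cosang = u @ op.center_direction
        out[cosang >= np.cos(op.angular_radius)] = 0
    return out


# -------------------------------------------------------- tessellation


def tessellate_mesh(
    mesh: SurfaceMesh,
    n_scutes: int,
    relax_iters: int = 10,
    rng_seed: int = 0,
    sites: Optional[np.ndarray] = None,
    shell_thickness_mm: Optional[float] = None,
    openings: Optional[list[Opening]] = None,
) -> tuple[SurfaceMesh, GroundTruth]:
    """Surface Voronoi tessellation of a closed mesh into n_scutes tiles.

    Sites are sampled area-uniformly (or given explicitly), each face is
    assigned to the Euclidean-nearest site, and sites are moved to the
    area-weighted centroid of their patch (re-projected onto the
    surface) for ``relax_iters`` Lloyd steps.  Every label's face set is
    made edge-connected afterwards.  Deterministic for a fixed seed.
    """
    # explicit sites may describe degenerate test tilings (e.g. the six
    # faces of a cube); random sampling keeps the >= 12 floor
    if n_scutes < (4 if sites is not None else 12):
        raise ValueError("n_scutes must be >= 12 (>= 4 with explicit sites)")
    if not mesh.is_closed_manifold():
        raise ValueError("tessellation requires a closed mesh")
    rng = np.random.default_rng(rng_seed)
    centroids = mesh.face_centroids()
    areas = mesh.face_areas()

    if sites is None:
        probs = areas / areas.sum()
        chosen = rng.choice(len(centroids), size=n_scutes, replace=False, p=probs)
        sites = centroids[chosen]
    else:
        sites = np.asarray(sites, dtype=float)
        if len(sites) != n_scutes:
            raise ValueError("len(sites) must equal n_scutes")

    assign = np.empty(len(centroids), dtype=np.int64)
    for it in range(relax_iters + 1):
        _, assign = cKDTree(sites).query(centroids)
        # resample any site that captured no face
        empties = np.setdiff1d(np.arange(n_scutes), np.unique(assign))
        while len(empties):
            warnings.warn(f"{len(empties)} empty tessellation site(s); resampling")
            sites[empties] = centroids[
                rng.choice(len(centroids), size=len(empties), replace=False)
            ]
            _, assign = cKDTree(sites).query(centroids)
            empties = np.setdiff1d(np.arange(n_scutes), np.unique(assign))
        if it == relax_iters:
            break
        # Lloyd step: area-weighted patch centroid, re-projected to the
        # plane of the nearest face (continuous, so sites can converge
        # onto patch centroids instead of being quantized at face size)
        w = areas
        sums = np.zeros((n_scutes, 3))
        wsum = np.zeros(n_scutes)
        np.add.at(sums, assign, centroids * w[:, None])
        np.add.at(wsum, assign, w)
        new_sites = sums / wsum[:, None]
        _, nearest_face = cKDTree(centroids).query(new_sites)
        fn = mesh.face_normals()[nearest_face]
        offset = np.einsum("ij,ij->i", new_sites - centroids[nearest_face], fn)
        sites = new_sites - offset[:, None] * fn

    labels = assign + 1  # face labels 1..n
    labels = _enforce_connectivity(mesh, labels)
    if openings:
        labels = _cut_openings(labels, mesh, openings)

    labeled = SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy(), labels)
    truth = ground_truth_from_labeled_mesh(labeled, shell_thickness_mm)
    return labeled, truth


def _enforce_connectivity(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Reassign minority components of each label to an adjacent label."""
    adj = mesh.face_adjacency()
    areas = mesh.face_areas()
    labels = labels.copy()
    for _ in range(20):
        moved = False
        comp_of = _label_components(adj, labels, len(labels))
        for lbl in np.unique(labels):
            comps = comp_of.get(int(lbl), [])
            if len(comps) <= 1:
                continue
            comps = sorted(comps, key=lambda c: areas[c].sum(), reverse=True)
            for c in comps[1:]:
                mask = np.zeros(len(labels), bool)
                mask[c] = True
                # majority neighboring label outside the component
                cand = []
                for a, b in adj:
                    if mask[a] and not mask[b]:
                        cand.append(labels[b])
                    elif mask[b] and not mask[a]:
                        cand.append(labels[a])
                cand = [x for x in cand if x != lbl]
                if cand:
                    vals, cnts = np.unique(cand, return_counts=True)
                    labels[c] = vals[np.argmax(cnts)]
                    moved = True
        if not moved:
            break
    return labels


def _label_components(adj, labels, n_faces) -> dict[int, list[np.ndarray]]:
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    same = labels[adj[:, 0]] == labels[adj[:, 1]]
    g = sparse.coo_matrix(
        (np.ones(same.sum()), (adj[same, 0], adj[same, 1])),
        shape=(n_faces, n_faces),
    )
    _, comp = connected_components(g, directed=False)
    out: dict[int, list[np.ndarray]] = {}
    for cid in np.unique(comp):
        idx = np.flatnonzero(comp == cid)
        out.setdefault(int(labels[idx[0]]), []).append(idx)
    return out


def ground_truth_from_labeled_mesh(
    labeled: SurfaceMesh, shell_thickness_mm: Optional[float] = None
) -> GroundTruth:
    """Patch areas/centers/neighbors from per-face labels.

    True scute volume is the thin-shell approximation
    ``patch area x shell thickness`` when a thickness is given.
    """
    labels = labeled.face_labels
    if labels is None:
        raise ValueError("mesh has no face labels")
    areas = labeled.face_areas()
    centroids = labeled.face_centroids()
    present = np.unique(labels)
    present = present[present > 0]

    centers: dict[int, np.ndarray] = {}
    patch: dict[int, float] = {}
    vols: dict[int, float] = {}
    for lbl in present:
        m = labels == lbl
        w = areas[m]
        patch[int(lbl)] = float(w.sum())
        centers[int(lbl)] = (centroids[m] * w[:, None]).sum(axis=0) / w.sum()
        if shell_thickness_mm is not None:
            vols[int(lbl)] = patch[int(lbl)] * shell_thickness_mm

    neighbors: dict[int, set[int]] = {int(l): set() for l in present}
    adj = labeled.face_adjacency()
    la, lb = labels[adj[:, 0]], labels[adj[:, 1]]
    diff = (la != lb) & (la > 0) & (lb > 0)
    for a, b in zip(la[diff], lb[diff]):
        neighbors[int(a)].add(int(b))
        neighbors[int(b)].add(int(a))

    return GroundTruth(
        centers_mm=centers,
        patch_areas_mm2=patch,
        volumes_mm3=vols,
        neighbors=neighbors,
        total_area_mm2=float(areas[labels > 0].sum()),
    )


# -------------------------------------------------------- voxelization


def voxelize_labeled_shell(
    labeled_mesh: SurfaceMesh,
    spec: ShellSpec,
    voxel_spacing_mm: float = 0.15,
    valley_depth: float = 0.0,
    noise_sd: float = 5.0,
    plateau: float = PLATEAU,
    label_method: str = "nearest_center",
    label_subdivisions: int = 2,
):
    """Render a labeled shell as intensity + label volumes with seeds.

    Foreground voxels are those whose center lies within
    ``shell_thickness_mm`` below the outer superellipsoid surface
    (radial depth).  Each gets the label of the nearest surface patch:
    with ``label_method='nearest_center'`` the patch whose (Voronoi)
    center is nearest — the continuous partition the face labels
    sample — and with ``'nearest_face'`` the patch owning the nearest
    face centroid (refined ``label_subdivisions`` times), which is
    quantized at face size.
    Intensity is a plateau inside scutes dipping by
    ``valley_depth * plateau`` in a 1-voxel band along inter-scute
    boundaries, plus seeded Gaussian noise; background is 0.

    Returns (IntensityVolume, LabelField, SeedSet).
    """
    from .segment import SeedSet

    if not 0 <= valley_depth <= 1:
        raise ValueError("valley_depth must be in [0, 1]")
    sp = float(voxel_spacing_mm)
    if spec.shell_thickness_mm < 2 * sp:
        raise ValueError(
            "voxel spacing too coarse for shell thickness "
            f"{spec.shell_thickness_mm} mm; need spacing <= "
            f"{spec.shell_thickness_mm / 2:.6g} mm"
        )
    semi = spec.semi_axes
    margin = 2 * sp
    origin = -(semi + margin)
    extent = 2 * (semi + margin)
    shape = np.ceil(extent / sp).astype(int)
    spacing = np.full(3, sp)

    ii, jj, kk = np.meshgrid(
        *[np.arange(n) for n in shape], indexing="ij"
    )
    pts = origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * sp
    flat = pts.reshape(-1, 3)

    depth = superellipsoid_depth(flat, semi, spec.boxiness)
    fg = (depth >= 0.0) & (depth <= spec.shell_thickness_mm)

    labels_flat = np.zeros(len(flat), dtype=np.int32)
    if labeled_mesh.face_labels is None:
        raise ValueError("mesh must carry face labels")
    truth = ground_truth_from_labeled_mesh(labeled_mesh, spec.shell_thickness_mm)
    if label_method == "nearest_center":
        ids = np.array(sorted(truth.centers_mm))
        tree = cKDTree(np.array([truth.centers_mm[i] for i in ids]))
        _, nearest = tree.query(flat[fg])
        labels_flat[fg] = ids[nearest]
    elif label_method == "nearest_face":
        fine = _refine_labeled(labeled_mesh, label_subdivisions)
        tree = cKDTree(fine.face_centroids())
        _, nearest = tree.query(flat[fg])
        labels_flat[fg] = fine.face_labels[nearest]
    else:
        raise ValueError(f"unknown label_method: {label_method}")
    label_arr = labels_flat.reshape(shape)
    # voxels nearest an opening face (label 0) become background
    fg_arr = label_arr > 0

    # one seed per scute: foreground voxel of that label nearest its
    # ground-truth patch center (the seed landmark is that voxel center)
    seeds = []
    idx_all = np.argwhere(fg_arr)
    world_all = origin + (idx_all + 0.5) * sp
    lbl_all = label_arr[fg_arr]
    for lbl in sorted(truth.centers_mm):
        m = lbl_all == lbl
        if not m.any():
            warnings.warn(f"scute {lbl} has no voxels at this spacing; skipped")
            continue
        d = np.linalg.norm(world_all[m] - truth.centers_mm[lbl], axis=1)
        seeds.append((lbl, world_all[m][np.argmin(d)]))

    if label_method == "nearest_center":
        # re-partition around the realizable landmarks so the ground
        # truth is the Voronoi diagram of the seeds actually handed to
        # the segmenter (patch centers voxel-snap by up to half a voxel)
        seed_ids = np.array([s[0] for s in seeds])
        tree = cKDTree(np.array([s[1] for s in seeds]))
        _, nearest = tree.query(world_all)
        label_arr[fg_arr] = seed_ids[nearest]

    intensity = np.zeros(shape, dtype=np.float64)
    intensity[fg_arr] = plateau
    if valley_depth > 0:
        boundary = _boundary_band(label_arr)
        intensity[boundary] -= valley_depth * plateau
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xB0C5]))
    if noise_sd > 0:
        intensity[fg_arr] += rng.normal(0.0, noise_sd, size=int(fg_arr.sum()))

    labf = LabelField(label_arr.astype(np.int32), spacing, origin)
    vol = IntensityVolume(intensity.astype(np.float32), spacing, origin)
    return vol, labf, SeedSet(seeds)


def _refine_labeled(mesh: SurfaceMesh, subdivisions: int) -> SurfaceMesh:
    """Subdivide a labeled mesh; child faces inherit the parent label."""
    from .mesh import _subdivide

    v, f, l = mesh.vertices, mesh.faces, mesh.face_labels
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
        l = np.concatenate([l, l, l, l])  # _subdivide emits 4 per-parent blocks
    return SurfaceMesh(v, f, l)


def _boundary_band(label_arr: np.ndarray) -> np.ndarray:
    """Foreground voxels 6-adjacent to a different nonzero label."""
    band = np.zeros(label_arr.shape, dtype=bool)
    fg = label_arr > 0
    for ax in range(3):
        for sh in (1, -1):
            rolled = np.roll(label_arr, sh, axis=ax)
            edge = fg & (rolled > 0) & (rolled != label_arr)
            # roll wraps around; voxels at array edge are background-padded
            sl = [slice(None)] * 3
            sl[ax] = slice(0, 1) if sh == 1 else slice(-1, None)
            edge[tuple(sl)] = False
            band |= edge
    return band


# -------------------------------------------------------------- series

#: scaling-law coefficients for table-only rows (arbitrary but fixed)
DEFAULT_COEFFICIENTS = {
    "length": 2.0, "height": 1.5, "width": 1.2,
    "scute_volume": 0.01, "scute_thickness": 0.05,
    "scute_width": 0.3, "scute_pba": 0.002,
}

ISOMETRIC_EXPONENTS = {
    "b_length": 0.5, "b_height": 0.5, "b_width": 0.5,
    "b_scute_volume": 1.5, "b_scute_thickness": 0.5,
    "b_scute_width": 0.5, "b_scute_pba": 1.0,
}


def generate_series(series: SeriesSpec):
    """Generate an ontogenetic series.

    Returns ``(specimens, table)`` where ``table`` is a per-specimen
    DataFrame (SA, dimensions, medians, scute count).  ``specimens`` is
    a list of dicts with geometry (mesh, truth, scale) for geometric
    modes and empty for ``table_only``.
    """
    if series.mode == "table_only":
        return [], _table_only_series(series)
    if series.mode == "isometric":
        return _isometric_series(series)
    return _allometric_series(series)


def _resolve_exponents(series: SeriesSpec) -> dict:
    if series.mode == "isometric":
        return dict(ISOMETRIC_EXPONENTS)
    exps = dict(ISOMETRIC_EXPONENTS)
    exps.update(series.exponents)
    return exps


def _default_sa_values(n: int) -> np.ndarray:
    # linear span 8.5x -> SA span 8.5^2, log-spaced, base 100 mm^2
    return 100.0 * np.logspace(0, 2 * np.log10(8.5), n)


def _table_only_series(series: SeriesSpec) -> pd.DataFrame:
    sa = series.sa_values
    if sa is None:
        sa = _default_sa_values(series.n_specimens)
    exps = _resolve_exponents(series)
    coef = dict(DEFAULT_COEFFICIENTS)
    coef.update(series.coefficients)
    rng = np.random.default_rng(np.random.SeedSequence([series.rng_seed, 0x5E12]))

    def jitter(n):
        if series.noise_sd > 0:
            return np.exp(rng.normal(0.0, series.noise_sd, size=n))
        return np.ones(n)

    n = len(sa)
    table = pd.DataFrame(
        {
            "specimen": np.arange(n),
            "sa_mm2": sa,
            "length_mm": coef["length"] * sa ** exps["b_length"] * jitter(n),
            "height_mm": coef["height"] * sa ** exps["b_height"] * jitter(n),
            "width_mm": coef["width"] * sa ** exps["b_width"] * jitter(n),
            "median_scute_volume_mm3":
                coef["scute_volume"] * sa ** exps["b_scute_volume"] * jitter(n),
            "median_scute_pba_mm2":
                coef["scute_pba"] * sa ** exps["b_scute_pba"] * jitter(n),
            "median_scute_thickness_mm":
                coef["scute_thickness"] * sa ** exps["b_scute_thickness"] * jitter(n),
            "median_scute_width_mm":
                coef["scute_width"] * sa ** exps["b_scute_width"] * jitter(n),
            "n_scutes": series.n_scutes,
        }
    )
    _warn_if_disordered(table)
    return table


def _warn_if_disordered(table: pd.DataFrame) -> None:
    bad = (table["length_mm"] < table["height_mm"]) | (
        table["height_mm"] < table["width_mm"]
    )
    if bad.any():
        warnings.warn(
            "exponent/coefficient set breaks length >= height >= width for "
            f"{int(bad.sum())} specimen(s)"
        )


def _template(series: SeriesSpec) -> tuple[ShellSpec, SurfaceMesh, GroundTruth]:
    base = series.base_shell
    if base is None:
        base = ShellSpec(
            length_mm=20.0, height_mm=14.0, width_mm=11.0,
            n_scutes=series.n_scutes, rng_seed=series.rng_seed,
        )
    mesh = make_shell_mesh(base)
    labeled, truth = tessellate_mesh(
        mesh, base.n_scutes, relax_iters=series.relax_iters,
        rng_seed=base.rng_seed, shell_thickness_mm=base.shell_thickness_mm,
        openings=base.openings,
    )
    truth.dims_mm = (base.length_mm, base.height_mm, base.width_mm)
    return base, labeled, truth


def _isometric_series(series: SeriesSpec):
    """Uniform scaling of one tessellated template; scute count constant."""
    scales = series.scale_factors
    if scales is None:
        scales = np.logspace(0, np.log10(8.5), series.n_specimens)
    base, labeled, truth = _template(series)
    specimens = []
    rows = []
    for i, s in enumerate(scales):
        spec_i = ShellSpec(
            length_mm=base.length_mm * s, height_mm=base.height_mm * s,
            width_mm=base.width_mm * s, boxiness=base.boxiness,
            shell_thickness_mm=base.shell_thickness_mm * s,
            n_scutes=base.n_scutes, openings=base.openings,
            rng_seed=_subseed(series.rng_seed, i),
        )
        scaled = labeled.scaled(s)
        truth_i = GroundTruth(
            centers_mm={k: v * s for k, v in truth.centers_mm.items()},
            patch_areas_mm2={k: v * s**2 for k, v in truth.patch_areas_mm2.items()},
            volumes_mm3={k: v * s**3 for k, v in truth.volumes_mm3.items()},
            neighbors={k: set(v) for k, v in truth.neighbors.items()},
            total_area_mm2=truth.total_area_mm2 * s**2,
            dims_mm=(base.length_mm * s, base.height_mm * s, base.width_mm * s),
        )
        specimens.append({"spec": spec_i, "mesh": scaled, "truth": truth_i,
                          "scale": float(s)})
        rows.append(_truth_row(i, truth_i))
    return specimens, pd.DataFrame(rows)


def _allometric_series(series: SeriesSpec):
    """Per-specimen shells with dimensions c * s^b; fresh tessellations."""
    scales = series.scale_factors
    if scales is None:
        scales = np.logspace(0, np.log10(8.5), series.n_specimens)
    exps = _resolve_exponents(series)
    base = series.base_shell
    if base is None:
        base = ShellSpec(20.0, 14.0, 11.0, n_scutes=series.n_scutes,
                         rng_seed=series.rng_seed)
    # express dims as functions of the SA proxy s^2 so that exponents are
    # relative to surface area, matching the table-only convention
    specimens = []
    rows = []
    for i, s in enumerate(scales):
        sa_proxy = s**2
        dims = np.array(
            [
                base.length_mm * sa_proxy ** (exps["b_length"] - 0.5) * s,
                base.height_mm * sa_proxy ** (exps["b_height"] - 0.5) * s,
                base.width_mm * sa_proxy ** (exps["b_width"] - 0.5) * s,
            ]
        )
        if not (dims[0] >= dims[1] >= dims[2]):
            warnings.warn(
                f"specimen {i}: allometric dims break length>=height>=width"
            )
        spec_i = ShellSpec(
            length_mm=dims[0], height_mm=dims[1], width_mm=dims[2],
            boxiness=base.boxiness,
            shell_thickness_mm=base.shell_thickness_mm * s,
            n_scutes=base.n_scutes, openings=base.openings,
            rng_seed=_subseed(series.rng_seed, i),
        )
        mesh = make_shell_mesh(spec_i)
        labeled, truth_i = tessellate_mesh(
            mesh, spec_i.n_scutes, relax_iters=series.relax_iters,
            rng_seed=spec_i.rng_seed,
            shell_thickness_mm=spec_i.shell_thickness_mm,
            openings=spec_i.openings,
        )
        truth_i.dims_mm = tuple(dims)
        specimens.append({"spec": spec_i, "mesh": labeled, "truth": truth_i,
                          "scale": float(s)})
        rows.append(_truth_row(i, truth_i))
    return specimens, pd.DataFrame(rows)


def _truth_row(i: int, truth: GroundTruth) -> dict:
    vols = np.array(sorted(truth.volumes_mm3.values()))
    pbas = np.array(sorted(truth.patch_areas_mm2.values()))
    med_vol = float(np.median(vols)) if len(vols) else np.nan
    med_pba = float(np.median(pbas))
    return {
        "specimen": i,
        "sa_mm2": truth.total_area_mm2,
        "length_mm": truth.dims_mm[0] if truth.dims_mm else np.nan,
        "height_mm": truth.dims_mm[1] if truth.dims_mm else np.nan,
        "width_mm": truth.dims_mm[2] if truth.dims_mm else np.nan,
        "median_scute_volume_mm3": med_vol,
        "median_scute_pba_mm2": med_pba,
        # thin-shell truths: thickness = volume / patch area (exact for
        # the generator), width proxy = sqrt(patch area)
        "median_scute_thickness_mm": med_vol / med_pba,
        "median_scute_width_mm": float(np.sqrt(med_pba)),
        "n_scutes": len(truth.centers_mm),
    }


def _subseed(seed: int, i: int) -> int:
    """Counter-based split: one child seed per specimen index."""
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
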
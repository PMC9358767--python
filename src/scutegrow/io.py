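"""File formats: NRRD and TIFF+sidecar volumes, ASCII PLY/OBJ meshes,
JSON seed sets, GraphML/CSV graphs.

NRRD support is a minimal detached-header-free reader/writer for the
raw-encoded 3D case (enough for label fields and intensity volumes);
the full format is not needed here.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

from .grid import IntensityVolume, LabelField, _Grid
from .mesh import SurfaceMesh

PathLike = Union[str, Path]

_NRRD_TYPES = {
    "float": np.float32, "double": np.float64,
    "unsigned short": np.uint16, "unsigned int": np.uint32,
    "short": np.int16, "int": np.int32, "unsigned char": np.uint8,
    "signed char": np.int8, "long long int": np.int64,
    "unsigned long long int": np.uint64,
}
_NRRD_NAMES = {v: k for k, v in _NRRD_TYPES.items()}


# ---------------------------------------------------------------- NRRD


def write_nrrd(path: PathLike, grid: _Grid) -> None:
    arr = np.ascontiguousarray(grid.array)
    tname = _NRRD_NAMES.get(arr.dtype.type)
    if tname is None:
        raise ValueError(f"unsupported dtype for NRRD: {arr.dtype}")
    sp = grid.voxel_spacing_mm
    org = grid.origin_mm
    # C-order array with axis order (i,j,k): fastest axis last, so NRRD
    # sizes (fastest first) are reversed shape and we write Fortran data.
    header = [
        "NRRD0004",
        "# scutegrow volume",
        f"type: {tname}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        f"space directions: ({sp[0]},0,0) (0,{sp[1]},0) (0,0,{sp[2]})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        f"space origin: ({org[0]},{org[1]},{org[2]})",
        "",
        "",
    ]
    data = arr.astype(arr.dtype.newbyteorder("<"), copy=False)
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(np.asfortranarray(data).tobytes(order="F"))


def read_nrrd(path: PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (array, spacing, origin) from a raw-encoded NRRD."""
    with open(path, "rb") as fh:
        raw = fh.read()
    head_end = raw.find(b"\n\n")
    if head_end < 0:
        raise ValueError("malformed NRRD: no blank line after header")
    fields: dict[str, str] = {}
    for line in raw[:head_end].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        k, v = line.split(":", 1)
        fields[k.strip()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw-encoded NRRD supported")
    dtype = _NRRD_TYPES[fields["type"]]
    sizes = tuple(int(s) for s in fields["sizes"].split())
    spacing = np.array(
        [float(t.strip("() ").split(",")[i]) for i, t in
         enumerate(fields["space directions"].split(") ("))]
    )
    origin = np.array(
        [float(t) for t in fields["space origin"].strip("()").split(",")]
    )
    data = np.frombuffer(raw[head_end + 2:], dtype=np.dtype(dtype).newbyteorder("<"))
    arr = data.reshape(sizes, order="F")
    return np.ascontiguousarray(arr), spacing, origin


def read_intensity_nrrd(path: PathLike) -> IntensityVolume:
    arr, sp, org = read_nrrd(path)
    return IntensityVolume(arr.astype(np.float32), sp, org)


def read_labels_nrrd(path: PathLike) -> LabelField:
    arr, sp, org = read_nrrd(path)
    return LabelField(arr.astype(np.int64), sp, org)


# ------------------------------------------------- TIFF + JSON sidecar


def write_tiff(path: PathLike, grid: _Grid) -> None:
    """Multipage TIFF (pages along axis 0) + ``<stem>.json`` frame sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(grid.array),
                     photometric="minisblack")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "voxel_spacing_mm": list(map(float, grid.voxel_spacing_mm)),
                "origin_mm": list(map(float, grid.origin_mm)),
                "axis_order": "ijk",
            },
            fh,
            indent=2,
        )


def _read_tiff(path: PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        spacing = np.array(meta["voxel_spacing_mm"], dtype=float)
        origin = np.array(meta["origin_mm"], dtype=float)
    else:
        spacing = np.ones(3)
        origin = np.zeros(3)
    return arr, spacing, origin


def read_intensity(path: PathLike) -> IntensityVolume:
    """Dispatch on extension: .nrrd or .tif/.tiff (+sidecar)."""
    ext = Path(path).suffix.lower()
    if ext == ".nrrd":
        return read_intensity_nrrd(path)
    if ext in (".tif", ".tiff"):
        arr, sp, org = _read_tiff(path)
        return IntensityVolume(arr.astype(np.float32), sp, org)
    raise ValueError(f"unsupported volume format: {ext}")


def read_labels(path: PathLike) -> LabelField:
    ext = Path(path).suffix.lower()
    if ext == ".nrrd":
        return read_labels_nrrd(path)
    if ext in (".tif", ".tiff"):
        arr, sp, org = _read_tiff(path)
        return LabelField(arr.astype(np.int64), sp, org)
    raise ValueError(f"unsupported volume format: {ext}")


# ----------------------------------------------------------------- PLY


def write_ply(path: PathLike, mesh: SurfaceMesh, face_scalar=None,
              scalar_name: str = "quality") -> None:
    """ASCII PLY; per-face labels and an optional per-face scalar."""
    has_labels = mesh.face_labels is not None
    lines = [
        "ply",
        "format ascii 1.0",
        "comment scutegrow surface",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
    ]
    if has_labels:
        lines.append("property int label")
    if face_scalar is not None:
        face_scalar = np.asarray(face_scalar, dtype=float)
        lines.append(f"property float {scalar_name}")
    lines.append("end_header")
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for i, f in enumerate(mesh.faces):
        row = f"3 {f[0]} {f[1]} {f[2]}"
        if has_labels:
            row += f" {mesh.face_labels[i]}"
        if face_scalar is not None:
            row += f" {face_scalar[i]:.9g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path: PathLike) -> SurfaceMesh:
    text = Path(path).read_text().splitlines()
    n_vert = n_face = 0
    face_props: list[str] = []
    i = 0
    element = None
    for i, line in enumerate(text):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "face" and tok[1] != "list":
            face_props.append(tok[2])
        elif tok[0] == "end_header":
            break
    body = text[i + 1:]
    verts = np.array([[float(x) for x in body[j].split()] for j in range(n_vert)])
    faces = np.empty((n_face, 3), dtype=np.int64)
    labels = np.empty(n_face, dtype=np.int64) if "label" in face_props else None
    for j in range(n_face):
        tok = body[n_vert + j].split()
        faces[j] = [int(tok[1]), int(tok[2]), int(tok[3])]
        if labels is not None:
            labels[j] = int(tok[4 + face_props.index("label")])
    return SurfaceMesh(verts, faces, labels)


def write_obj(path: PathLike, mesh: SurfaceMesh) -> None:
    lines = ["# scutegrow surface"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- seeds


def write_seeds(path: PathLike, seeds) -> None:
    """SeedSet -> JSON [{label, x_mm, y_mm, z_mm}]."""
    rows = [
        {"label": int(lbl), "x_mm": float(p[0]), "y_mm": float(p[1]),
         "z_mm": float(p[2])}
        for lbl, p in seeds
    ]
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2)


def read_seeds(path: PathLike):
    from .segment import SeedSet

    with open(path) as fh:
        rows = json.load(fh)
    return SeedSet(
        [(int(r["label"]), np.array([r["x_mm"], r["y_mm"], r["z_mm"]]))
         for r in rows]
    )


# -------------------------------------------------------------- graphs


def write_rag(path_graphml: PathLike, rag, path_edges_csv: PathLike | None = None):
    import networkx as nx

    g = rag.graph.copy()
    for n, data in g.nodes(data=True):
        c = data.pop("center_mm", None)
        if c is not None:
            data["x_mm"], data["y_mm"], data["z_mm"] = map(float, c)
    nx.write_graphml(g, path_graphml)
    if path_edges_csv is not None:
        with open(path_edges_csv, "w") as fh:
            fh.write("label_a,label_b,contact_faces\n")
            for a, b, d in rag.graph.edges(data=True):
                fh.write(f"{a},{b},{d.get('contact_faces', 1)}\n")
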
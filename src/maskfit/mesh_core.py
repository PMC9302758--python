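"""Triangle-surface mesh data model, I/O and the synthetic face generator.

Units are millimetres throughout.  A :class:`TriSurfaceMesh` is an open or
closed triangulated surface with optional named landmarks stored as vertex
indices (so they survive mesh operations).  The synthetic face generator
produces template-like open facial shells — a smooth convex dome with a
Gaussian nose ridge and chin bump, facing +Z — that stand in for 3D face
scans with registered topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import GeometryError, MeshFormatError, ParameterError

__all__ = [
    "TriSurfaceMesh",
    "SyntheticFaceSpec",
    "boundary_vertex_set",
    "generate_synthetic_face",
    "face_height_function",
    "reference_loop_on_face",
    "NASAL_LIP_EXTRA_ANGLES",
    "structured_rectangle_mesh",
    "load_mesh",
    "save_obj",
    "save_vtk",
    "load_landmarks",
    "save_landmarks",
]

_DEGENERATE_AREA = 1e-9  # mm^2


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def _edge_multiplicities(triangles: np.ndarray):
    edges = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq, counts


@dataclass
class TriSurfaceMesh:
    """A triangulated surface in mm with optional landmarks.

    ``boundary_vertices`` is always the set of vertices incident to an edge
    used by exactly one triangle; it is recomputed on construction.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    landmarks: dict[str, int] = field(default_factory=dict)
    boundary_vertices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("vertex coordinates must be finite")
        n = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise GeometryError("triangle index out of range")
        same = (
            (self.triangles[:, 0] == self.triangles[:, 1])
            | (self.triangles[:, 1] == self.triangles[:, 2])
            | (self.triangles[:, 2] == self.triangles[:, 0])
        )
        if np.any(same):
            raise GeometryError(
                f"triangle {int(np.flatnonzero(same)[0])} repeats a vertex"
            )
        areas = _triangle_areas(self.vertices, self.triangles)
        bad = areas <= _DEGENERATE_AREA
        if np.any(bad):
            raise GeometryError(
                f"degenerate (zero-area) triangle {int(np.flatnonzero(bad)[0])}"
            )
        for name, idx in self.landmarks.items():
            if not 0 <= int(idx) < n:
                raise GeometryError(f"landmark {name!r} index out of range")
        self.boundary_vertices = boundary_vertex_set(self)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        return _triangle_areas(self.vertices, self.triangles)

    def is_manifold_interior(self) -> bool:
        """True when every edge is used by at most two triangles."""
        _, counts = _edge_multiplicities(self.triangles)
        return bool(np.all(counts <= 2))

    def translated(self, offset) -> "TriSurfaceMesh":
        return TriSurfaceMesh(
            self.vertices + np.asarray(offset, dtype=float),
            self.triangles.copy(),
            dict(self.landmarks),
        )


def boundary_vertex_set(mesh: TriSurfaceMesh | np.ndarray) -> np.ndarray:
    """Sorted indices of vertices incident to an open (multiplicity-1) edge."""
    triangles = mesh.triangles if isinstance(mesh, TriSurfaceMesh) else mesh
    if len(triangles) == 0:
        return np.empty(0, dtype=np.int64)
    uniq, counts = _edge_multiplicities(np.asarray(triangles, dtype=np.int64))
    open_edges = uniq[counts == 1]
    return np.unique(open_edges)


# ---------------------------------------------------------------------------
# synthetic face generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Parameters of the synthetic facial shell (all lengths in mm)."""

    target_vertex_count: int = 5303
    face_width: float = 140.0
    face_height: float = 180.0
    face_depth: float = 55.0
    nose_height: float = 16.0
    nose_width: float = 22.0
    chin_protrusion: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_vertex_count < 16:
            raise ParameterError("target_vertex_count must be at least 16")
        for name in (
            "face_width",
            "face_height",
            "face_depth",
            "nose_height",
            "nose_width",
            "chin_protrusion",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


def face_height_function(spec: SyntheticFaceSpec):
    """The generating height field z = f(x, y) of the synthetic face.

    A flattened half-ellipsoid dome plus a Gaussian nose ridge (centred a
    little above mid-face) and a Gaussian chin bump low on the mid-line.
    """
    a = spec.face_width / 2.0
    b = spec.face_height / 2.0
    sx = spec.nose_width / 3.0
    sy = 0.28 * b
    y_nose = 0.05 * b
    y_chin = -0.72 * b
    s_chin = 0.14 * b

    def f(x, y):
        r2 = (np.asarray(x) / a) ** 2 + (np.asarray(y) / b) ** 2
        dome = spec.face_depth * np.sqrt(np.maximum(0.0, 1.0 - 0.9 * r2))
        nose = spec.nose_height * np.exp(
            -(np.asarray(x) / sx) ** 2 / 2.0
            - ((np.asarray(y) - y_nose) / sy) ** 2 / 2.0
        )
        chin = spec.chin_protrusion * np.exp(
            -(np.asarray(x) / (1.2 * s_chin)) ** 2 / 2.0
            - ((np.asarray(y) - y_chin) / s_chin) ** 2 / 2.0
        )
        return dome + nose + chin

    return f


def _grid_shape(target: int) -> tuple[int, int]:
    # polar grid: 1 centre + n_r rings of n_t vertices; pick the closest count
    best = None
    for n_r in range(2, int(np.sqrt(target)) + 3):
        n_t = max(4, round((target - 1) / n_r))
        count = 1 + n_r * n_t
        key = (abs(count - target), abs(n_t / n_r - 2.0))
        if best is None or key < best[0]:
            best = (key, n_r, n_t)
    return best[1], best[2]


def generate_synthetic_face(spec: SyntheticFaceSpec) -> TriSurfaceMesh:
    """Generate an open facial shell facing +Z on a structured polar UV grid.

    The grid (centre vertex plus ``n_r`` rings of ``n_t`` vertices) is mapped
    onto an ellipse in the XY plane, interior vertices get a small seeded
    in-plane jitter emulating scan irregularity, and heights come from
    :func:`face_height_function`.  Deterministic per seed; vertex count is
    within +-2% of the target.
    """
    n_r, n_t = _grid_shape(spec.target_vertex_count)
    a = spec.face_width / 2.0
    b = spec.face_height / 2.0

    r = np.arange(1, n_r + 1) / n_r
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    x = a * rr * np.cos(tt)
    y = b * rr * np.sin(tt)

    rng = np.random.default_rng(spec.seed)
    # jitter interior rings only; amplitude is a quarter of the local cell
    # size (tangential spacing shrinks toward the centre), so triangles
    # cannot flip
    cell = np.minimum(1.0 / n_r, np.pi * r / n_t) * min(a, b)
    jit = rng.uniform(-0.25, 0.25, size=(n_r, n_t, 2)) * cell[:, None, None]
    jit[-1] = 0.0  # keep the open boundary ring clean
    x = x + jit[:, :, 0]
    y = y + jit[:, :, 1]

    xs = np.concatenate([[0.0], x.ravel()])
    ys = np.concatenate([[0.0], y.ravel()])
    f = face_height_function(spec)
    zs = f(xs, ys)
    vertices = np.column_stack([xs, ys, zs])

    def vid(i_ring: int, j: int) -> int:
        return 1 + i_ring * n_t + (j % n_t)

    tris = []
    for j in range(n_t):
        tris.append((0, vid(0, j), vid(0, j + 1)))
    for i in range(n_r - 1):
        for j in range(n_t):
            a0, b0 = vid(i, j), vid(i, j + 1)
            c0, d0 = vid(i + 1, j + 1), vid(i + 1, j)
            # CCW seen from +Z (the polar->Cartesian map flips orientation)
            tris.append((a0, c0, b0))
            tris.append((a0, d0, c0))
    triangles = np.asarray(tris, dtype=np.int64)

    landmarks = _place_landmarks(vertices, spec)
    return TriSurfaceMesh(vertices, triangles, landmarks)


def _place_landmarks(vertices: np.ndarray, spec: SyntheticFaceSpec) -> dict[str, int]:
    from scipy.spatial import cKDTree

    f = face_height_function(spec)
    b = spec.face_height / 2.0
    y_nose = 0.05 * b
    y_chin = -0.72 * b

    # mid-line extrema of the generating function, found on a dense 1D scan
    yy = np.linspace(-b, b, 2001)
    zz = f(np.zeros_like(yy), yy)
    nose_zone = (yy > y_nose - 0.3 * b) & (yy < y_nose + 0.3 * b)
    y_pron = yy[nose_zone][np.argmax(zz[nose_zone])]
    upper = (yy > y_pron) & (yy < 0.8 * b)
    y_sell = yy[upper][np.argmin(zz[upper])] if np.any(upper) else y_pron
    chin_zone = (yy > y_chin - 0.15 * b) & (yy < y_chin + 0.15 * b)
    y_prom = yy[chin_zone][np.argmax(zz[chin_zone])]

    xc = 0.45 * spec.face_width / 2.0
    targets = {
        "pronasale": (0.0, y_pron),
        "sellion": (0.0, y_sell),
        "promentale": (0.0, y_prom),
        "left_cheek": (-xc, 0.0),
        "right_cheek": (xc, 0.0),
    }
    tree = cKDTree(vertices[:, :2])
    return {
        name: int(tree.query(np.asarray(t))[1]) for name, t in targets.items()
    }


#: loop angles (rad) of the four extra reference points used by the
#: enriched 12-point design: the sides of the nasal root and of the lip,
#: where an 8-point reference line loses contact with the face.
NASAL_LIP_EXTRA_ANGLES = tuple(np.radians([72.0, 108.0, 252.0, 288.0]))


def reference_loop_on_face(
    mesh_or_spec,
    n_points: int = 8,
    scale: float = 0.42,
    clearance: float = 0.5,
    center=(0.0, -0.05),
    aspect: float = 1.0,
    phase: float = 0.0,
    extra_angles=(),
) -> np.ndarray:
    """Build a closed loop of mask reference points hovering over the face.

    Points sit on an ellipse in XY (fraction ``scale`` of the face extents,
    shifted to ``center`` in normalized coordinates), at the local surface
    height plus ``clearance`` mm.  With the defaults the loop crosses the
    nose ridge and chin like a medical mask; ``extra_angles`` inserts
    additional reference points (e.g. :data:`NASAL_LIP_EXTRA_ANGLES`) at
    the given loop angles.  Accepts a :class:`SyntheticFaceSpec` (uses the
    analytic height field) so loops are exactly reproducible.
    """
    if isinstance(mesh_or_spec, SyntheticFaceSpec):
        spec = mesh_or_spec
        f = face_height_function(spec)
        a = spec.face_width / 2.0
        b = spec.face_height / 2.0
    else:  # pragma: no cover - convenience path for loaded meshes
        mesh = mesh_or_spec
        a = (mesh.vertices[:, 0].max() - mesh.vertices[:, 0].min()) / 2.0
        b = (mesh.vertices[:, 1].max() - mesh.vertices[:, 1].min()) / 2.0
        from scipy.interpolate import LinearNDInterpolator

        interp = LinearNDInterpolator(mesh.vertices[:, :2], mesh.vertices[:, 2])
        f = lambda x, y: np.nan_to_num(interp(x, y))  # noqa: E731

    t = np.sort(
        np.mod(
            np.concatenate(
                [
                    2.0 * np.pi * np.arange(n_points) / n_points + phase,
                    np.asarray(extra_angles, dtype=float),
                ]
            ),
            2.0 * np.pi,
        )
    )
    x = scale * a * np.cos(t) + center[0] * a
    y = scale * b * aspect * np.sin(t) + center[1] * b
    z = np.asarray(f(x, y)) + clearance
    return np.column_stack([x, y, z])


def structured_rectangle_mesh(
    nx: int, ny: int, width: float, height: float
) -> TriSurfaceMesh:
    """Flat rectangular plate mesh (nx x ny cells, alternating diagonals)."""
    xs = np.linspace(-width / 2.0, width / 2.0, nx + 1)
    ys = np.linspace(-height / 2.0, height / 2.0, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack(
        [xx.ravel(), yy.ravel(), np.zeros(xx.size)]
    )

    def vid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris.append((v00, v10, v11))
                tris.append((v00, v11, v01))
            else:
                tris.append((v00, v10, v01))
                tris.append((v10, v11, v01))
    return TriSurfaceMesh(vertices, np.asarray(tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex")
                vertices.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) for p in parts[1:]]
                if len(idx) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: face with {len(idx)} vertices "
                        "(only triangles are supported)"
                    )
                faces.append([i - 1 if i > 0 else len(vertices) + i for i in idx])
    if not vertices:
        raise MeshFormatError(f"{path}: no vertices found")
    return np.asarray(vertices, float), np.asarray(faces, np.int64)


def _parse_ascii_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        text = fh.read().decode("ascii", errors="replace")
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}: missing 'ply' magic")
    n_vert = n_face = None
    elements: list[tuple[str, int]] = []
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "element":
            elements.append((parts[1], int(parts[2])))
        elif parts[0] == "end_header":
            break
    for name, count in elements:
        if name == "vertex":
            n_vert = count
        elif name == "face":
            n_face = count
    if n_vert is None or n_face is None:
        raise MeshFormatError(f"{path}: PLY header lacks vertex/face elements")
    body = lines[i : i + n_vert + n_face]
    verts = np.array(
        [[float(v) for v in ln.split()[:3]] for ln in body[:n_vert]], float
    )
    faces = []
    for k, ln in enumerate(body[n_vert : n_vert + n_face]):
        parts = ln.split()
        cnt = int(parts[0])
        if cnt != 3:
            raise MeshFormatError(
                f"{path}: face {k} has {cnt} vertices (only triangles supported)"
            )
        faces.append([int(p) for p in parts[1:4]])
    return verts, np.asarray(faces, np.int64)


def _merge_duplicate_vertices(
    vertices: np.ndarray, triangles: np.ndarray, snap: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly-coincident vertices after snapping to a 1e-6 mm grid.

    STL stores each triangle's corners independently, so shared topology must
    be reconstructed.
    """
    keys = np.round(vertices / snap).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[np.sort(first)], rank[inverse][triangles]


def load_mesh(path, fmt: str | None = None) -> TriSurfaceMesh:
    """Load an OBJ / PLY / STL triangle mesh (coordinates in mm)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        vertices, triangles = _parse_obj(path)
    elif fmt == "ply":
        with open(path, "rb") as fh:
            head = fh.read(256)
        if b"format ascii" in head:
            vertices, triangles = _parse_ascii_ply(path)
        else:
            tm = _trimesh.load(str(path), file_type="ply", process=False)
            vertices, triangles = np.asarray(tm.vertices), np.asarray(tm.faces)
    elif fmt == "stl":
        tm = _trimesh.load(str(path), file_type="stl", process=False)
        vertices, triangles = _merge_duplicate_vertices(
            np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64)
        )
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    return TriSurfaceMesh(vertices, triangles)


def save_obj(mesh: TriSurfaceMesh, path) -> None:
    """Write OBJ (mm). Landmarks go in comments; use save_landmarks for data."""
    with open(path, "w") as fh:
        fh.write("# maskfit surface mesh, units mm\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def save_ply(mesh: TriSurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment maskfit, units mm\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def save_vtk(mesh: TriSurfaceMesh, path, point_data: dict | None = None) -> None:
    """Write a legacy-VTK unstructured grid with optional nodal scalar fields
    (e.g. ``contact_pressure_MPa``) for visualization."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("maskfit surface, units mm\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_triangles}\n")
        fh.write("\n".join(["5"] * mesh.n_triangles) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values, float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in values) + "\n")


def load_landmarks(path) -> dict[str, int]:
    with open(path) as fh:
        data = json.load(fh)
    return {str(k): int(v) for k, v in data.items()}


def save_landmarks(landmarks: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: int(v) for k, v in landmarks.items()}, fh, indent=2)
        fh.write("\n")
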
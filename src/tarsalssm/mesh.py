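"""Triangle-mesh container, icosphere construction and plain-text mesh I/O.

The mesh model used throughout the package is deliberately small: closed,
manifold, consistently wound triangle surfaces with outward normals (positive
signed volume), optionally carrying named vertex patches used as landmark
regions.  Surfaces are ASCII PLY / OBJ on disk so every artifact stays
diffable and text-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "TriMesh",
    "icosphere",
    "icosphere_vertex_count",
    "write_ply",
    "read_ply",
    "write_obj",
]


@dataclass
class TriMesh:
    """A triangle surface mesh in millimetre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Vertex index triples; consistent counter-clockwise winding seen from
        outside gives a positive signed volume.
    vertex_labels : dict[str, ndarray]
        Optional named vertex patches (landmark regions), label -> sorted
        vertex index array.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidInputError("faces must be an (m, 3) array")
        self.vertex_labels = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.vertex_labels.items()
        }

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.vertex_labels.items()},
        )

    def edges(self) -> np.ndarray:
        """Directed edges, one per face side: (3m, 2) array."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces
        with opposite orientation (closed, manifold, consistently wound)."""
        e = self.edges()
        if len(e) == 0:
            return False
        # consistent winding <=> every directed edge appears exactly once
        # and its reverse appears exactly once
        key = e[:, 0] * (self.n_vertices + 1) + e[:, 1]
        rev = e[:, 1] * (self.n_vertices + 1) + e[:, 0]
        uniq, counts = np.unique(key, return_counts=True)
        if np.any(counts != 1):
            return False
        return np.array_equal(np.sort(key), np.sort(rev))

    def signed_volume(self) -> float:
        """Signed volume by the divergence theorem; positive for outward
        winding."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def euler_characteristic(self) -> int:
        e = self.edges()
        und = np.unique(np.sort(e, axis=1), axis=0)
        return self.n_vertices - len(und) + self.n_faces

    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the vertices (the radial expansion origin)."""
        return self.vertices.mean(axis=0)

    def validate_closed(self) -> None:
        if not self.is_closed():
            raise InvalidInputError("mesh is not a closed, consistently wound manifold")
        if self.signed_volume() <= 0:
            raise InvalidInputError("mesh winding is inward (signed volume <= 0)")


# -- icosphere ---------------------------------------------------------


def icosphere_vertex_count(subdiv_level: int) -> int:
    """Vertex count of a subdivided icosahedron: 10 * 4**s + 2."""
    return 10 * 4**subdiv_level + 2


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def icosphere(subdiv_level: int = 3, radius: float = 1.0) -> TriMesh:
    """Unit-sphere triangulation by recursive icosahedron subdivision.

    Level ``s`` yields ``10 * 4**s + 2`` vertices and ``20 * 4**s`` faces,
    near-uniformly distributed on the sphere, with outward winding.
    """
    if subdiv_level < 0:
        raise InvalidInputError("subdiv_level must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(subdiv_level):
        midpoint: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midindex(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint.get(key)
            if idx is None:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                vlist.append(m)
                idx = len(vlist) - 1
                midpoint[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midindex(a, b), midindex(b, c), midindex(c, a)
            new_faces.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return TriMesh(verts * radius, faces)


# -- plain-text I/O ----------------------------------------------------


def write_ply(mesh: TriMesh, path: str | Path, normals: np.ndarray | None = None) -> None:
    """Write an ASCII PLY file; vertex labels go to a JSON sidecar."""
    path = Path(path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if normals is not None:
        lines += ["property float nx", "property float ny", "property float nz"]
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for i, v in enumerate(mesh.vertices):
        row = f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
        if normals is not None:
            n = normals[i]
            row += f" {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
    if mesh.vertex_labels:
        sidecar = {k: v.tolist() for k, v in mesh.vertex_labels.items()}
        path.with_suffix(path.suffix + ".labels.json").write_text(
            json.dumps(sidecar, sort_keys=True)
        )


def read_ply(path: str | Path) -> TriMesh:
    """Read an ASCII PLY written by :func:`write_ply` (x,y,z [+normals])."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise InvalidInputError(f"{path} is not a PLY file")
    n_vert = n_face = 0
    header_end = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            header_end = i + 1
            break
    verts = np.array(
        [[float(x) for x in lines[header_end + i].split()[:3]] for i in range(n_vert)]
    )
    faces = np.array(
        [
            [int(x) for x in lines[header_end + n_vert + i].split()[1:4]]
            for i in range(n_face)
        ],
        dtype=np.int64,
    )
    labels: dict[str, np.ndarray] = {}
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        labels = {k: np.asarray(v) for k, v in json.loads(sidecar.read_text()).items()}
    return TriMesh(verts, faces, labels)


def write_obj(mesh: TriMesh, path: str | Path) -> None:
    path = Path(path)
    lines = [f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")
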
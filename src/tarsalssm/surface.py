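"""Surface building from contour point clouds.

Normals are estimated by local plane fits over k-nearest neighbourhoods and
oriented outward from the cloud centroid.  The reconstruction step replaces
the screened-Poisson reconstruction (an external GUI tool in the original
workflow) with radial remeshing, exact for star-shaped surfaces: an
icosphere's directions are scaled by inverse-distance-weighted radii of the
angularly nearest cloud points.  The substitution keeps the whole chain
deterministic and testable, and matches the radial SPHARM representation the
surface feeds into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError, NotStarShapedError
from .mesh import TriMesh, icosphere
from .segmentation import PointCloud3D

__all__ = ["OrientedPointCloud", "estimate_normals", "radial_remesh"]

#: Maximum tolerated angular gap (degrees) between an icosphere direction and
#: the nearest cloud point before the cloud is declared not star-shaped.
MAX_ANGULAR_GAP_DEG = 30.0


@dataclass
class OrientedPointCloud:
    """Points with outward unit normals."""

    points_mm: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if len(self.points_mm) != len(self.normals):
            raise InvalidInputError("points and normals must have equal cardinality")
        norms = np.linalg.norm(self.normals, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidInputError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points_mm)


def estimate_normals(cloud: PointCloud3D, k: int = 12) -> OrientedPointCloud:
    """Per-point outward normals from k-nearest-neighbour plane fits.

    The normal is the smallest-variance principal direction of the k
    neighbours (plus the point itself), with sign flipped so it points away
    from the cloud centroid — correct for star-shaped clouds.  Neighbour ties
    at equal distance resolve to the lower point index.
    """
    pts = cloud.points_mm
    if k < 3:
        raise InvalidInputError("k must be >= 3")
    if len(pts) < k + 1:
        raise InvalidInputError(f"need at least k+1={k + 1} points, got {len(pts)}")
    tree = cKDTree(pts)
    # query k+2 and re-sort by (distance, index) for deterministic ties
    kk = min(k + 2, len(pts))
    dists, idx = tree.query(pts, k=kk)
    centroid = pts.mean(axis=0)
    normals = np.empty_like(pts)
    for i in range(len(pts)):
        order = np.lexsort((idx[i], np.round(dists[i], 12)))
        nbrs = idx[i][order][: k + 1]
        local = pts[nbrs] - pts[nbrs].mean(axis=0)
        cov = local.T @ local
        w, v = np.linalg.eigh(cov)
        if w[1] <= 1e-12 * max(w[2], 1e-30):
            raise InvalidInputError(
                f"degenerate neighbourhood at point {i}: neighbours are collinear "
                "or coincident"
            )
        n = v[:, 0]
        if n @ (pts[i] - centroid) < 0:
            n = -n
        normals[i] = n
    return OrientedPointCloud(pts, normals)


def radial_remesh(
    cloud: OrientedPointCloud | PointCloud3D,
    subdiv_level: int = 3,
    k_interp: int = 6,
) -> TriMesh:
    """Closed star-shaped surface through a point cloud by radial sampling.

    Every vertex direction of a level-``subdiv_level`` icosphere (10*4^s + 2
    vertices) receives a radius interpolated from the ``k_interp`` angularly
    nearest cloud points by inverse squared angular distance; an exact
    directional hit copies that radius.  If any icosphere direction has no
    cloud point within 30 degrees the cloud does not cover the sphere and a
    :class:`NotStarShapedError` reports the gap direction.
    """
    pts = cloud.points_mm
    if len(pts) < 4:
        raise InvalidInputError("need at least 4 points to remesh")
    center = pts.mean(axis=0)
    d = pts - center
    radii = np.linalg.norm(d, axis=1)
    if np.any(radii <= 0):
        raise InvalidInputError("a cloud point coincides with the centroid")
    units = d / radii[:, None]

    sphere = icosphere(subdiv_level)
    tree = cKDTree(units)
    kk = min(k_interp, len(pts))
    chord, idx = tree.query(sphere.vertices, k=kk)
    chord = np.atleast_2d(chord.reshape(len(sphere.vertices), kk))
    idx = idx.reshape(len(sphere.vertices), kk)
    ang = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))

    gap = ang[:, 0]
    worst = int(np.argmax(gap))
    if gap[worst] > np.deg2rad(MAX_ANGULAR_GAP_DEG):
        raise NotStarShapedError(
            f"angular coverage gap of {np.rad2deg(gap[worst]):.1f} deg at direction "
            f"{np.round(sphere.vertices[worst], 4).tolist()} — cloud is not "
            "star-shaped about its centroid"
        )

    exact = ang[:, 0] < 1e-12
    w = 1.0 / np.maximum(ang, 1e-12) ** 2
    r_interp = (w * radii[idx]).sum(axis=1) / w.sum(axis=1)
    r_interp[exact] = radii[idx[exact, 0]]

    verts = sphere.vertices * r_interp[:, None] + center
    out = TriMesh(verts, sphere.faces)
    out.validate_closed()
    return out
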
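"""Landmark-based rigid pose normalization.

Every bone is moved into a canonical frame by three rigid steps driven by its
landmark triple (a, b, c):

1. rotate by the angle alpha between the plane z = 0 and the landmark plane,
   about their intersection line, so the landmark-plane normal maps to +z;
2. translate by -c so landmark c sits at the origin;
3. fix the remaining in-plane freedom using the direction of landmark a
   (vector A), through the angle beta between the x axis and A.

Step 3 exists in two modes.  ``in_plane`` (default) rotates about the z axis
so A lands on the +x half-axis: the result is a well-defined canonical pose,
idempotent and invariant to any rigid motion of the input.  ``literal_x``
rotates about the x axis by beta, following the original verbal construction
verbatim; this tilts the landmark plane back out of z = 0 and leaves a
residual in-plane ambiguity, so it cannot be rigid-motion invariant — it is
provided for fidelity, not recommended.

No scaling is ever applied: bone size is part of the shape and is preserved
into the SPHARM coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegeneratePlaneError, InvalidInputError
from .landmarks import LandmarkTriple
from .mesh import TriMesh

__all__ = ["PoseTransform", "plane_angle", "normalize_pose"]


@dataclass
class PoseTransform:
    """Record of the three normalization steps applied to one bone.

    ``alpha_rad`` is the (unoriented) angle between the landmark plane and
    z = 0, always in [0, pi/2].  The rotation actually applied in step 1
    maps the *winding* normal (b - a) x (c - a) onto +z — the winding is
    intrinsic to the anatomy, which is what makes normalization invariant to
    rigid motions — so its angle ``theta1_rad`` in [0, pi] can exceed alpha
    (theta1 = pi - alpha when the winding normal points below the z = 0
    plane).  Composing rotation(axis1, theta1), translation by -C, and the
    step-3 rotation reproduces the normalized landmarks.
    """

    alpha_rad: float
    axis1: np.ndarray | None  # unit rotation axis of step 1; None when theta1 = 0
    C_mm: np.ndarray  # translation applied in step 2 (the moved landmark c)
    beta_rad: float
    mode: str  # {in_plane, literal_x}
    theta1_rad: float = 0.0
    gamma3_rad: float = 0.0  # signed step-3 rotation actually applied

    def __post_init__(self) -> None:
        if self.axis1 is not None:
            self.axis1 = np.asarray(self.axis1, dtype=float)
        self.C_mm = np.asarray(self.C_mm, dtype=float)
        if not 0.0 <= self.alpha_rad <= np.pi / 2 + 1e-12:
            raise InvalidInputError("alpha must lie in [0, pi/2]")
        if not 0.0 <= self.beta_rad <= np.pi + 1e-12:
            raise InvalidInputError("beta must lie in [0, pi]")
        if self.mode not in ("in_plane", "literal_x"):
            raise InvalidInputError("mode must be 'in_plane' or 'literal_x'")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Replay the recorded steps on raw input points."""
        pts = np.asarray(points, dtype=float)
        if self.axis1 is not None:
            pts = _rotation_about(self.axis1, self.theta1_rad).apply(pts)
        pts = pts - self.C_mm
        axis3 = np.array([0.0, 0.0, 1.0]) if self.mode == "in_plane" else np.array([1.0, 0.0, 0.0])
        return _rotation_about(axis3, self.gamma3_rad).apply(pts)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha_rad": self.alpha_rad,
                    "axis1": None if self.axis1 is None else self.axis1.tolist(),
                    "theta1_rad": self.theta1_rad,
                    "C_mm": self.C_mm.tolist(),
                    "beta_rad": self.beta_rad,
                    "gamma3_rad": self.gamma3_rad,
                    "mode": self.mode,
                },
                sort_keys=True,
            )
        )


def plane_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> tuple[float, np.ndarray | None]:
    """Angle between the plane z = 0 and the plane through a, b, c.

    The plane normal n = (b - a) x (c - a) is normalized with its sign chosen
    so n_z >= 0 (ties: first nonzero of n_x, n_y positive); the returned
    angle alpha = arccos(n_z) lies in [0, pi/2].  The rotation axis for step
    1 is the intersection-line direction n x z-hat, or None when alpha = 0.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise DegeneratePlaneError("landmark points are collinear; plane undefined")
    n = n / norm
    if n[2] < 0 or (n[2] == 0 and (n[0] < 0 or (n[0] == 0 and n[1] < 0))):
        n = -n
    alpha = float(np.arccos(np.clip(n[2], -1.0, 1.0)))
    if alpha < 1e-12:
        return 0.0, None
    axis = np.cross(n, np.array([0.0, 0.0, 1.0]))
    axis /= np.linalg.norm(axis)
    return alpha, axis


def _rotation_about(axis: np.ndarray, angle: float) -> Rotation:
    return Rotation.from_rotvec(np.asarray(axis, dtype=float) * angle)


def normalize_pose(
    mesh: TriMesh, lm: LandmarkTriple, mode: str = "in_plane"
) -> tuple[TriMesh, LandmarkTriple, PoseTransform]:
    """Move a bone into the canonical landmark frame.

    Returns the transformed mesh, the transformed landmarks, and the recorded
    :class:`PoseTransform`.  In ``in_plane`` mode the result satisfies:
    landmark c at the origin, landmark a on the +x half-axis, landmark b in
    the z = 0 plane, independent (to ~1e-9) of any rigid motion applied to
    the input.
    """
    if mode not in ("in_plane", "literal_x"):
        raise InvalidInputError("mode must be 'in_plane' or 'literal_x'")
    lm.validate()
    alpha, _ = plane_angle(lm.a_mm, lm.b_mm, lm.c_mm)

    # step 1 rotates the intrinsic winding normal (b-a) x (c-a) onto +z:
    # the winding travels with the bone under any rigid motion, so the
    # normalized pose does not depend on how the input was placed
    n_raw = np.cross(lm.b_mm - lm.a_mm, lm.c_mm - lm.a_mm)
    n_raw = n_raw / np.linalg.norm(n_raw)
    cross = np.cross(n_raw, np.array([0.0, 0.0, 1.0]))
    s = np.linalg.norm(cross)
    theta1 = float(np.arctan2(s, n_raw[2]))
    if s < 1e-12:
        axis1 = None if n_raw[2] > 0 else np.array([1.0, 0.0, 0.0])
        theta1 = 0.0 if n_raw[2] > 0 else float(np.pi)
    else:
        axis1 = cross / s

    verts = mesh.vertices
    pts = lm.points()
    if axis1 is not None:
        rot1 = _rotation_about(axis1, theta1)
        verts = rot1.apply(verts)
        pts = rot1.apply(pts)

    C = pts[2].copy()
    verts = verts - C
    pts = pts - C

    A = pts[0]
    beta = float(np.arccos(np.clip(A[0] / np.linalg.norm(A), -1.0, 1.0)))
    if mode == "in_plane":
        gamma = float(-np.arctan2(A[1], A[0]))
        rot3 = _rotation_about(np.array([0.0, 0.0, 1.0]), gamma)
    else:
        # verbatim construction: rotate about x-hat by beta; with A in z = 0
        # both signs leave the same |A_z|, so the positive sign is canonical
        gamma = beta
        rot3 = _rotation_about(np.array([1.0, 0.0, 0.0]), gamma)
    verts = rot3.apply(verts)
    pts = rot3.apply(pts)

    out_mesh = TriMesh(
        verts, mesh.faces.copy(), {k: v.copy() for k, v in mesh.vertex_labels.items()}
    )
    out_lm = LandmarkTriple(
        pts[0], pts[1], pts[2], lm.bone, lm.a_idx, lm.b_idx, lm.c_idx
    )
    transform = PoseTransform(alpha, axis1, C, beta, mode, theta1, gamma)
    return out_mesh, out_lm, transform
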
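"""Automatic landmark location on labeled bone surfaces.

Each bone carries three anatomical landmarks (a, b, c) defined in the field
as extremal points of named surface features, e.g. the highest point of the
talar trochlea or the most posterior point of the cuboid tuberosity.  Since
no algorithm can recognise an unnamed articular facet from raw geometry, the
anatomy-recognition step is factored out: surfaces arrive with labeled vertex
patches (painted by the synthetic generator or by user annotation), and each
landmark is the extremal vertex of its patch along a stated anatomical
direction.  "Highest/lowest" queries project on z, "most posterior" on y; the
axis mapping is configurable through the rule directions.

An override map (label -> vertex index) stands in for the expert intervention
occasionally needed on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, MissingRegionError
from .mesh import TriMesh

__all__ = ["LandmarkRule", "LandmarkTriple", "find_extremal_vertex", "detect_landmarks"]

#: Minimal triangle area (mm^2) below which a landmark triple is considered
#: collinear and rejected.
COLLINEARITY_TOL = 1e-9


@dataclass(frozen=True)
class LandmarkRule:
    """Extremal-projection query: search ``region_label`` for the vertex with
    maximal (or minimal) projection onto ``direction``."""

    region_label: str
    direction: tuple[float, float, float]
    sense: str = "max"  # {max, min}

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise InvalidInputError(f"rule direction must be unit length, got {d}")
        if self.sense not in ("max", "min"):
            raise InvalidInputError("sense must be 'max' or 'min'")

    def mirrored(self) -> "LandmarkRule":
        """The same anatomical rule for the contralateral (x-reflected) side."""
        dx, dy, dz = self.direction
        return LandmarkRule(self.region_label, (-dx, dy, dz), self.sense)


@dataclass
class LandmarkTriple:
    """The three anatomical points a, b, c of one bone, as mesh vertices."""

    a_mm: np.ndarray
    b_mm: np.ndarray
    c_mm: np.ndarray
    bone: str
    a_idx: int
    b_idx: int
    c_idx: int

    def __post_init__(self) -> None:
        self.a_mm = np.asarray(self.a_mm, dtype=float)
        self.b_mm = np.asarray(self.b_mm, dtype=float)
        self.c_mm = np.asarray(self.c_mm, dtype=float)

    def points(self) -> np.ndarray:
        return np.stack([self.a_mm, self.b_mm, self.c_mm])

    def triangle_area(self) -> float:
        return 0.5 * float(
            np.linalg.norm(np.cross(self.b_mm - self.a_mm, self.c_mm - self.a_mm))
        )

    def validate(self) -> None:
        idx = {self.a_idx, self.b_idx, self.c_idx}
        if len(idx) != 3:
            raise InvalidInputError("landmark vertices must be pairwise distinct")
        if self.triangle_area() <= COLLINEARITY_TOL:
            raise InvalidInputError(
                "landmarks are collinear (triangle area below tolerance); "
                "supply an override map to fix the offending point"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "bone": self.bone,
                    "a": {"idx": int(self.a_idx), "mm": self.a_mm.tolist()},
                    "b": {"idx": int(self.b_idx), "mm": self.b_mm.tolist()},
                    "c": {"idx": int(self.c_idx), "mm": self.c_mm.tolist()},
                },
                sort_keys=True,
            )
        )


def find_extremal_vertex(mesh: TriMesh, rule: LandmarkRule) -> int:
    """Index of the labeled vertex with extremal projection on the rule
    direction.

    Ties are broken by lexicographic vertex coordinates, then lowest index,
    so the result is reproducible across runs and vertex orderings.
    """
    if rule.region_label not in mesh.vertex_labels:
        raise MissingRegionError(
            f"mesh carries no vertex region labeled {rule.region_label!r}"
        )
    members = np.asarray(mesh.vertex_labels[rule.region_label], dtype=np.int64)
    if members.size == 0:
        raise MissingRegionError(f"region {rule.region_label!r} is empty")
    pts = mesh.vertices[members]
    proj = pts @ np.asarray(rule.direction)
    if rule.sense == "min":
        proj = -proj
    best = proj.max()
    cand = np.flatnonzero(proj >= best - 0.0)  # exact ties only
    if cand.size > 1:
        order = np.lexsort(
            (members[cand], pts[cand, 2], pts[cand, 1], pts[cand, 0])
        )
        return int(members[cand[order[0]]])
    return int(members[cand[0]])


def detect_landmarks(
    mesh: TriMesh,
    bone: str,
    rules: tuple[LandmarkRule, LandmarkRule, LandmarkRule],
    override: dict[str, int] | None = None,
) -> LandmarkTriple:
    """Apply the three extremal-vertex rules (a, b, c) and validate the
    resulting triple.

    ``override`` maps landmark names ('a', 'b', 'c') to vertex indices and
    takes precedence over the corresponding rule — the computational stand-in
    for expert correction of a mis-detected point.
    """
    if len(rules) != 3:
        raise InvalidInputError("exactly three landmark rules are required")
    labels = [r.region_label for r in rules]
    if len(set(labels)) != 3:
        raise InvalidInputError(f"landmark rules must have distinct region labels, got {labels}")
    override = override or {}
    idx = []
    for name, rule in zip("abc", rules):
        if name in override:
            i = int(override[name])
            if not 0 <= i < mesh.n_vertices:
                raise InvalidInputError(f"override index {i} for {name!r} out of range")
            idx.append(i)
        else:
            idx.append(find_extremal_vertex(mesh, rule))
    triple = LandmarkTriple(
        mesh.vertices[idx[0]], mesh.vertices[idx[1]], mesh.vertices[idx[2]],
        bone, idx[0], idx[1], idx[2],
    )
    triple.validate()
    return triple
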
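"""Synthetic populations of bone-like shapes with known ground truth.

The study population this emulates — 15 left and 15 right tarsal-bone models
for each of four bone classes — came from CT scans that are not publicly
deposited.  The generator therefore produces star-shaped, closed surfaces
from per-class mean SPHARM coefficient vectors (degree L = 4, 25
coefficients) with independent Gaussian inter-subject variation, painted
landmark patches, mirror-related left/right sides, and optional voxelization
into noisy CT-like volumes.  Every downstream stage — segmentation, surface
building, landmarking, pose normalization, SPHARM fitting, statistics,
classification — can thus be tested against known coefficients.

Modeling choices
----------------
* Class mean radii and the number/size of discriminating coefficients are
  invented (the study reports no coefficient values); classes differ by at
  least 3 SD in 5-10 low-order coefficients so that near-perfect class
  separability, as observed on the real bones, is emulated.
* Degree-1 coefficients are zero with zero variance: in a radial expansion
  they encode translation of the expansion origin rather than shape, and the
  parameterization recenters every surface at its vertex centroid.
* Left bones are mirrored *independent* draws from the class mean — the two
  sides share mean shape without assuming subject-level symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, InvalidInputError
from .landmarks import LandmarkRule, LandmarkTriple, detect_landmarks
from .mesh import TriMesh, icosphere
from .spharm import (
    SPHARMModel,
    directions_to_angles,
    index_from_lm,
    real_sph_harm_basis,
)
from .volume import VoxelVolume

__all__ = [
    "BoneClassSpec",
    "SyntheticSample",
    "default_class_specs",
    "landmark_rules_for",
    "mesh_from_coeffs",
    "sample_population",
    "mirror_shape",
    "voxelize",
]

#: Generating degree of the class means: (4+1)^2 = 25 coefficients,
#: matching the number of coefficients reported descriptively.
DEFAULT_L = 4

#: Angular radius (degrees) of the painted landmark patches.
PATCH_ANGLE_DEG = 10.0

#: Redraws allowed when a drawn coefficient vector yields a non-positive
#: radius function, before failing loudly.
MAX_RETRIES = 100

# The three patch directions shared by all default classes (right side);
# pairwise separated by >= 110 degrees so patches never overlap.
_PATCH_DIRS = np.array(
    [
        [0.0, 0.0, 1.0],
        [0.93969262, 0.0, -0.34202014],
        [-0.60402277, 0.71984631, -0.34202014],
    ]
)


@dataclass
class BoneClassSpec:
    """Generating model of one bone class.

    ``mean_coeffs`` is the class-mean real SPHARM vector (length (L+1)^2,
    flat index k = l^2 + l + m); ``coeff_sd`` the per-coefficient Gaussian SD
    of inter-subject variation; ``landmark_patch_dirs`` the three unit
    directions around which landmark patches a, b, c are painted.
    """

    name: str
    mean_coeffs: np.ndarray
    coeff_sd: np.ndarray
    landmark_patch_dirs: np.ndarray = field(
        default_factory=lambda: _PATCH_DIRS.copy()
    )

    def __post_init__(self) -> None:
        self.mean_coeffs = np.asarray(self.mean_coeffs, dtype=float)
        self.coeff_sd = np.asarray(self.coeff_sd, dtype=float)
        self.landmark_patch_dirs = np.asarray(self.landmark_patch_dirs, dtype=float)
        if self.mean_coeffs.shape != self.coeff_sd.shape:
            raise InvalidInputError("mean_coeffs and coeff_sd must share a shape")
        if np.any(self.coeff_sd < 0):
            raise InvalidInputError("coeff_sd must be elementwise nonnegative")
        L = int(np.sqrt(self.mean_coeffs.size)) - 1
        if (L + 1) ** 2 != self.mean_coeffs.size:
            raise InvalidInputError("coefficient vector length must be a square")
        d = self.landmark_patch_dirs
        if d.shape != (3, 3):
            raise InvalidInputError("landmark_patch_dirs must be three 3-vectors")
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(np.cross(d[i], d[j])) < 1e-6:
                    raise InvalidInputError("patch directions must be pairwise non-parallel")

    @property
    def L(self) -> int:
        return int(np.sqrt(self.mean_coeffs.size)) - 1


@dataclass
class SyntheticSample:
    """One generated bone surface with its ground truth."""

    class_name: str
    side: str  # {left, right}
    coeffs_true: np.ndarray
    mesh: TriMesh
    landmarks_true: LandmarkTriple
    subject_id: int
    seed: int


def _coeff_vector(L: int, entries: dict[tuple[int, int], float]) -> np.ndarray:
    c = np.zeros((L + 1) ** 2)
    for (l, m), v in entries.items():
        c[index_from_lm(l, m)] = v
    return c


def default_class_specs(coeff_sd: float = 0.5, c0_sd: float = 3.0) -> list[BoneClassSpec]:
    """The four default bone classes (calcaneus-, cuboid-, navicular-,
    talus-like).

    Mean radii (35 / 17 / 16 / 27 mm) follow typical adult male tarsal bone
    scale; shape coefficients are chosen so every class pair differs by
    >= 3 SD in 5-10 coefficients.  SDs are parameters, not constants, since
    the real inter-subject variances are unknown.
    """
    two_sqrt_pi = 2.0 * np.sqrt(np.pi)
    shapes: dict[str, tuple[float, dict[tuple[int, int], float]]] = {
        "calcaneus": (35.0, {(2, 0): 6.0, (2, 2): 3.0, (3, 0): 2.0,
                             (3, 2): -1.5, (4, 0): 1.5}),
        "cuboid": (17.0, {(2, 0): 2.0, (2, 2): -2.5, (3, 2): 1.5,
                          (4, 0): -1.0, (3, -2): 1.5}),
        "navicular": (16.0, {(2, 0): -4.5, (2, 2): 1.5, (3, 0): -1.8,
                             (4, 0): 0.8, (3, 3): 1.5}),
        "talus": (27.0, {(2, 0): 3.5, (2, 2): 1.0, (3, 0): 1.8,
                         (3, 2): -1.6, (2, -1): 1.8}),
    }
    specs = []
    for name, (mean_radius, entries) in shapes.items():
        mean = _coeff_vector(DEFAULT_L, entries)
        mean[0] = mean_radius * two_sqrt_pi
        sd = np.full_like(mean, coeff_sd)
        sd[0] = c0_sd
        sd[1:4] = 0.0  # degree-1 harmonics: translation, not shape
        specs.append(BoneClassSpec(name, mean, sd))
    return specs


def landmark_rules_for(
    spec: BoneClassSpec, side: str = "right"
) -> tuple[LandmarkRule, LandmarkRule, LandmarkRule]:
    """Extremal-projection rules matching the painted patches: each landmark
    is the patch vertex furthest along the patch direction (mirrored in x for
    left bones)."""
    rules = tuple(
        LandmarkRule(label, tuple(d), "max")
        for label, d in zip("abc", spec.landmark_patch_dirs)
    )
    if side == "left":
        rules = tuple(r.mirrored() for r in rules)
    elif side != "right":
        raise InvalidInputError("side must be 'left' or 'right'")
    return rules


def mesh_from_coeffs(
    coeffs: np.ndarray,
    subdiv_level: int = 3,
    patch_dirs: np.ndarray | None = None,
    patch_angle_deg: float = PATCH_ANGLE_DEG,
) -> TriMesh:
    """Band-limited star-shaped surface: icosphere directions scaled by the
    SPHARM radius function, optionally with painted landmark patches.

    Raises :class:`GenerationError` when the radius function is non-positive
    anywhere on the sampling.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    L = int(np.sqrt(coeffs.size)) - 1
    sphere = icosphere(subdiv_level)
    units = sphere.vertices
    thetas, phis = directions_to_angles(units)
    radii = real_sph_harm_basis(L, thetas, phis) @ coeffs
    if np.any(radii <= 0):
        worst = np.argsort(np.abs(coeffs))[::-1][:5]
        raise GenerationError(
            f"radius function non-positive at {int(np.sum(radii <= 0))} directions; "
            f"largest coefficient magnitudes at k={worst.tolist()}: "
            f"{np.round(coeffs[worst], 3).tolist()}"
        )
    labels: dict[str, np.ndarray] = {}
    if patch_dirs is not None:
        cos_cap = np.cos(np.deg2rad(patch_angle_deg))
        for label, d in zip("abc", np.asarray(patch_dirs, dtype=float)):
            dots = units @ d
            members = np.flatnonzero(dots >= cos_cap)
            if members.size == 0:  # cap smaller than vertex spacing
                members = np.array([int(np.argmax(dots))])
            labels[label] = members
    return TriMesh(units * radii[:, None], sphere.faces, labels)


def true_model(sample: SyntheticSample) -> SPHARMModel:
    """The generating coefficients of a sample as a SPHARM model."""
    return SPHARMModel(
        int(np.sqrt(sample.coeffs_true.size)) - 1,
        sample.coeffs_true.copy(),
        np.zeros(3),
    )


def sample_population(
    spec: BoneClassSpec,
    n_per_side: int,
    seed: int,
    subdiv_level: int = 3,
) -> list[SyntheticSample]:
    """Draw ``n_per_side`` right and ``n_per_side`` left samples of a class.

    Right-side coefficient vectors are ``mean + sd * N(0, 1)`` draws; left
    samples are mirrored surfaces of further independent draws.  Draws whose
    radius function is non-positive are redrawn (at most
    :data:`MAX_RETRIES` times).  Identical ``(spec, n_per_side, seed)``
    reproduce the returned list bit for bit.
    """
    if n_per_side < 1:
        raise InvalidInputError("n_per_side must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    for side in ("right", "left"):
        rules = landmark_rules_for(spec, side)
        for subject in range(n_per_side):
            mesh = None
            for _attempt in range(MAX_RETRIES):
                coeffs = spec.mean_coeffs + spec.coeff_sd * rng.standard_normal(
                    spec.mean_coeffs.size
                )
                try:
                    mesh = mesh_from_coeffs(
                        coeffs, subdiv_level, spec.landmark_patch_dirs
                    )
                    break
                except GenerationError:
                    mesh = None
            if mesh is None:
                raise GenerationError(
                    f"class {spec.name!r}: no positive radius function within "
                    f"{MAX_RETRIES} redraws; coefficient SDs are too large for "
                    "the mean shape"
                )
            if side == "left":
                lm_right = detect_landmarks(mesh, spec.name, landmark_rules_for(spec, "right"))
                mesh, landmarks = mirror_shape(mesh, lm_right)
            else:
                landmarks = detect_landmarks(mesh, spec.name, rules)
            samples.append(
                SyntheticSample(
                    class_name=spec.name,
                    side=side,
                    coeffs_true=coeffs,
                    mesh=mesh,
                    landmarks_true=landmarks,
                    subject_id=subject,
                    seed=seed,
                )
            )
    return samples


def mirror_shape(
    mesh: TriMesh, landmarks: LandmarkTriple | None = None
) -> tuple[TriMesh, LandmarkTriple | None]:
    """Reflect a closed surface across the x = 0 plane.

    Face winding is flipped so outward orientation (positive signed volume)
    is preserved; vertex labels keep their indices; landmark coordinates are
    reflected in place.
    """
    mesh.validate_closed()
    verts = mesh.vertices.copy()
    verts[:, 0] *= -1.0
    faces = mesh.faces[:, [0, 2, 1]].copy()
    out = TriMesh(verts, faces, {k: v.copy() for k, v in mesh.vertex_labels.items()})
    if landmarks is None:
        return out, None
    refl = LandmarkTriple(
        landmarks.a_mm * np.array([-1.0, 1.0, 1.0]),
        landmarks.b_mm * np.array([-1.0, 1.0, 1.0]),
        landmarks.c_mm * np.array([-1.0, 1.0, 1.0]),
        landmarks.bone,
        landmarks.a_idx,
        landmarks.b_idx,
        landmarks.c_idx,
    )
    return out, refl


def voxelize(
    mesh: TriMesh,
    spacing_mm: float,
    inside_level: float = 1200.0,
    outside_level: float = 40.0,
    noise_sd: float = 30.0,
    seed: int = 0,
    sagittal_axis: int = 0,
) -> VoxelVolume:
    """Rasterize a closed surface into a CT-like intensity volume.

    Voxel centres inside the surface get ``inside_level``, outside
    ``outside_level`` (defaults are Hounsfield-like bone vs. soft tissue),
    plus Gaussian noise of SD ``noise_sd``.  The grid pads the mesh bounding
    box by two voxels on every side.  Inside/outside is decided by even-odd
    parity of surface crossings along vertical (z) rays through each voxel
    column — exact for closed meshes.
    """
    if spacing_mm <= 0:
        raise InvalidInputError("spacing must be positive")
    mesh.validate_closed()
    v = mesh.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    if np.any(hi - lo <= 0):
        raise InvalidInputError("degenerate (zero-extent) mesh cannot be voxelized")
    # voxels are cells of a world-anchored lattice (cell centres at
    # (i + 1/2) * spacing), covering the bounding box padded by >= 2 voxels;
    # anchoring the grid to the world rather than to the object keeps grids
    # of different objects comparable and leaves grid-vs-surface alignment —
    # which biases digital volume estimates when symmetric — to the object's
    # placement, as in a real scanner
    i_lo = np.floor((lo - 2.0 * spacing_mm) / spacing_mm).astype(int)
    i_hi = np.ceil((hi + 2.0 * spacing_mm) / spacing_mm).astype(int)
    shape = i_hi - i_lo
    origin = (i_lo + 0.5) * spacing_mm
    nx, ny, nz = (int(s) for s in shape)

    xs = origin[0] + spacing_mm * np.arange(nx)
    ys = origin[1] + spacing_mm * np.arange(ny)
    zs = origin[2] + spacing_mm * np.arange(nz)

    inside = _scanline_inside(mesh, xs, ys, zs, spacing_mm)
    values = np.where(inside, inside_level, outside_level).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return VoxelVolume(values, np.full(3, float(spacing_mm)), origin, sagittal_axis)


def _scanline_inside(
    mesh: TriMesh, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray, spacing: float
) -> np.ndarray:
    """Even-odd parity point-in-mesh test along +z rays per (x, y) column."""
    # tiny deterministic ray offset avoids exact edge/vertex hits
    eps = 1e-7 * spacing
    nx, ny, nz = len(xs), len(ys), len(zs)
    crossings: list[list[list[float]]] = [[[] for _ in range(ny)] for _ in range(nx)]
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    for a, b, c in tri:
        x0 = min(a[0], b[0], c[0])
        x1 = max(a[0], b[0], c[0])
        y0 = min(a[1], b[1], c[1])
        y1 = max(a[1], b[1], c[1])
        i0, i1 = np.searchsorted(xs, [x0 - eps, x1 + eps])
        j0, j1 = np.searchsorted(ys, [y0 - eps, y1 + eps])
        if i0 == i1 or j0 == j1:
            continue
        px = xs[i0:i1] + eps
        py = ys[j0:j1] + eps * np.sqrt(2.0)
        PX, PY = np.meshgrid(px, py, indexing="ij")
        d1x, d1y = b[0] - a[0], b[1] - a[1]
        d2x, d2y = c[0] - a[0], c[1] - a[1]
        det = d1x * d2y - d1y * d2x
        if abs(det) < 1e-30:
            continue  # triangle vertical in z; parity handled by neighbours
        rx, ry = PX - a[0], PY - a[1]
        u = (rx * d2y - ry * d2x) / det
        w = (d1x * ry - d1y * rx) / det
        hit = (u >= 0) & (w >= 0) & (u + w <= 1)
        if not hit.any():
            continue
        zhit = a[2] + u * (b[2] - a[2]) + w * (c[2] - a[2])
        ii, jj = np.nonzero(hit)
        for k in range(len(ii)):
            crossings[i0 + ii[k]][j0 + jj[k]].append(float(zhit[ii[k], jj[k]]))
    inside = np.zeros((nx, ny, nz), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            cr = sorted(crossings[i][j])
            if len(cr) < 2:
                continue
            if len(cr) % 2 == 1:  # degenerate grazing hit: drop the duplicate
                cr = _dedupe_crossings(cr)
            for lo_z, hi_z in zip(cr[0::2], cr[1::2]):
                k0, k1 = np.searchsorted(zs, [lo_z, hi_z])
                inside[i, j, k0:k1] = True
    return inside


def _dedupe_crossings(cr: list[float], tol: float = 1e-9) -> list[float]:
    out: list[float] = []
    for z in cr:
        if out and abs(z - out[-1]) < tol:
            out.pop()
        else:
            out.append(z)
    return out
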
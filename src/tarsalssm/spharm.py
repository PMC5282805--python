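"""Spherical-harmonics (SPHARM) shape decomposition of star-shaped surfaces.

The surface radius about the vertex centroid is treated as a scalar function
on the unit sphere and expanded in a real orthonormal spherical-harmonic
basis.  The coefficient vector is the shape descriptor used by the statistical
shape model and the bone classifier; its length for maximum degree L is
(L+1)^2 and the flat index is k = l^2 + l + m with sine harmonics at m < 0,
the zonal harmonic at m = 0 and cosine harmonics at m > 0.  The basis carries
no Condon-Shortley phase, so for the unit sphere the single nonzero
coefficient is c_0 = 2*sqrt(pi).

Model order is selected by the minimum-description-length criterion for
regression, MDL(L) = (N/2) ln(RSS_L / N) + ((L+1)^2 / 2) ln N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import sph_harm_y

from .errors import ConditioningError, InvalidInputError, InvalidShapeError, NotStarShapedError
from .mesh import TriMesh, icosphere

__all__ = [
    "SphericalSamples",
    "SPHARMModel",
    "real_sph_harm_basis",
    "lm_from_index",
    "index_from_lm",
    "parameterize",
    "fit_spharm",
    "select_order_mdl",
    "reconstruct_radii",
    "reconstruct_mesh",
]


def index_from_lm(l: int, m: int) -> int:
    """Flat coefficient index k = l^2 + l + m."""
    if abs(m) > l:
        raise InvalidInputError(f"|m| must be <= l, got l={l}, m={m}")
    return l * l + l + m


def lm_from_index(k: int) -> tuple[int, int]:
    """Inverse of :func:`index_from_lm`."""
    l = int(np.floor(np.sqrt(k)))
    return l, k - l * l - l


def real_sph_harm_basis(L: int, thetas: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Design matrix of real orthonormal spherical harmonics.

    Columns follow k = l^2 + l + m for l = 0..L.  Built from the complex
    harmonics Y_l^m(theta, phi) as

        m = 0:  Y_l^0            (real already)
        m > 0:  sqrt(2) (-1)^m Re Y_l^m
        m < 0:  sqrt(2) (-1)^m Im Y_l^|m|

    which cancels the Condon-Shortley phase and keeps orthonormality under
    the solid-angle inner product.
    """
    thetas = np.asarray(thetas, dtype=float)
    phis = np.asarray(phis, dtype=float)
    n = thetas.size
    B = np.empty((n, (L + 1) ** 2))
    for l in range(L + 1):
        for m in range(l + 1):
            y = sph_harm_y(l, m, thetas, phis)
            if m == 0:
                B[:, index_from_lm(l, 0)] = y.real
            else:
                sign = (-1.0) ** m
                B[:, index_from_lm(l, m)] = np.sqrt(2.0) * sign * y.real
                B[:, index_from_lm(l, -m)] = np.sqrt(2.0) * sign * y.imag
    return B


@dataclass
class SphericalSamples:
    """Radius samples of a star-shaped surface in spherical coordinates."""

    thetas: np.ndarray  # polar angle in [0, pi]
    phis: np.ndarray  # azimuth in [0, 2*pi)
    radii_mm: np.ndarray  # positive radii
    origin_mm: np.ndarray  # expansion origin

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.phis = np.asarray(self.phis, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if not (self.thetas.shape == self.phis.shape == self.radii_mm.shape):
            raise InvalidInputError("thetas, phis and radii must share a shape")
        if np.any(self.radii_mm <= 0):
            raise InvalidInputError("all radii must be positive")

    @property
    def n(self) -> int:
        return self.radii_mm.size


@dataclass
class SPHARMModel:
    """Degree-ordered real SPHARM coefficient vector for one bone surface."""

    L: int
    coeffs: np.ndarray  # length (L+1)^2, flat index k = l^2 + l + m
    origin_mm: np.ndarray
    rms_residual_mm: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.coeffs.size != (self.L + 1) ** 2:
            raise InvalidInputError(
                f"coefficient vector must have length {(self.L + 1) ** 2} for L={self.L}"
            )

    def truncated(self, L_new: int) -> "SPHARMModel":
        """Keep coefficients up to degree ``L_new`` (no refit)."""
        if L_new > self.L:
            raise InvalidInputError("cannot truncate to a higher degree")
        return SPHARMModel(
            L_new, self.coeffs[: (L_new + 1) ** 2].copy(), self.origin_mm.copy(),
            self.rms_residual_mm,
        )

    def to_csv(self, path: str | Path) -> None:
        lines = ["l,m,k,value"]
        for k, c in enumerate(self.coeffs):
            l, m = lm_from_index(k)
            lines.append(f"{l},{m},{k},{c:.12g}")
        Path(path).write_text("\n".join(lines) + "\n")


def directions_to_angles(units: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction vectors -> (theta, phi) with phi wrapped to [0, 2*pi)."""
    thetas = np.arccos(np.clip(units[:, 2], -1.0, 1.0))
    phis = np.mod(np.arctan2(units[:, 1], units[:, 0]), 2.0 * np.pi)
    return thetas, phis


def parameterize(mesh: TriMesh, star_check: bool = True) -> SphericalSamples:
    """Radial spherical parameterization of a closed star-shaped mesh.

    The expansion origin is the vertex centroid.  Each vertex maps to
    (theta, phi, r).  A star-shape violation — two vertices whose directions
    agree within 0.1 degree while their radii differ by more than 1% — raises
    :class:`NotStarShapedError`.
    """
    mesh.validate_closed()
    origin = mesh.centroid()
    d = mesh.vertices - origin
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise NotStarShapedError("a vertex coincides with the expansion origin")
    units = d / r[:, None]
    if star_check:
        _check_unique_directions(units, r)
    thetas, phis = directions_to_angles(units)
    return SphericalSamples(thetas, phis, r, origin)


def _check_unique_directions(units: np.ndarray, radii: np.ndarray) -> None:
    from scipy.spatial import cKDTree

    chord = 2.0 * np.sin(np.deg2rad(0.1) / 2.0)
    tree = cKDTree(units)
    pairs = tree.query_pairs(chord, output_type="ndarray")
    if len(pairs):
        ri, rj = radii[pairs[:, 0]], radii[pairs[:, 1]]
        rel = np.abs(ri - rj) / np.maximum(ri, rj)
        bad = rel > 0.01
        if np.any(bad):
            i, j = pairs[bad][0]
            raise NotStarShapedError(
                f"vertices {i} and {j} share a direction (within 0.1 deg) but their "
                f"radii differ by {rel[bad][0] * 100:.2f}% — surface is not "
                "star-shaped about the centroid"
            )


def fit_spharm(samples: SphericalSamples, L: int) -> SPHARMModel:
    """Least-squares fit of the radius function at maximum degree ``L``.

    Solved by SVD-based least squares (``numpy.linalg.lstsq``), so the result
    is independent of sample ordering to ~1e-10.  Requires at least
    2*(L+1)^2 samples; a rank-deficient design raises
    :class:`ConditioningError` with the condition estimate.
    """
    n_coef = (L + 1) ** 2
    if samples.n < 2 * n_coef:
        raise InvalidInputError(
            f"need >= {2 * n_coef} samples for L={L}, got {samples.n}"
        )
    B = real_sph_harm_basis(L, samples.thetas, samples.phis)
    coeffs, _, rank, sv = np.linalg.lstsq(B, samples.radii_mm, rcond=None)
    if rank < n_coef:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        raise ConditioningError(
            f"design matrix rank {rank} < {n_coef}; condition estimate {cond:.3g} — "
            "sample directions are too poorly distributed for this degree"
        )
    resid = samples.radii_mm - B @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return SPHARMModel(L, coeffs, samples.origin_mm.copy(), rms)


def select_order_mdl(
    samples: SphericalSamples, L_max: int
) -> tuple[int, np.ndarray]:
    """Model-order selection by minimum description length.

    Computes MDL(L) = (N/2) ln(RSS_L/N) + ((L+1)^2/2) ln N for every
    L = 0..L_max and returns (argmin L, full MDL curve); ties resolve to the
    smaller L.  An (numerically) exact fit at some L short-circuits: the
    smallest exactly fitting L is selected and the MDL value is -inf there.
    """
    if L_max < 0:
        raise InvalidInputError("L_max must be >= 0")
    n = samples.n
    scale = float(np.mean(np.abs(samples.radii_mm)))
    exact_rss = n * (1e-8 * max(scale, 1e-30)) ** 2
    mdl = np.full(L_max + 1, np.nan)
    for L in range(L_max + 1):
        model = fit_spharm(samples, L)
        rss = model.rms_residual_mm**2 * n
        if rss <= exact_rss:
            mdl[L] = -np.inf
            # exact fit: larger orders cannot describe the data more cheaply
            for L2 in range(L + 1, L_max + 1):
                mdl[L2] = -np.inf
            return L, mdl
        mdl[L] = 0.5 * n * np.log(rss / n) + 0.5 * (L + 1) ** 2 * np.log(n)
    return int(np.argmin(mdl)), mdl


def reconstruct_radii(model: SPHARMModel, thetas: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Evaluate the fitted radius function; raise on non-positive radii."""
    B = real_sph_harm_basis(model.L, np.asarray(thetas), np.asarray(phis))
    radii = B @ model.coeffs
    if np.any(radii <= 0):
        bad = np.flatnonzero(radii <= 0)
        pts = ", ".join(
            f"(theta={np.asarray(thetas).ravel()[i]:.3f}, phi={np.asarray(phis).ravel()[i]:.3f})"
            for i in bad[:5]
        )
        raise InvalidShapeError(
            f"reconstructed radius non-positive at {bad.size} directions, e.g. {pts}"
        )
    return radii


def reconstruct_mesh(model: SPHARMModel, subdiv_level: int = 3) -> TriMesh:
    """Evaluate the model on an icosphere and return the closed surface."""
    sphere = icosphere(subdiv_level)
    thetas, phis = directions_to_angles(sphere.vertices)
    radii = reconstruct_radii(model, thetas, phis)
    verts = sphere.vertices * radii[:, None] + model.origin_mm
    return TriMesh(verts, sphere.faces)
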
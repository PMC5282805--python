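import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tarsalssm import (
    SphericalSamples,
    fit_spharm,
    icosphere,
    parameterize,
    real_sph_harm_basis,
    reconstruct_mesh,
    reconstruct_radii,
    select_order_mdl,
)
from tarsalssm.errors import (
    ConditioningError,
    InvalidInputError,
    InvalidShapeError,
    NotStarShapedError,
)
from tarsalssm.mesh import TriMesh
from tarsalssm.spharm import SPHARMModel, directions_to_angles, index_from_lm, lm_from_index

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)


def gauss_legendre_grid(n_theta, n_phi):
    """Sphere quadrature exact for band-limited products: Gauss-Legendre in
    cos(theta), trapezoid in phi."""
    x, w = np.polynomial.legendre.leggauss(n_theta)
    thetas = np.arccos(x)
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    T, P = np.meshgrid(thetas, phis, indexing="ij")
    W = np.broadcast_to(w[:, None] * (2 * np.pi / n_phi), T.shape)
    return T.ravel(), P.ravel(), W.ravel()


def test_index_roundtrip():
    k = 0
    for l in range(7):
        for m in range(-l, l + 1):
            assert index_from_lm(l, m) == k
            assert lm_from_index(k) == (l, m)
            k += 1
    with pytest.raises(InvalidInputError):
        index_from_lm(2, 3)


def test_basis_orthonormal_gauss_legendre():
    """Gram matrix under exact quadrature equals identity to 1e-10."""
    L = 6
    th, ph, w = gauss_legendre_grid(2 * L + 2, 4 * L + 1)
    B = real_sph_harm_basis(L, th, ph)
    gram = (B * w[:, None]).T @ B
    np.testing.assert_allclose(gram, np.eye((L + 1) ** 2), atol=1e-10)


def test_basis_near_orthonormal_uniform_sampling():
    """Unweighted Gram on a 10^4-point uniform (Fibonacci) sphere sampling
    stays within 2e-2 per entry of the identity."""
    i = np.arange(10_000)
    z = 1 - 2 * (i + 0.5) / 10_000
    rho = np.sqrt(1 - z**2)
    ang = np.pi * (3 - np.sqrt(5)) * i
    v = np.stack([rho * np.cos(ang), rho * np.sin(ang), z], axis=1)
    th, ph = directions_to_angles(v)
    B = real_sph_harm_basis(6, th, ph)
    gram = B.T @ B * (4 * np.pi / len(v))
    np.testing.assert_allclose(gram, np.eye(49), atol=2e-2)


def test_unit_sphere_identity(sphere_angles):
    """r = 1 everywhere has the single coefficient c0 = 2*sqrt(pi)."""
    th, ph = sphere_angles
    model = fit_spharm(SphericalSamples(th, ph, np.ones_like(th), np.zeros(3)), 6)
    assert model.coeffs[0] == pytest.approx(TWO_SQRT_PI, abs=1e-9)
    assert np.abs(model.coeffs[1:]).max() < 1e-9
    assert model.rms_residual_mm < 1e-12


def test_y20_field_recovery(sphere_angles):
    """r = 1 + 0.3*Y20 on 642 directions, fit at L = 2: the (2,0)
    coefficient is 0.3 and c0 = 2*sqrt(pi), verified against numerical
    quadrature of the projection integrals on a fine grid."""
    th, ph = sphere_angles
    y20 = real_sph_harm_basis(2, th, ph)[:, index_from_lm(2, 0)]
    samples = SphericalSamples(th, ph, 1.0 + 0.3 * y20, np.zeros(3))
    model = fit_spharm(samples, 2)
    assert model.coeffs[index_from_lm(2, 0)] == pytest.approx(0.3, abs=1e-6)
    assert model.coeffs[0] == pytest.approx(TWO_SQRT_PI, abs=1e-6)
    # quadrature oracle: c_k = integral r * Y_k dOmega
    tq, pq, wq = gauss_legendre_grid(20, 41)
    Bq = real_sph_harm_basis(2, tq, pq)
    r = 1.0 + 0.3 * Bq[:, index_from_lm(2, 0)]
    c_oracle = (Bq * wq[:, None]).T @ r
    np.testing.assert_allclose(model.coeffs, c_oracle, atol=1e-9)


def test_degree_zero_closed_form(sphere_angles):
    """L = 0 least squares has the closed form c0 = mean(r) * 2*sqrt(pi)."""
    th, ph = sphere_angles
    rng = np.random.default_rng(3)
    r = rng.uniform(4, 6, th.size)
    model = fit_spharm(SphericalSamples(th, ph, r, np.zeros(3)), 0)
    assert model.coeffs[0] == pytest.approx(r.mean() * TWO_SQRT_PI, rel=1e-12)


def test_fit_sample_count_precondition(sphere_angles):
    th, ph = sphere_angles
    few = SphericalSamples(th[:49], ph[:49], np.ones(49), np.zeros(3))
    with pytest.raises(InvalidInputError, match="samples"):
        fit_spharm(few, 4)


def test_fit_rank_deficient_ring():
    """Samples on a single ring of constant theta cannot separate the
    degrees; the fit reports a conditioning error."""
    n = 300
    ph = 2 * np.pi * np.arange(n) / n
    th = np.full(n, np.pi / 2)
    ring = SphericalSamples(th, ph, np.ones(n), np.zeros(3))
    with pytest.raises(ConditioningError):
        fit_spharm(ring, 3)


# -- parameterization --------------------------------------------------


def test_parameterize_sphere_and_axis_points(sphere_642):
    samples = parameterize(icosphere(3, radius=5.0))
    np.testing.assert_allclose(samples.radii_mm, 5.0, rtol=1e-12)
    # axis points: theta = 0 at +z pole, theta = pi/2 & phi = 0 at +x
    v = np.array([[0, 0, 3.0], [2.0, 0, 0], [0, 1.5, 0]])
    th, ph = directions_to_angles(v / np.linalg.norm(v, axis=1)[:, None])
    assert th[0] == pytest.approx(0.0)
    assert (th[1], ph[1]) == (pytest.approx(np.pi / 2), pytest.approx(0.0))
    assert ph[2] == pytest.approx(np.pi / 2)


def test_parameterize_roundtrip(cuboid_sample):
    """(theta, phi, r) triples invert back to the original vertices."""
    samples = parameterize(cuboid_sample.mesh)
    st, ct = np.sin(samples.thetas), np.cos(samples.thetas)
    back = samples.origin_mm + samples.radii_mm[:, None] * np.stack(
        [st * np.cos(samples.phis), st * np.sin(samples.phis), ct], axis=1
    )
    np.testing.assert_allclose(back, cuboid_sample.mesh.vertices, atol=1e-9)


def test_parameterize_star_violation():
    """Two vertices along one direction with different radii are rejected."""
    sph = icosphere(2)
    verts = sph.vertices.copy()
    # move vertex 5 onto vertex 0's direction at a different radius
    verts[5] = 1.1 * verts[0]
    with pytest.raises(NotStarShapedError):
        parameterize(TriMesh(verts, sph.faces))


# -- model order selection --------------------------------------------


def test_mdl_exact_fit_shortcircuit(sphere_angles):
    """A noiseless sphere fits exactly at L = 0, which short-circuits."""
    th, ph = sphere_angles
    samples = SphericalSamples(th, ph, np.full(th.size, 5.0), np.zeros(3))
    L_opt, curve = select_order_mdl(samples, 6)
    assert L_opt == 0
    assert curve.shape == (7,)
    assert np.isneginf(curve[0])


def test_mdl_curve_bookkeeping(sphere_angles):
    th, ph = sphere_angles
    rng = np.random.default_rng(8)
    r = 5.0 + 0.05 * rng.standard_normal(th.size)
    L_opt, curve = select_order_mdl(SphericalSamples(th, ph, r, np.zeros(3)), 5)
    assert curve.shape == (6,)
    assert np.all(np.isfinite(curve))
    assert L_opt == int(np.argmin(curve))


# -- reconstruction ----------------------------------------------------


def test_reconstruct_pure_sphere():
    model = SPHARMModel(2, np.array([TWO_SQRT_PI] + [0.0] * 8), np.zeros(3))
    th = np.array([0.1, 1.0, 2.0])
    ph = np.array([0.0, 3.0, 5.0])
    np.testing.assert_allclose(reconstruct_radii(model, th, ph), 1.0)


def test_fit_then_reconstruct_consistency(cuboid_sample):
    """Reconstruction on the fitting directions reproduces the fitted values
    and the recorded RMS residual (design-matrix product oracle)."""
    samples = parameterize(cuboid_sample.mesh)
    model = fit_spharm(samples, 4)
    radii = reconstruct_radii(model, samples.thetas, samples.phis)
    B = real_sph_harm_basis(4, samples.thetas, samples.phis)
    np.testing.assert_allclose(radii, B @ model.coeffs, atol=1e-12)
    rms = np.sqrt(np.mean((samples.radii_mm - radii) ** 2))
    assert rms == pytest.approx(model.rms_residual_mm, abs=1e-12)


def test_reconstruct_negative_radius_guard():
    model = SPHARMModel(0, np.array([-TWO_SQRT_PI]), np.zeros(3))
    with pytest.raises(InvalidShapeError):
        reconstruct_radii(model, np.array([0.5]), np.array([0.5]))
    with pytest.raises(InvalidShapeError):
        reconstruct_mesh(model)


# -- invariants --------------------------------------------------------


def test_parseval_energy(sphere_angles):
    """For a band-limited radius field, sum(c^2) equals the quadrature
    estimate of the integral of r^2 over the sphere (rel err < 1e-6)."""
    rng = np.random.default_rng(5)
    c_true = np.zeros(16)
    c_true[0] = 20.0
    c_true[1:] = rng.uniform(-1, 1, 15)
    th, ph = sphere_angles
    r = real_sph_harm_basis(3, th, ph) @ c_true
    model = fit_spharm(SphericalSamples(th, ph, r, np.zeros(3)), 3)
    tq, pq, wq = gauss_legendre_grid(10, 21)
    rq = real_sph_harm_basis(3, tq, pq) @ c_true
    energy_quad = float(np.sum(wq * rq**2))
    assert abs(np.sum(model.coeffs**2) - energy_quad) / energy_quad < 1e-6


def test_rotation_preserves_per_degree_energy(cuboid_sample):
    """Rotating a band-limited shape changes the coefficients but not the
    per-degree energies sum_m c(l,m)^2."""
    mesh = cuboid_sample.mesh
    model0 = fit_spharm(parameterize(mesh), 4)
    R = Rotation.from_euler("zyx", [0.4, -0.9, 1.3])
    rotated = TriMesh(R.apply(mesh.vertices), mesh.faces)
    model1 = fit_spharm(parameterize(rotated), 4)
    assert not np.allclose(model0.coeffs, model1.coeffs)
    for l in range(5):
        k0, k1 = l * l, (l + 1) ** 2
        e0 = np.sum(model0.coeffs[k0:k1] ** 2)
        e1 = np.sum(model1.coeffs[k0:k1] ** 2)
        assert abs(e1 - e0) / max(e0, 1e-12) < 1e-6


def test_fit_order_independence(sphere_angles):
    """The least-squares solution does not depend on sample ordering."""
    th, ph = sphere_angles
    rng = np.random.default_rng(11)
    r = 5 + 0.3 * rng.standard_normal(th.size)
    m0 = fit_spharm(SphericalSamples(th, ph, r, np.zeros(3)), 3)
    perm = rng.permutation(th.size)
    m1 = fit_spharm(SphericalSamples(th[perm], ph[perm], r[perm], np.zeros(3)), 3)
    np.testing.assert_allclose(m0.coeffs, m1.coeffs, atol=1e-10)
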
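import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tarsalssm import (
    enhance_contrast,
    grow_region,
    segment_volume,
    stack_contours,
    trace_contour,
    voxelize,
)
from tarsalssm.errors import InvalidInputError
from tarsalssm.segmentation import SliceContour
from tarsalssm.spharm import directions_to_angles, real_sph_harm_basis
from tarsalssm.synthetic import sample_population
from tarsalssm.volume import VoxelVolume


def brute_force_flood(img, seed, tol):
    """Independent oracle: breadth-first 4-connected flood fill against the
    seed-value band."""
    img = np.asarray(img, dtype=float)
    target = img[seed]
    mask = np.zeros(img.shape, dtype=bool)
    stack = [seed]
    mask[seed] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1] and not mask[rr, cc]:
                if abs(img[rr, cc] - target) <= tol:
                    mask[rr, cc] = True
                    stack.append((rr, cc))
    return mask


def disc_image(shape, center, radius, value=100.0, bg=0.0):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    img = np.full(shape, bg)
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return img


# -- contrast enhancement ---------------------------------------------


def test_enhance_contrast_affine_and_monotone():
    img = np.linspace(10, 60, 100).reshape(10, 10)
    out = enhance_contrast(img, 0, 100)
    np.testing.assert_allclose(out, (img - 10) / 50, atol=1e-12)
    flat = out.ravel()
    assert np.all(np.diff(flat) >= 0)  # rank order preserved


def test_enhance_contrast_two_level_exact():
    img = np.array([[0.0, 100.0], [100.0, 0.0]])
    out = enhance_contrast(img, 0, 100)
    assert set(np.unique(out)) == {0.0, 1.0}


def test_enhance_contrast_constant_slice_warns_zeros():
    with pytest.warns(UserWarning):
        out = enhance_contrast(np.full((5, 5), 3.0))
    np.testing.assert_array_equal(out, 0.0)


def test_enhance_contrast_bad_percentiles():
    with pytest.raises(InvalidInputError):
        enhance_contrast(np.zeros((3, 3)), 50, 40)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_enhance_contrast_output_range_and_order(seed):
    """Output is always in [0, 1] and never inverts the input order."""
    rng = np.random.default_rng(seed)
    img = rng.normal(size=(12, 12)) * rng.uniform(0.1, 50)
    out = enhance_contrast(img, 1, 99)
    assert out.min() >= 0 and out.max() <= 1
    order = np.argsort(img.ravel())
    assert np.all(np.diff(out.ravel()[order]) >= 0)


# -- region growing ----------------------------------------------------


def test_grow_region_uniform_slice():
    mask = grow_region(np.full((8, 9), 2.5), (3, 3), 0.0)
    assert mask.all()


def test_grow_region_disc_exact():
    img = disc_image((40, 40), (20, 20), 10)
    mask = grow_region(img, (20, 20), 50.0)
    np.testing.assert_array_equal(mask, img == 100.0)


def test_grow_region_background_seed_excludes_disc():
    img = disc_image((40, 40), (20, 20), 10)
    mask = grow_region(img, (1, 1), 50.0)
    assert not mask[img == 100.0].any()
    np.testing.assert_array_equal(mask, img == 0.0)


def test_grow_region_seed_bounds():
    with pytest.raises(InvalidInputError):
        grow_region(np.zeros((5, 5)), (5, 0), 1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_grow_region_matches_brute_force_oracle(seed):
    """Exact mask equality with an independently coded flood fill on random
    piecewise-constant-plus-noise slices."""
    rng = np.random.default_rng(seed)
    img = rng.normal(50, 5, size=(24, 24))
    img[4:12, 6:18] += rng.uniform(50, 150)
    seed_px = (int(rng.integers(24)), int(rng.integers(24)))
    tol = float(rng.uniform(0, 40))
    np.testing.assert_array_equal(
        grow_region(img, seed_px, tol), brute_force_flood(img, seed_px, tol)
    )


# -- contour tracing ---------------------------------------------------


def test_trace_contour_full_frame():
    """An all-foreground mask traces the image border in order."""
    contour = trace_contour(np.ones((5, 7), dtype=bool), 0)
    pts = {tuple(p) for p in contour.points_px}
    border = {
        (r, c)
        for r in range(5)
        for c in range(7)
        if r in (0, 4) or c in (0, 6)
    }
    assert pts == border
    # ordered: successive pixels 8-adjacent
    d = np.abs(np.diff(contour.points_px, axis=0)).max(axis=1)
    assert (d == 1).all()


def test_trace_contour_single_pixel():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 3] = True
    contour = trace_contour(mask, 4)
    np.testing.assert_array_equal(contour.points_px, [[2, 3]])
    assert contour.slice_index == 4


def test_trace_contour_disc_perimeter():
    """Digital perimeter of a radius-10 disc within 15% of 2*pi*10."""
    img = disc_image((30, 30), (15, 15), 10)
    contour = trace_contour(img == 100.0, 0)
    assert abs(len(contour.points_px) - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.15
    # every contour pixel is foreground and 8-adjacent to background/border
    mask = img == 100.0
    pad = np.pad(mask, 1)
    for r, c in contour.points_px:
        assert mask[r, c]
        nb = pad[r : r + 3, c : c + 3]
        assert not nb.all()


def test_trace_contour_errors():
    with pytest.raises(InvalidInputError, match="empty"):
        trace_contour(np.zeros((4, 4), dtype=bool), 0)
    two = np.zeros((5, 5), dtype=bool)
    two[0, 0] = two[4, 4] = True
    with pytest.raises(InvalidInputError, match="2"):
        trace_contour(two, 0)


def test_trace_contour_padding_invariance():
    """Padding the mask with background shifts the contour by the pad only."""
    img = disc_image((20, 20), (9, 10), 6)
    mask = img == 100.0
    c0 = trace_contour(mask, 0)
    c1 = trace_contour(np.pad(mask, 3), 0)
    np.testing.assert_array_equal(c1.points_px - 3, c0.points_px)


# -- stacking ----------------------------------------------------------


def test_stack_contours_identity_spacing():
    vol = VoxelVolume(np.zeros((4, 5, 6)), np.ones(3))
    contour = SliceContour(2, np.array([[0, 0], [1, 0], [1, 1]]), (0, 0))
    cloud = stack_contours([contour], vol)
    np.testing.assert_array_equal(
        cloud.points_mm, [[2, 0, 0], [2, 1, 0], [2, 1, 1]]
    )


def test_stack_contours_anisotropic_spacing():
    vol = VoxelVolume(np.zeros((4, 5, 6)), [0.5, 0.5, 2.0], origin_mm=[1.0, -1.0, 0.0])
    contour = SliceContour(3, np.array([[2, 4], [3, 4]]), (2, 4))
    cloud = stack_contours([contour], vol)
    # oracle: manual affine map of each (slice, row, col) index triple
    expect = np.array([[1 + 3 * 0.5, -1 + 2 * 0.5, 0 + 4 * 2.0],
                       [1 + 3 * 0.5, -1 + 3 * 0.5, 0 + 4 * 2.0]])
    np.testing.assert_allclose(cloud.points_mm, expect)


def test_stack_contours_empty_and_bounds():
    vol = VoxelVolume(np.zeros((4, 5, 6)), np.ones(3))
    assert len(stack_contours([], vol)) == 0
    bad = SliceContour(9, np.array([[0, 0]]), (0, 0))
    with pytest.raises(InvalidInputError):
        stack_contours([bad], vol)


# -- synthetic-volume chain -------------------------------------------


def test_segmented_cloud_near_true_surface(class_specs):
    """Segmenting a low-noise voxelized bone gives a cloud with >= 95% of
    points within 1.5 * spacing of the generating surface."""
    s = sample_population(class_specs[1], 1, seed=7)[0]
    spacing = 1.0
    vol = voxelize(s.mesh, spacing, noise_sd=10.0, seed=11)
    truth = vol.values > 600
    seeds = {}
    for i in range(vol.shape[0]):
        ys, zs = np.nonzero(truth[i])
        if len(ys) > 30:
            j = np.argmin((ys - ys.mean()) ** 2 + (zs - zs.mean()) ** 2)
            seeds[i] = (int(ys[j]), int(zs[j]))
    cloud, contours = segment_volume(vol, seeds, tolerance=0.3)
    assert len(contours) >= 10
    d = cloud.points_mm
    r = np.linalg.norm(d, axis=1)
    th, ph = directions_to_angles(d / r[:, None])
    r_true = real_sph_harm_basis(4, th, ph) @ s.coeffs_true
    assert np.mean(np.abs(r - r_true) <= 1.5 * spacing) >= 0.95
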
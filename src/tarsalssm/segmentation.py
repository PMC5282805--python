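"""Slice-wise bone segmentation: contrast enhancement, seeded region growing,
contour tracing, and assembly of a 3D point cloud in physical coordinates.

A volume is decomposed into sagittal slices (a fixed grid axis chosen in
configuration).  Per slice, intensities are rescaled by percentile-clipped
linear stretch, a 4-connected region is grown from a seed pixel under a fixed
intensity band around the seed value (traversal-order independent by
construction), and the outer boundary of the region is traced as an ordered
closed pixel loop.  Contour pixels from all slices map to millimetres through
the voxel spacing and origin.

Seed points are inputs throughout: supplied by an operator in real mode,
taken from ground truth in synthetic mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import flood

from .errors import InvalidInputError
from .volume import VoxelVolume

__all__ = [
    "SliceContour",
    "PointCloud3D",
    "enhance_contrast",
    "grow_region",
    "trace_contour",
    "stack_contours",
    "segment_volume",
]


@dataclass
class SliceContour:
    """Ordered closed boundary loop of one segmented slice region."""

    slice_index: int
    points_px: np.ndarray  # (n, 2) integer pixel coordinates (row, col)
    seed_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.points_px = np.asarray(self.points_px, dtype=np.int64)
        if self.points_px.ndim != 2 or self.points_px.shape[1] != 2:
            raise InvalidInputError("points_px must be an (n, 2) array")
        if len(self.points_px) > 1:
            gap = np.abs(self.points_px[0] - self.points_px[-1]).max()
            if gap > 1:
                raise InvalidInputError("contour loop is not closed under 8-connectivity")


@dataclass
class PointCloud3D:
    """Unordered 3D points in millimetres."""

    points_mm: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points_mm)):
            raise InvalidInputError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points_mm)


def enhance_contrast(
    slice_img: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Percentile-clipped linear rescale of a 2D slice to [0, 1].

    The mapping is monotone non-decreasing; values at or below the
    ``low_pct`` percentile map to 0, at or above ``high_pct`` to 1.  A
    constant slice yields all zeros with a warning.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise InvalidInputError("need 0 <= low_pct < high_pct <= 100")
    img = np.asarray(slice_img, dtype=float)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant (or near-constant) slice: contrast output is all zeros")
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def grow_region(
    slice_img: np.ndarray, seed_px: tuple[int, int], tolerance: float
) -> np.ndarray:
    """Seeded region growing: the maximal 4-connected component containing
    the seed whose member values v satisfy |v - v_seed| <= tolerance.

    The criterion is fixed by the seed value, so the result does not depend
    on traversal order.
    """
    img = np.asarray(slice_img, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("slice must be 2D")
    r, c = int(seed_px[0]), int(seed_px[1])
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise InvalidInputError(f"seed {seed_px} outside slice of shape {img.shape}")
    if tolerance < 0:
        raise InvalidInputError("tolerance must be nonnegative")
    return flood(img, (r, c), connectivity=1, tolerance=tolerance)


# Moore neighbourhood in clockwise order starting from west, for a clockwise
# boundary walk in (row, col) pixel axes.
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)],
    dtype=np.int64,
)


def trace_contour(mask: np.ndarray, slice_index: int) -> SliceContour:
    """Moore-neighbour boundary tracing of a single-component mask.

    Returns the ordered outer boundary as a closed clockwise loop of
    foreground pixels, each 8-adjacent to background or the image border.
    Raises on empty masks and on masks with more than one 4-connected
    component (ambiguous region).
    """
    from scipy.ndimage import label as cc_label

    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise InvalidInputError("mask must be 2D")
    if not mask.any():
        raise InvalidInputError("empty mask: no region to trace")
    _, n_comp = cc_label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp != 1:
        raise InvalidInputError(
            f"mask has {n_comp} 4-connected components; expected exactly one"
        )
    pad = np.pad(mask, 1)
    rows, cols = np.nonzero(pad)
    start = np.array([rows.min(), cols[rows == rows.min()].min()])
    if mask.sum() == 1:
        return SliceContour(slice_index, (start - 1)[None, :], tuple(start - 1))

    # Moore tracing with Jacob's stopping criterion: stop when the start
    # pixel is re-entered from the same backtrack direction.
    loop = [start.copy()]
    # backtrack points west of start (we scanned top-to-bottom, left-to-right)
    backtrack_dir = 0  # index into _MOORE pointing at the backtrack pixel
    cur = start.copy()
    first_dir = None
    while True:
        found = False
        for step in range(1, 9):
            d = (backtrack_dir + step) % 8
            nb = cur + _MOORE[d]
            if pad[nb[0], nb[1]]:
                if first_dir is None:
                    first_dir = d
                elif np.array_equal(cur, start) and d == first_dir:
                    return SliceContour(
                        slice_index,
                        np.array(loop[:-1]) - 1,
                        tuple(start - 1),
                    )
                cur = nb
                loop.append(cur.copy())
                backtrack_dir = _backtrack_index(_MOORE[d])
                found = True
                break
        if not found:  # isolated pixel handled above; safety net
            return SliceContour(slice_index, np.array(loop) - 1, tuple(start - 1))
        if len(loop) > 4 * pad.size:
            raise RuntimeError("contour tracing failed to terminate")


def _backtrack_index(move: np.ndarray) -> int:
    """Index in the Moore ring of the pixel we came from (opposite of the
    move just taken)."""
    opp = -move
    for i, d in enumerate(_MOORE):
        if d[0] == opp[0] and d[1] == opp[1]:
            return i
    raise RuntimeError("invalid move")


def stack_contours(contours: list[SliceContour], volume: VoxelVolume) -> PointCloud3D:
    """Map contour pixels of all slices into millimetres.

    A contour pixel (row, col) of slice s becomes a 3D voxel index with s on
    the sagittal axis and (row, col) on the two remaining axes in order; the
    physical coordinate is ``origin + index * spacing``.
    """
    ax = volume.sagittal_axis
    other = [i for i in range(3) if i != ax]
    n_slices = volume.shape[ax]
    pts = []
    for c in contours:
        if not 0 <= c.slice_index < n_slices:
            raise InvalidInputError(
                f"slice index {c.slice_index} out of range [0, {n_slices})"
            )
        idx = np.zeros((len(c.points_px), 3))
        idx[:, ax] = c.slice_index
        idx[:, other[0]] = c.points_px[:, 0]
        idx[:, other[1]] = c.points_px[:, 1]
        pts.append(volume.index_to_mm(idx))
    if not pts:
        return PointCloud3D(np.empty((0, 3)))
    return PointCloud3D(np.concatenate(pts))


def segment_volume(
    volume: VoxelVolume,
    seeds: dict[int, tuple[int, int]],
    tolerance: float,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    enhance: bool = True,
) -> tuple[PointCloud3D, list[SliceContour]]:
    """Full slice-wise chain: enhance -> grow -> trace -> stack.

    ``seeds`` maps slice index -> seed pixel (row, col) on that slice;
    slices without a seed are skipped.  ``tolerance`` applies to the
    enhanced [0, 1] intensities when ``enhance`` is on, otherwise to raw
    values.
    """
    contours = []
    for s_idx in sorted(seeds):
        img = volume.slice(s_idx)
        if enhance:
            img = enhance_contrast(img, low_pct, high_pct)
        mask = grow_region(img, seeds[s_idx], tolerance)
        contours.append(trace_contour(mask, s_idx))
    return stack_contours(contours, volume), contours
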
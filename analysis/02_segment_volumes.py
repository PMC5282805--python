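"""Demonstrate the CT-like volume pathway on a handful of bones.

Voxelizes one synthetic bone per class into a noisy volume (bone ~1200,
soft tissue ~40, noise SD 30, 1 mm isotropic), segments it slice by slice
(contrast enhancement, seeded region growing, contour tracing), rebuilds the
surface by oriented normals + radial remeshing, and refits the SPHARM
coefficients.  Reports how close the recovered cloud and coefficients are to
the generating ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tarsalssm import (
    default_class_specs,
    estimate_normals,
    fit_spharm,
    parameterize,
    radial_remesh,
    sample_population,
    segment_volume,
    voxelize,
)
from tarsalssm.spharm import directions_to_angles, real_sph_harm_basis

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def slice_seeds(vol, level=600.0, min_pixels=30):
    """Ground-truth seeds: the inside pixel nearest each slice's centroid."""
    seeds = {}
    for i in range(vol.shape[0]):
        ys, zs = np.nonzero(vol.slice(i) > level)
        if len(ys) >= min_pixels:
            j = np.argmin((ys - ys.mean()) ** 2 + (zs - zs.mean()) ** 2)
            seeds[i] = (int(ys[j]), int(zs[j]))
    return seeds


def main() -> None:
    rows = []
    for ci, spec in enumerate(default_class_specs()):
        s = sample_population(spec, 1, seed=SEED + 101 * ci)[0]
        vol = voxelize(s.mesh, spacing_mm=1.0, noise_sd=30.0, seed=SEED + ci)
        cloud, contours = segment_volume(vol, slice_seeds(vol), tolerance=0.3)
        d = cloud.points_mm
        r = np.linalg.norm(d, axis=1)
        th, ph = directions_to_angles(d / r[:, None])
        r_true = real_sph_harm_basis(spec.L, th, ph) @ s.coeffs_true
        frac_close = float(np.mean(np.abs(r - r_true) <= 1.5))
        mesh = radial_remesh(estimate_normals(cloud), subdiv_level=3)
        model = fit_spharm(parameterize(mesh), spec.L)
        err = np.abs(model.coeffs - s.coeffs_true)
        rows.append({
            "class": spec.name,
            "n_slices": len(contours),
            "n_cloud_points": len(cloud),
            "frac_within_1.5mm": frac_close,
            "c0_error_mm": err[0],
            "max_shape_coeff_error_mm": err[1:].max(),
        })
        print(f"{spec.name:>10s}: {len(cloud):5d} cloud points over "
              f"{len(contours)} slices; {frac_close:.1%} within 1.5 mm of the true "
              f"surface; c0 error {err[0]:.2f} mm (half-voxel inward contour bias), "
              f"shape-coefficient error <= {err[1:].max():.2f} mm")
    out = ROOT / "results" / "segmentation_recovery.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
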
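import numpy as np
import pytest

from tarsalssm import (
    FeatureMatrix,
    default_class_specs,
    detect_landmarks,
    fit_spharm,
    icosphere,
    landmark_rules_for,
    normalize_pose,
    parameterize,
    sample_population,
)
from tarsalssm.spharm import directions_to_angles


@pytest.fixture(scope="session")
def sphere_642():
    return icosphere(3)


@pytest.fixture(scope="session")
def sphere_angles(sphere_642):
    return directions_to_angles(sphere_642.vertices)


@pytest.fixture(scope="session")
def class_specs():
    return default_class_specs()


@pytest.fixture(scope="session")
def cuboid_sample(class_specs):
    """One deterministic cuboid-like bone with ground truth."""
    return sample_population(class_specs[1], 1, seed=3)[0]


@pytest.fixture(scope="session")
def default_population(class_specs):
    """The study-design analog: 4 classes x 15 subjects x 2 sides = 120
    samples, pose-normalized and fitted at L = 6 — shared by the statistics
    and classification tests."""
    feats, labels, sides = [], [], []
    mean_coeffs: dict[tuple[str, str], list] = {}
    for ci, spec in enumerate(class_specs):
        for s in sample_population(spec, 15, seed=1 + 101 * ci):
            lm = detect_landmarks(s.mesh, s.class_name, landmark_rules_for(spec, s.side))
            normed, _, _ = normalize_pose(s.mesh, lm)
            model = fit_spharm(parameterize(normed), 6)
            feats.append(model.coeffs)
            labels.append(s.class_name)
            sides.append(s.side)
            mean_coeffs.setdefault((s.class_name, s.side), []).append(model.coeffs)
    fm = FeatureMatrix(np.array(feats), np.array(labels), np.array(sides))
    means = {k: np.mean(v, axis=0) for k, v in mean_coeffs.items()}
    return fm, means
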
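import numpy as np
import pandas as pd
import pytest

from tarsalssm import (
    coefficient_stats,
    laterality_correlation,
    make_coefficient_table,
    mean_shape,
    reconstruct_radii,
    two_way_anova,
)
from tarsalssm.errors import InvalidInputError, UnbalancedDesignError
from tarsalssm.spharm import SPHARMModel

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)


def table_from_values(values_by_cell, reps_key="subject_id"):
    rows = []
    for (bone, k), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append({"subject_id": i, "bone": bone, "side": "right", "k": k, "value": v})
    return make_coefficient_table(rows)


# -- descriptive statistics -------------------------------------------


def test_quartiles_hand_case():
    t = table_from_values({("b", 0): [1, 2, 3, 4, 5]})
    st = coefficient_stats(t)
    row = st.loc[0]
    assert (row.q1, row["median"], row.q3, row["mean"]) == (2, 3, 4, 3)
    assert row.n_outliers == 0


def test_quartiles_degenerate_spread():
    t = table_from_values({("b", 1): [7.0] * 6})
    row = coefficient_stats(t).loc[1]
    assert row.q1 == row["median"] == row.q3 == row["mean"] == 7.0
    assert row.n_outliers == 0


def test_outlier_fraction_normal_draws():
    """Tukey fences flag ~0.7% of standard-normal draws; the observed
    fraction over 500 draws must fall in [0.002, 0.02]."""
    rng = np.random.default_rng(42)
    t = table_from_values({("b", 0): rng.standard_normal(500)})
    row = coefficient_stats(t).loc[0]
    assert 0.002 <= row.n_outliers / 500 <= 0.02
    # flagged values really lie beyond the fences
    iqr = row.q3 - row.q1
    for v in row.outliers:
        assert v < row.q1 - 1.5 * iqr or v > row.q3 + 1.5 * iqr


def test_empty_group_error():
    t = table_from_values({("b", 0): [1, 2]})
    with pytest.raises(InvalidInputError):
        coefficient_stats(t, bone="missing")


def test_duplicate_keys_rejected():
    rows = [
        {"subject_id": 0, "bone": "b", "side": "right", "k": 0, "value": 1.0},
        {"subject_id": 0, "bone": "b", "side": "right", "k": 0, "value": 2.0},
    ]
    with pytest.raises(InvalidInputError):
        make_coefficient_table(rows)


# -- mean shape --------------------------------------------------------


def sphere_model(radius):
    c = np.zeros(9)
    c[0] = radius * TWO_SQRT_PI
    return SPHARMModel(2, c, np.zeros(3))


def test_mean_shape_idempotent_and_single():
    m = sphere_model(4.0)
    np.testing.assert_array_equal(mean_shape([m, m]).coeffs, m.coeffs)
    np.testing.assert_array_equal(mean_shape([m]).coeffs, m.coeffs)


def test_mean_shape_two_spheres():
    """Means of radius-4 and radius-6 spheres reconstruct radius 5."""
    m = mean_shape([sphere_model(4.0), sphere_model(6.0)])
    th = np.linspace(0.1, 3.0, 7)
    np.testing.assert_allclose(reconstruct_radii(m, th, th), 5.0, atol=1e-12)


def test_mean_shape_commutes_with_reconstruction():
    rng = np.random.default_rng(1)
    models = []
    for _ in range(5):
        c = np.zeros(16)
        c[0] = 30.0
        c[1:] = rng.uniform(-1, 1, 15)
        models.append(SPHARMModel(3, c, np.zeros(3)))
    th = np.linspace(0.05, np.pi - 0.05, 20)
    ph = np.linspace(0, 6.0, 20)
    mean_recon = reconstruct_radii(mean_shape(models), th, ph)
    recon_mean = np.mean([reconstruct_radii(m, th, ph) for m in models], axis=0)
    np.testing.assert_allclose(mean_recon, recon_mean, atol=1e-10)


def test_mean_shape_mismatched_L():
    with pytest.raises(InvalidInputError):
        mean_shape([sphere_model(4.0), SPHARMModel(1, np.ones(4), np.zeros(3))])


# -- laterality correlation -------------------------------------------


def test_laterality_perfect_linearity():
    x = np.array([1.0, 2.0, 5.0, -3.0])
    lat = laterality_correlation(x, 2 * x)
    assert lat.r_squared == pytest.approx(1.0)


def test_laterality_hand_pearson():
    """x = (1,2,3), y = (1,2,4): r^2 = 27/28 by the direct formula."""
    lat = laterality_correlation(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
    assert lat.r_squared == pytest.approx(27 / 28, abs=1e-12)


def test_laterality_reduced_drops_largest():
    x = np.array([100.0, 1.0, 2.0, 3.0])
    y = np.array([100.0, 1.1, 1.9, 3.2])
    lat = laterality_correlation(x, y)
    assert lat.omitted_index == 0
    assert lat.r_squared_reduced < lat.r_squared


def test_laterality_affine_invariance():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=(2, 20))
    a = laterality_correlation(x, y)
    b = laterality_correlation(3.5 * x + 0.0, 3.5 * y + 0.0)
    assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)


def test_laterality_zero_variance_error():
    with pytest.raises(InvalidInputError):
        laterality_correlation(np.ones(5), np.arange(5.0))


# -- two-way ANOVA -----------------------------------------------------


def test_anova_null_data():
    t = table_from_values({("a", 0): [3, 3], ("a", 1): [3, 3],
                           ("b", 0): [3, 3], ("b", 1): [3, 3]})
    eff = two_way_anova(t)
    for name in ("bone", "k", "interaction"):
        assert eff[name].ss == 0.0 and eff[name].F == 0.0


def brute_force_anova(y):
    """Independent sums-of-squares oracle on an (a, b, r) array."""
    a, b, r = y.shape
    grand = y.mean()
    am = y.mean(axis=(1, 2))
    bm = y.mean(axis=(0, 2))
    cm = y.mean(axis=2)
    ss_a = r * b * ((am - grand) ** 2).sum()
    ss_b = r * a * ((bm - grand) ** 2).sum()
    ss_ab = r * ((cm - am[:, None] - bm[None, :] + grand) ** 2).sum()
    ss_e = ((y - cm[:, :, None]) ** 2).sum()
    ms_e = ss_e / (a * b * (r - 1))
    return (
        (ss_a, ss_b, ss_ab, ss_e),
        (ss_a / (a - 1) / ms_e, ss_b / (b - 1) / ms_e, ss_ab / ((a - 1) * (b - 1)) / ms_e),
    )


def test_anova_matches_brute_force_oracle():
    """Hand-crafted 2x2 design with 2 replicates: F statistics agree with an
    independent sums-of-squares computation to 1e-10."""
    y = np.array([[[3.0, 4.0], [7.0, 6.5]], [[1.0, 0.5], [9.0, 9.5]]])
    t = table_from_values({
        ("a", 0): y[0, 0], ("a", 1): y[0, 1],
        ("b", 0): y[1, 0], ("b", 1): y[1, 1],
    })
    eff = two_way_anova(t)
    (ss_a, ss_b, ss_ab, ss_e), (fa, fb, fab) = brute_force_anova(y)
    assert eff["bone"].F == pytest.approx(fa, abs=1e-10)
    assert eff["k"].F == pytest.approx(fb, abs=1e-10)
    assert eff["interaction"].F == pytest.approx(fab, abs=1e-10)
    assert eff["residual"].ss == pytest.approx(ss_e, abs=1e-10)


def test_anova_matches_statsmodels():
    """Independent route: OLS + anova_lm reproduces F and p."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(0)
    rows = []
    for bone in ("u", "v", "w"):
        for k in range(4):
            for s in range(5):
                rows.append({"subject_id": s, "bone": bone, "side": "right",
                             "k": k, "value": rng.normal() + (2.0 if bone == "u" else 0.0)})
    t = make_coefficient_table(rows)
    eff = two_way_anova(t)
    df = t.copy()
    df["k"] = df["k"].astype(str)
    fit = ols("value ~ C(bone) * C(k)", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    assert eff["bone"].F == pytest.approx(aov.loc["C(bone)", "F"], rel=1e-8)
    assert eff["k"].F == pytest.approx(aov.loc["C(k)", "F"], rel=1e-8)
    assert eff["interaction"].F == pytest.approx(aov.loc["C(bone):C(k)", "F"], rel=1e-8)
    assert eff["bone"].p == pytest.approx(aov.loc["C(bone)", "PR(>F)"], abs=1e-10)


def test_anova_total_ss_conservation():
    rng = np.random.default_rng(2)
    rows = []
    for bone in ("u", "v"):
        for k in range(3):
            for s in range(4):
                rows.append({"subject_id": s, "bone": bone, "side": "right",
                             "k": k, "value": rng.normal()})
    t = make_coefficient_table(rows)
    eff = two_way_anova(t)
    total = np.sum((t["value"] - t["value"].mean()) ** 2)
    parts = eff["bone"].ss + eff["k"].ss + eff["interaction"].ss + eff["residual"].ss
    assert parts == pytest.approx(total, rel=1e-9)


def test_anova_unbalanced_rejected():
    rows = [
        {"subject_id": i, "bone": b, "side": "right", "k": k, "value": float(i)}
        for b, k, n in (("u", 0, 3), ("u", 1, 3), ("v", 0, 3), ("v", 1, 2))
        for i in range(n)
    ]
    with pytest.raises(UnbalancedDesignError):
        two_way_anova(make_coefficient_table(rows))


def test_anova_exclude_level():
    rng = np.random.default_rng(3)
    rows = []
    for bone in ("u", "v"):
        for k in range(3):
            for s in range(3):
                rows.append({"subject_id": s, "bone": bone, "side": "right",
                             "k": k, "value": rng.normal() + (50.0 if k == 0 else 0)})
    t = make_coefficient_table(rows)
    full = two_way_anova(t)
    red = two_way_anova(t, exclude_b_level=0)
    assert red["k"].df == full["k"].df - 1
    assert red["k"].F < full["k"].F
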
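"""Statistical shape model summaries over SPHARM coefficient tables.

Works on long-format coefficient tables (one row per subject x bone x side x
coefficient index): per-coefficient descriptive statistics with Tukey-fence
outliers, mean-shape models, squared Pearson correlation between left and
right mean coefficient vectors (with a reduced variant omitting the dominant
size coefficient), and classical balanced two-way fixed-effects ANOVA over
bones x coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, UnbalancedDesignError
from .spharm import SPHARMModel

__all__ = [
    "make_coefficient_table",
    "coefficient_stats",
    "mean_shape",
    "LateralityCorrelation",
    "laterality_correlation",
    "AnovaEffect",
    "two_way_anova",
]

TABLE_COLUMNS = ["subject_id", "bone", "side", "k", "value"]


def make_coefficient_table(records: list[dict]) -> pd.DataFrame:
    """Assemble and validate a long-format coefficient table."""
    table = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    if table.duplicated(["subject_id", "bone", "side", "k"]).any():
        raise InvalidInputError("duplicate (subject, bone, side, k) keys in table")
    if not np.all(np.isfinite(table["value"])):
        raise InvalidInputError("coefficient table contains non-finite values")
    return table


def coefficient_stats(table: pd.DataFrame, **filters) -> pd.DataFrame:
    """Per-coefficient quartiles, mean, and Tukey outliers for one group.

    ``filters`` restrict the table by column equality (e.g. ``bone="talus",
    side="right"``).  Quartiles use the linear-interpolation convention;
    outliers are values beyond 1.5 IQR from the quartiles, the usual box-plot
    cross convention.  Returns one row per coefficient index k with columns
    q1, median, q3, mean, n, n_outliers, outliers (list).
    """
    sub = table
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    if len(sub) == 0:
        raise InvalidInputError(f"no rows match the group filter {filters!r}")
    rows = []
    for k, grp in sub.groupby("k"):
        v = grp["value"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out = v[(v < lo) | (v > hi)]
        rows.append(
            {
                "k": int(k),
                "q1": q1,
                "median": med,
                "q3": q3,
                "mean": v.mean(),
                "n": len(v),
                "n_outliers": len(out),
                "outliers": out.tolist(),
            }
        )
    return pd.DataFrame(rows).set_index("k").sort_index()


def mean_shape(models: list[SPHARMModel]) -> SPHARMModel:
    """Element-wise mean of coefficient vectors (and origins)."""
    if not models:
        raise InvalidInputError("mean_shape needs at least one model")
    L = models[0].L
    if any(m.L != L for m in models):
        raise InvalidInputError("all models must share the same degree L")
    coeffs = np.mean([m.coeffs for m in models], axis=0)
    origin = np.mean([m.origin_mm for m in models], axis=0)
    rms = float(np.mean([m.rms_residual_mm for m in models]))
    return SPHARMModel(L, coeffs, origin, rms)


@dataclass
class LateralityCorrelation:
    """Left-vs-right agreement of mean coefficient vectors."""

    r_squared: float
    p_value: float
    r_squared_reduced: float
    p_value_reduced: float
    omitted_index: int  # index dropped in the reduced variant (largest |left|)


def laterality_correlation(
    left_mean: np.ndarray, right_mean: np.ndarray
) -> LateralityCorrelation:
    """Squared Pearson correlation between the two mean vectors.

    p-values come from the two-sided t transform with n - 2 degrees of
    freedom.  The reduced variant omits the single largest-|left| coefficient
    (in practice the dominant degree-0 size term, which otherwise inflates
    the correlation).
    """
    x = np.asarray(left_mean, dtype=float)
    y = np.asarray(right_mean, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidInputError("vectors must share a length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("zero variance in a coefficient vector; correlation undefined")
    r, p = sps.pearsonr(x, y)
    drop = int(np.argmax(np.abs(x)))
    keep = np.ones(x.size, dtype=bool)
    keep[drop] = False
    r2, p2 = sps.pearsonr(x[keep], y[keep])
    return LateralityCorrelation(r**2, p, r2**2, p2, drop)


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    F: float
    p: float


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "bone",
    factor_b: str = "k",
    exclude_b_level=None,
) -> dict[str, AnovaEffect]:
    """Classical balanced two-way fixed-effects ANOVA with interaction.

    Factor A defaults to bone class, factor B to coefficient index; the
    replicates in each cell are the subjects (and sides).  The layout must be
    balanced — equal replicate counts r >= 2 in every cell — which sidesteps
    the Type-I/II/III sums-of-squares ambiguity entirely.

    ``exclude_b_level`` drops one level of factor B before testing (the
    reduced variant excluding the dominant size coefficient).

    Returns effects keyed by ``factor_a``, ``factor_b``, "interaction" and
    "residual" (residual carries SS and df; its F and p are NaN).
    """
    sub = table if exclude_b_level is None else table[table[factor_b] != exclude_b_level]
    piv = sub.groupby([factor_a, factor_b])["value"]
    counts = piv.count()
    a_levels = counts.index.get_level_values(0).unique()
    b_levels = counts.index.get_level_values(1).unique()
    if len(counts) != len(a_levels) * len(b_levels) or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "two-way ANOVA requires a complete balanced layout "
            f"(cell counts: {sorted(set(counts))})"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise UnbalancedDesignError("need >= 2 replicates per cell")
    a, b = len(a_levels), len(b_levels)

    y = sub["value"].to_numpy()
    grand = y.mean()
    cell_means = piv.mean().unstack()  # a x b
    a_means = cell_means.mean(axis=1).to_numpy()
    b_means = cell_means.mean(axis=0).to_numpy()
    cm = cell_means.to_numpy()

    ss_a = r * b * np.sum((a_means - grand) ** 2)
    ss_b = r * a * np.sum((b_means - grand) ** 2)
    ss_ab = r * np.sum((cm - a_means[:, None] - b_means[None, :] + grand) ** 2)
    resid = sub["value"] - piv.transform("mean")
    ss_e = float(np.sum(resid.to_numpy() ** 2))

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    ms_e = ss_e / df_e

    def effect(name: str, ss: float, df: int) -> AnovaEffect:
        if ss <= 0 or df == 0:
            return AnovaEffect(name, max(ss, 0.0), df, 0.0, 1.0)
        if ms_e == 0:
            return AnovaEffect(name, ss, df, np.inf, 0.0)
        F = (ss / df) / ms_e
        return AnovaEffect(name, ss, df, F, float(sps.f.sf(F, df, df_e)))

    return {
        factor_a: effect(factor_a, ss_a, df_a),
        factor_b: effect(factor_b, ss_b, df_b),
        "interaction": effect("interaction", ss_ab, df_ab),
        "residual": AnovaEffect("residual", ss_e, df_e, np.nan, np.nan),
    }
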
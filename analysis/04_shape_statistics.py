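"""Descriptive statistics, laterality correlation and two-way ANOVA.

Consumes the coefficient table from script 03: per-coefficient quartiles and
Tukey outliers for the first 25 coefficients of each bone/side group,
left-vs-right correlation of mean coefficient vectors per class (full and
with the dominant size coefficient omitted), and balanced two-way ANOVA over
bones x coefficients with the subject/side replicates, full and reduced.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tarsalssm import coefficient_stats, laterality_correlation, two_way_anova

ROOT = Path(__file__).resolve().parents[1]
N_REPORT = 25


def main() -> None:
    table = pd.read_csv(ROOT / "scratch" / "coefficients_long.csv")  # run 03 first
    report = table[table["k"] < N_REPORT]

    stats_frames = []
    for (bone, side), _ in report.groupby(["bone", "side"]):
        st = coefficient_stats(report, bone=bone, side=side)
        stats_frames.append(st.drop(columns="outliers").assign(bone=bone, side=side))
    stats = pd.concat(stats_frames).reset_index()
    stats.to_csv(ROOT / "results" / "coefficient_stats.csv", index=False,
                 float_format="%.6g")

    lat_report = {}
    for bone, grp in table.groupby("bone"):
        piv = grp.pivot_table(index="k", columns="side", values="value", aggfunc="mean")
        lat = laterality_correlation(piv["left"].to_numpy(), piv["right"].to_numpy())
        lat_report[bone] = {"r_squared": lat.r_squared,
                            "r_squared_reduced": lat.r_squared_reduced,
                            "p_value": lat.p_value,
                            "omitted_index": lat.omitted_index}
        print(f"{bone:>10s}: left/right mean-coefficient r^2 = {lat.r_squared:.3f} "
              f"(reduced, dropping k={lat.omitted_index}: {lat.r_squared_reduced:.3f})")
    (ROOT / "results" / "laterality.json").write_text(
        json.dumps(lat_report, sort_keys=True, indent=1))

    dominant = int(report.groupby("k")["value"].mean().abs().idxmax())
    anova_out = {}
    for name, excl in (("full", None), ("reduced", dominant)):
        eff = two_way_anova(report, exclude_b_level=excl)
        anova_out[name] = {e.name: {"F": e.F, "df": e.df, "p": e.p}
                           for e in eff.values()}
        print(f"ANOVA ({name}): bone F = {eff['bone'].F:.1f}, "
              f"coefficient F = {eff['k'].F:.1f}, "
              f"interaction F = {eff['interaction'].F:.1f} "
              f"(all p < {max(eff['bone'].p, eff['k'].p, eff['interaction'].p, 1e-300):.1e})")
    anova_out["excluded_coefficient"] = dominant
    (ROOT / "results" / "anova.json").write_text(
        json.dumps(anova_out, sort_keys=True, indent=1))
    print("wrote results/coefficient_stats.csv, laterality.json, anova.json")


if __name__ == "__main__":
    main()
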
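"""Build the normative database and characterize its age structure.

Builds per-(age group, electrode, band) means and SDs from the healthy
cohort, serializes them (JSON + CSV mirror), then runs the age
analyses: one-way ANOVA with Bonferroni post hoc on whole-head delta
power across the five age groups, and a LOWESS age-trend curve per
band.  Writes results/norms.json, norms.csv and age_trends.csv.
"""

from pathlib import Path

import pandas as pd

import qeegnorm as q

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    powers = pd.read_csv(OUT / "hc_powers.csv")
    cohort = q.powers_from_frame(powers)
    db = q.build_norms(cohort)
    db.to_json(OUT / "norms.json")
    db.to_csv(OUT / "norms.csv")
    print(f"normative database: {len(db.cells)} cells "
          f"({len(db.scheme.labels)} age groups x 19 electrodes x 5 bands), "
          f"{len(db.degenerate_cells())} degenerate")

    # whole-head delta per subject, grouped by age group
    delta = powers[powers["band"] == "delta"].groupby(
        ["subject_id", "age"], as_index=False)["power_uv2"].mean()
    delta["group"] = [q.assign_age_group(a) for a in delta["age"]]
    groups = [delta.loc[delta["group"] == g, "power_uv2"].to_numpy()
              for g in db.scheme.labels]
    anova = q.one_way_anova(groups)
    print(f"delta across age groups: F({anova.df_between}, "
          f"{anova.df_within}) = {anova.F:.3f}, p = {anova.p:.2g}")
    for c in q.bonferroni_posthoc(groups):
        if c.significant:
            a, b = db.scheme.labels[c.i], db.scheme.labels[c.j]
            print(f"  post hoc: {a} vs {b}, adjusted p = {c.p_adjusted:.4f}")

    trend_rows = []
    for band in q.DEFAULT_BANDS.names:
        sub = powers[powers["band"] == band].groupby(
            ["subject_id", "age"], as_index=False)["power_uv2"].mean()
        curve = q.lowess_trend(sub["age"], sub["power_uv2"], fraction=0.5)
        for x, y in curve[:: max(1, len(curve) // 60)]:
            trend_rows.append({"band": band, "age": x, "smoothed_uv2": y})
        young = curve[curve[:, 0] <= 30, 1].mean()
        old = curve[curve[:, 0] >= 60, 1].mean()
        direction = "declines" if old < young else "rises"
        print(f"{band:9s}: LOWESS {direction} from {young:.2f} to "
              f"{old:.2f} µV² across 20-70")
    pd.DataFrame(trend_rows).to_csv(OUT / "age_trends.csv", index=False)
    print(f"wrote {OUT / 'norms.json'} and {OUT / 'age_trends.csv'}")


if __name__ == "__main__":
    main()
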
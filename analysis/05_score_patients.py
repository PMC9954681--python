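"""Score the patient cohort against the normative database.

Converts every patient's band powers to z and |z| against their own
age group's norms, aggregates the cohort report (17-electrode layout,
regional means, cells with mean z or mean |z| above 1 flagged), and
writes results/mdd_z_report.csv and mdd_z_regional.csv.
"""

from pathlib import Path

import pandas as pd

import qeegnorm as q
from qeegnorm.normdb import score_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    mdd = q.powers_from_frame(pd.read_csv(OUT / "mdd_powers.csv"))
    db = q.NormativeDatabase.from_json(OUT / "norms.json")
    z = score_cohort(mdd, db)
    report = q.cohort_z_summary([z.loc[sid] for sid in z.index])

    report.table.reset_index().to_csv(OUT / "mdd_z_report.csv", index=False)
    report.regional_summary.reset_index().to_csv(
        OUT / "mdd_z_regional.csv", index=False)

    flagged = report.flagged_cells()
    by_band: dict[str, list[str]] = {}
    for electrode, band in flagged:
        by_band.setdefault(band, []).append(electrode)
    print(f"scored {report.n_subjects} patients against "
          f"{db.meta.get('n_subjects')}-subject norms")
    for band, electrodes in sorted(by_band.items()):
        print(f"  {band}: mean z or |z| > 1 at {', '.join(electrodes)}")
    frontal = report.regional_summary.loc[("frontal", "high-beta")]
    print(f"frontal high-beta: mean z = {frontal['mean_z']:.2f}, "
          f"mean |z| = {frontal['mean_abs_z']:.2f}")
    print(f"wrote {OUT / 'mdd_z_report.csv'}")


if __name__ == "__main__":
    main()
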
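"""Reliability and validity of the normative database.

Four checks: Cronbach's alpha per band over the central electrodes
(C3, Cz, C4); leave-one-out cross-validation of the healthy cohort;
completely independent cross-validation (two databases from
independent half-cohorts score the patient benchmark, paired z-scores
correlated per cell); and the Gaussian coverage audit of self-scored
z values.  Writes results/cronbach_alpha.csv, loo_z.csv and
crossdb_correlations.csv.
"""

from pathlib import Path

import pandas as pd

import qeegnorm as q
from qeegnorm.normdb import score_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2025
GROUPS = ("20-30", "31-40", "41-50", "51-60", "61-70")


def main() -> None:
    hc = q.powers_from_frame(pd.read_csv(OUT / "hc_powers.csv"))
    mdd = q.powers_from_frame(pd.read_csv(OUT / "mdd_powers.csv"))
    db = q.NormativeDatabase.from_json(OUT / "norms.json")

    # internal consistency: participants x {C3, Cz, C4} per band
    alpha_rows = []
    for band in q.DEFAULT_BANDS.names:
        matrix = [[r.power[(e, band)] for e in ("C3", "Cz", "C4")]
                  for r in hc]
        alpha_rows.append({"band": band,
                           "cronbach_alpha": q.cronbach_alpha(matrix)})
    alphas = pd.DataFrame(alpha_rows)
    alphas.to_csv(OUT / "cronbach_alpha.csv", index=False)
    print("Cronbach's alpha at C3/Cz/C4 (independent cells by "
          "construction, so low alpha is expected here):")
    for row in alpha_rows:
        print(f"  {row['band']:9s}: {row['cronbach_alpha']:.3f}")

    # leave-one-out cross-validation
    loo = q.leave_one_out(hc)
    loo.to_csv(OUT / "loo_z.csv")
    flat = loo.to_numpy().ravel()
    print(f"leave-one-out z over {loo.shape[0]} subjects: "
          f"mean {flat.mean():+.4f}, SD {flat.std(ddof=1):.4f}")

    # completely independent cross-validation with half databases
    half = {g: (13, 13) for g in GROUPS}
    a, _, _ = q.generate_cohort(q.hc_spec(group_sizes=half), seed=SEED)
    b, _, _ = q.generate_cohort(q.hc_spec(group_sizes=half), seed=SEED + 1)
    report = q.cross_database_validation(mdd, q.build_norms(a),
                                         q.build_norms(b))
    report.correlations.reset_index().to_csv(
        OUT / "crossdb_correlations.csv", index=False)
    print(f"cross-database r over {len(report.correlations)} cells: "
          f"min {report.min_r:.3f}, median "
          f"{report.correlations['r'].median():.3f}, max {report.max_r:.3f}")

    # Gaussian coverage of the self-scored construction cohort
    z = score_cohort(hc, db).to_numpy().ravel()
    audit = q.coverage_audit(z, 0.0, 1.0)
    print(f"self-scored z coverage: {audit.within_1sd * 100:.2f}% within "
          f"±1 SD, {audit.within_2sd * 100:.2f}% within ±2 SD, "
          f"{audit.within_3sd * 100:.2f}% within ±3 SD")
    print(f"wrote {OUT / 'crossdb_correlations.csv'}")


if __name__ == "__main__":
    main()
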
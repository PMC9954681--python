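"""Group comparisons on demographics and questionnaires.

Compares the two simulated cohorts the way normative-database studies
report their samples: pooled t on age, Welch t on the questionnaire
totals, chi-square with adjusted-residual cell comparisons on sex and
education.  Writes results/demographics.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import qeegnorm as q
from qeegnorm.io_preprocess import EDUCATION_LEVELS

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    hc = pd.read_csv(OUT / "hc_subjects.csv")
    mdd = pd.read_csv(OUT / "mdd_subjects.csv")
    rows = []

    for column, variant in (("age", "pooled"), ("bdi_ii", "welch"),
                            ("bai", "welch")):
        res = q.t_test_from_summary(q.summarize(hc[column]),
                                    q.summarize(mdd[column]), variant)
        rows.append({"measure": column, "test": f"{variant} t",
                     "statistic": res.t, "df": res.df, "p": res.p})
        print(f"{column:7s}: HC {hc[column].mean():6.2f} "
              f"({hc[column].std(ddof=1):.2f})  MDD {mdd[column].mean():6.2f} "
              f"({mdd[column].std(ddof=1):.2f})  t({res.df:.2f}) = "
              f"{res.t:.2f}, p = {res.p:.2g}")

    sex_table = np.array([
        [(hc["sex"] == "F").sum(), (hc["sex"] == "M").sum()],
        [(mdd["sex"] == "F").sum(), (mdd["sex"] == "M").sum()]])
    res = q.chi_square(sex_table)
    rows.append({"measure": "sex", "test": "chi-square",
                 "statistic": res.chi2, "df": res.df, "p": res.p})
    print(f"sex    : chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.2g}")

    edu_table = np.array([
        [(hc["education"] == level).sum() for level in EDUCATION_LEVELS],
        [(mdd["education"] == level).sum() for level in EDUCATION_LEVELS]])
    res = q.chi_square(edu_table)
    driving = [EDUCATION_LEVELS[j] for j in range(edu_table.shape[1])
               if abs(res.adjusted_residuals[0, j]) > 1.96]
    rows.append({"measure": "education", "test": "chi-square",
                 "statistic": res.chi2, "df": res.df, "p": res.p})
    print(f"edu    : chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.2g}; "
          f"cells driving the difference: {', '.join(driving) or 'none'}")

    pd.DataFrame(rows).to_csv(OUT / "demographics.csv", index=False)
    print(f"wrote {OUT / 'demographics.csv'}")


if __name__ == "__main__":
    main()
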
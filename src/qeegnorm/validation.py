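"""Reliability and validity machinery for a normative database.

Three checks are provided: completely independent cross-validation (a
benchmark cohort is z-scored against two databases and the paired
z-scores are correlated per electrode and band), leave-one-out
cross-validation (each subject is scored against norms rebuilt without
them), and a Gaussian coverage audit (the fractions of values within
mean +/- 1, 2 and 3 SD, which a normal reference puts at 68.26%,
95.44% and 99.74%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .normdb import (
    AgeGroupScheme,
    DEFAULT_AGE_GROUPS,
    NormativeDatabase,
    assign_age_group,
    score_cohort,
)
from .spectral import BandPowerRecord
from .stats import pearson_r


@dataclass
class CrossValidationReport:
    """Per-(electrode, band) correlation of z-scores from two databases."""

    correlations: pd.DataFrame  # index (electrode, band), columns r, p

    @property
    def min_r(self) -> float:
        return float(self.correlations["r"].min())

    @property
    def max_r(self) -> float:
        return float(self.correlations["r"].max())

    def matrix(self) -> pd.DataFrame:
        """Electrodes x bands grid of r (the printed-table layout)."""
        return self.correlations["r"].unstack("band")


@dataclass
class CoverageAudit:
    """Fractions of values inside mu +/- k sigma for k = 1, 2, 3."""

    within_1sd: float
    within_2sd: float
    within_3sd: float

    def __post_init__(self) -> None:
        fracs = (self.within_1sd, self.within_2sd, self.within_3sd)
        if not all(0 <= f <= 1 for f in fracs):
            raise DegenerateDataError("coverage fractions outside [0, 1]")
        if not (fracs[0] <= fracs[1] <= fracs[2]):
            raise DegenerateDataError("coverage fractions must be monotone")


def cross_database_validation(benchmark: list[BandPowerRecord],
                              db_a: NormativeDatabase,
                              db_b: NormativeDatabase
                              ) -> CrossValidationReport:
    """Correlate a benchmark cohort's z-scores from two databases.

    Every benchmark subject is scored (own_group) against both
    databases; per (electrode, band), Pearson r is computed across
    subjects between the two z vectors.
    """
    if len(benchmark) < 3:
        raise DegenerateDataError("benchmark needs >= 3 subjects")
    za = score_cohort(benchmark, db_a).T
    zb = score_cohort(benchmark, db_b).T
    rows = {}
    for cell in za.index:
        r, p = pearson_r(za.loc[cell].to_numpy(), zb.loc[cell].to_numpy())
        rows[cell] = {"r": r, "p": p}
    corr = pd.DataFrame.from_dict(rows, orient="index")
    corr.index = pd.MultiIndex.from_tuples(corr.index,
                                           names=["electrode", "band"])
    return CrossValidationReport(correlations=corr)


def leave_one_out(cohort: list[BandPowerRecord],
                  scheme: AgeGroupScheme = DEFAULT_AGE_GROUPS
                  ) -> pd.DataFrame:
    """Score every subject against norms rebuilt without them.

    Uses a mean/variance downdate per age group rather than n full
    rebuilds.  Returns a subjects x (electrode, band) DataFrame of
    leave-one-out z-scores.  Each group needs >= 3 subjects so the
    reduced norms retain n >= 2.
    """
    if not cohort:
        raise DegenerateDataError("empty cohort")
    cells = sorted(cohort[0].power)
    by_group: dict[str, list[BandPowerRecord]] = {}
    for rec in cohort:
        by_group.setdefault(assign_age_group(rec.age, scheme), []).append(rec)
    rows = {}
    for group, members in by_group.items():
        n = len(members)
        if n < 3:
            raise DegenerateDataError(
                f"group {group} has {n} subjects; leave-one-out needs >= 3")
        X = np.array([[m.power[c] for c in cells] for m in members])
        S = X.sum(axis=0)
        SS = (X ** 2).sum(axis=0)
        for i, rec in enumerate(members):
            x = X[i]
            loo_mean = (S - x) / (n - 1)
            # sample variance of the remaining n-1 values
            loo_var = (SS - x ** 2 - (n - 1) * loo_mean ** 2) / (n - 2)
            loo_var = np.maximum(loo_var, 0.0)
            sd = np.sqrt(loo_var)
            if (sd == 0).any():
                bad = cells[int(np.argmax(sd == 0))]
                raise DegenerateDataError(
                    f"group {group} cell {bad}: zero leave-one-out SD")
            rows[rec.subject_id] = (x - loo_mean) / sd
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(cells,
                                              names=["electrode", "band"])
    return frame


def coverage_audit(values: Sequence[float], mu: float, sigma: float
                   ) -> CoverageAudit:
    """Fractions of values within mu +/- k sigma, closed intervals."""
    if sigma <= 0:
        raise DegenerateDataError("sigma must be > 0")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateDataError("empty value vector")
    dev = np.abs(arr - mu)
    return CoverageAudit(
        within_1sd=float(np.mean(dev <= sigma)),
        within_2sd=float(np.mean(dev <= 2 * sigma)),
        within_3sd=float(np.mean(dev <= 3 * sigma)),
    )
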
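"""Age-stratified normative database construction and z-scoring.

The normative database stores, per (age group, electrode, band) cell,
the mean and sample standard deviation (n-1 denominator) of absolute
band power over the healthy construction cohort.  Any subject's band
power x is standardized against the matching cell as z = (x - mu) /
sigma; |z| is reported alongside because a cohort's signed mean can
cancel bidirectional deviation that the absolute mean exposes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AgeAssignmentError,
    BuildError,
    DegenerateDataError,
    ScoringError,
)
from .spectral import BandPowerRecord, regional_mean


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered age groups with integer-year inclusive bounds."""

    groups: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.groups:
            if lo > hi:
                raise BuildError(f"group {label}: min {lo} > max {hi}")
            if prev_hi is not None and lo <= prev_hi:
                raise BuildError(f"group {label} overlaps the previous group")
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.groups)


#: The default 10-year stratification covering ages 20-70 inclusive.
DEFAULT_AGE_GROUPS = AgeGroupScheme((
    ("20-30", 20, 30),
    ("31-40", 31, 40),
    ("41-50", 41, 50),
    ("51-60", 51, 60),
    ("61-70", 61, 70),
))

#: Electrodes shown in the cohort z-score report (Fp1/Fp2 are scored but
#: omitted from the 17-row report layout).
REPORT_ELECTRODES: tuple[str, ...] = (
    "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "Pz", "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2",
)


def assign_age_group(age: int, scheme: AgeGroupScheme = DEFAULT_AGE_GROUPS
                     ) -> str:
    """Map an integer age to its (inclusive-bounds) group label."""
    for label, lo, hi in scheme.groups:
        if lo <= age <= hi:
            return label
    raise AgeAssignmentError(f"age {age} outside every group of the scheme")


class NormativeDatabase:
    """Per-(age group, electrode, band) normative means and SDs.

    ``cells`` is a DataFrame indexed by (group, electrode, band) with
    columns mean, sd, n.  sigma = 0 cells are stored (flagged degenerate)
    but poison scoring with :class:`ScoringError`.
    """

    def __init__(self, cells: pd.DataFrame,
                 scheme: AgeGroupScheme = DEFAULT_AGE_GROUPS,
                 meta: dict | None = None):
        cells = cells.copy()
        if (cells["sd"] < 0).any():
            raise BuildError("negative sd in normative cells")
        if (cells.loc[cells["sd"] > 0, "n"] < 2).any():
            raise BuildError("sd reported from a cell with n < 2")
        self.cells = cells.sort_index()
        self.scheme = scheme
        self.meta = meta or {}

    # -- access -------------------------------------------------------
    def cell(self, group: str, electrode: str, band: str
             ) -> tuple[float, float, int]:
        row = self.cells.loc[(group, electrode, band)]
        return float(row["mean"]), float(row["sd"]), int(row["n"])

    @property
    def electrodes(self) -> list[str]:
        return sorted(self.cells.index.get_level_values("electrode").unique())

    @property
    def bands(self) -> list[str]:
        return list(self.cells.index.get_level_values("band").unique())

    def degenerate_cells(self) -> list[tuple[str, str, str]]:
        return [tuple(ix) for ix in self.cells.index[self.cells["sd"] == 0]]

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": [list(g) for g in self.scheme.groups],
            "meta": self.meta,
            "cells": [
                {"group": g, "electrode": e, "band": b,
                 "mean": float(r["mean"]), "sd": float(r["sd"]),
                 "n": int(r["n"])}
                for (g, e, b), r in self.cells.iterrows()
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeDatabase":
        payload = json.loads(Path(path).read_text())
        cells = pd.DataFrame(payload["cells"]).set_index(
            ["group", "electrode", "band"])
        scheme = AgeGroupScheme(tuple(
            (label, int(lo), int(hi)) for label, lo, hi in payload["scheme"]))
        return cls(cells, scheme=scheme, meta=payload.get("meta", {}))

    def to_csv(self, path: str | Path) -> None:
        self.cells.reset_index().to_csv(path, index=False)


def build_norms(cohort: list[BandPowerRecord],
                scheme: AgeGroupScheme = DEFAULT_AGE_GROUPS,
                by_sex: bool = False) -> NormativeDatabase:
    """Build the normative database from a healthy cohort.

    mu is the arithmetic mean and sigma the sample (n-1) standard
    deviation of power across the subjects of each age group, per
    (electrode, band).  Every group needs at least two subjects.
    ``by_sex`` additionally stratifies groups into "<group>/F" and
    "<group>/M".
    """
    if not cohort:
        raise BuildError("empty cohort")
    rows = []
    for rec in cohort:
        group = assign_age_group(rec.age, scheme)
        if by_sex:
            group = f"{group}/{rec.sex}"
        for (electrode, band), value in rec.power.items():
            rows.append((group, rec.subject_id, electrode, band, value))
    frame = pd.DataFrame(
        rows, columns=["group", "subject_id", "electrode", "band", "power"])

    subjects_per_group = frame.groupby("group")["subject_id"].nunique()
    small = subjects_per_group[subjects_per_group < 2]
    if not small.empty:
        raise BuildError(
            f"age group(s) {list(small.index)} have fewer than 2 subjects"
        )

    stats = frame.groupby(["group", "electrode", "band"])["power"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n="size")
    cohort_hash = hashlib.sha1(
        "|".join(sorted(r.subject_id for r in cohort)).encode()
    ).hexdigest()[:12]
    meta = {"build_date": date.today().isoformat(),
            "cohort_hash": cohort_hash,
            "n_subjects": len(cohort),
            "by_sex": by_sex}
    return NormativeDatabase(stats, scheme=scheme, meta=meta)


def zscore_subject(bp: BandPowerRecord, db: NormativeDatabase,
                   mode: str = "own_group") -> pd.Series:
    """Standardize one subject's band powers against the database.

    ``own_group`` returns a Series indexed (electrode, band) using the
    subject's own age group — the clinically meaningful score.
    ``all_groups`` returns a Series indexed (electrode, band, group)
    with one z per normative group, the bookkeeping under which a
    cohort yields n_subjects x 19 x 5 x 5 z values.
    """
    if mode not in ("own_group", "all_groups"):
        raise ScoringError(f"unknown scoring mode {mode!r}")
    if mode == "own_group":
        groups = [assign_age_group(bp.age, db.scheme)]
    else:
        groups = list(db.scheme.labels)
    out: dict[tuple, float] = {}
    for electrode, band in bp.power:
        x = bp.power[(electrode, band)]
        for group in groups:
            try:
                mu, sigma, _ = db.cell(group, electrode, band)
            except KeyError:
                raise ScoringError(
                    f"cell ({group}, {electrode}, {band}) missing from the "
                    f"database") from None
            if sigma == 0:
                raise ScoringError(
                    f"cell ({group}, {electrode}, {band}) has sigma = 0; "
                    f"z-score undefined")
            key = (electrode, band) if mode == "own_group" \
                else (electrode, band, group)
            out[key] = (x - mu) / sigma
    names = ["electrode", "band"] if mode == "own_group" \
        else ["electrode", "band", "group"]
    index = pd.MultiIndex.from_tuples(list(out), names=names)
    return pd.Series(list(out.values()), index=index, name=bp.subject_id)


def score_cohort(cohort: list[BandPowerRecord], db: NormativeDatabase,
                 mode: str = "own_group") -> pd.DataFrame:
    """Vectorized :func:`zscore_subject` over a whole cohort.

    Returns a subjects x (electrode, band) DataFrame in ``own_group``
    mode, or subjects x (electrode, band, group) in ``all_groups`` mode.
    Row order follows the cohort; results match per-subject scoring
    exactly.
    """
    if mode not in ("own_group", "all_groups"):
        raise ScoringError(f"unknown scoring mode {mode!r}")
    if not cohort:
        raise ScoringError("empty cohort")
    cells = sorted(cohort[0].power)
    X = np.array([[bp.power[c] for c in cells] for bp in cohort])
    groups = db.scheme.labels if mode == "all_groups" else None
    norm = {}
    wanted = set(db.scheme.labels) if mode == "all_groups" else \
        {assign_age_group(bp.age, db.scheme) for bp in cohort}
    for group in wanted:
        mu = np.empty(len(cells))
        sigma = np.empty(len(cells))
        for k, (electrode, band) in enumerate(cells):
            try:
                mu[k], sigma[k], _ = db.cell(group, electrode, band)
            except KeyError:
                raise ScoringError(
                    f"cell ({group}, {electrode}, {band}) missing from "
                    f"the database") from None
        if (sigma == 0).any():
            bad = cells[int(np.argmax(sigma == 0))]
            raise ScoringError(
                f"cell ({group}, {bad[0]}, {bad[1]}) has sigma = 0; "
                f"z-score undefined")
        norm[group] = (mu, sigma)
    index = pd.Index([bp.subject_id for bp in cohort], name="subject_id")
    if mode == "own_group":
        Z = np.empty_like(X)
        for i, bp in enumerate(cohort):
            mu, sigma = norm[assign_age_group(bp.age, db.scheme)]
            Z[i] = (X[i] - mu) / sigma
        columns = pd.MultiIndex.from_tuples(cells,
                                            names=["electrode", "band"])
        return pd.DataFrame(Z, index=index, columns=columns)
    blocks = []
    for group in groups:
        mu, sigma = norm[group]
        blocks.append((X - mu) / sigma)
    columns = pd.MultiIndex.from_tuples(
        [(e, b, g) for g in groups for e, b in cells],
        names=["electrode", "band", "group"])
    return pd.DataFrame(np.hstack(blocks), index=index, columns=columns)


@dataclass
class ZScoreReport:
    """Cohort-level z and |z| summary against one normative database.

    ``cell_summary`` holds mean/SD of z and of |z| per (electrode,
    band) with a flag where either mean magnitude exceeds 1 (the
    conventional potential-abnormality threshold); ``regional_summary``
    averages the cell means over scalp regions; ``table`` is the
    17-electrode report view (Fp1/Fp2 scored but not shown).
    """

    cell_summary: pd.DataFrame
    regional_summary: pd.DataFrame
    n_subjects: int

    @property
    def table(self) -> pd.DataFrame:
        present = [e for e in REPORT_ELECTRODES
                   if e in self.cell_summary.index.get_level_values(0)]
        return self.cell_summary.loc[present]

    def flagged_cells(self) -> list[tuple[str, str]]:
        return [tuple(ix) for ix in
                self.cell_summary.index[self.cell_summary["flagged"]]]


def cohort_z_summary(reports: list[pd.Series]) -> ZScoreReport:
    """Aggregate per-subject own-group z tables into a cohort report."""
    if not reports:
        raise DegenerateDataError("empty cohort in z summary")
    z = pd.concat(reports, axis=1)
    if z.isna().any().any():
        raise ScoringError("subjects scored over different cell sets")
    az = z.abs()
    summary = pd.DataFrame({
        "mean_z": z.mean(axis=1),
        "sd_z": z.std(axis=1, ddof=1),
        "mean_abs_z": az.mean(axis=1),
        "sd_abs_z": az.std(axis=1, ddof=1),
    })
    summary["flagged"] = (summary["mean_z"].abs() > 1) | \
        (summary["mean_abs_z"] > 1)
    regional = {}
    for col in ("mean_z", "mean_abs_z"):
        regional[col] = regional_mean(summary[col])
    reg_frame = pd.DataFrame(regional)
    reg_frame.index = pd.MultiIndex.from_tuples(
        reg_frame.index, names=["region", "band"])
    return ZScoreReport(cell_summary=summary, regional_summary=reg_frame,
                        n_subjects=z.shape[1])
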
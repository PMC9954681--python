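# qeegnorm

Age-stratified normative databases for resting-state quantitative EEG
(qEEG), with the full pipeline around them: recording ingestion and
artifact rejection, absolute band-power estimation, z-scoring of
individual subjects against the norms, and the reliability/validity
machinery used to qualify a normative database.

## The problem

Clinical qEEG interprets a patient's spectral features relative to a
healthy reference population. A *normative database* stores, for every
combination of age group *g*, electrode *e* (19-channel 10–20 montage)
and frequency band *b* (delta 1–4, theta 4–8, alpha 8–12, beta 12–25,
high-beta 25–30 Hz), the mean μ and standard deviation σ of absolute
band power (µV²) over a screened healthy cohort. A subject's power
*x* is then standardized as

    z = (x − μ_{g,e,b}) / σ_{g,e,b}

Under the Gaussian reference model, 68.26% / 95.44% / 99.74% of healthy
values fall within ±1 / ±2 / ±3 SD, and cohort-mean z or |z| above 1
flags potential abnormality. The absolute-value score |z| matters
because a patient cohort deviating in *both* directions can average to
a signed mean near zero while |z| exposes the deviation.

The package is aimed at clinical-neurophysiology and biostatistics
workflows that need to build such norms from their own cohorts, score
patient groups against them, and audit the result: internal consistency
(Cronbach's α across the central electrodes C3/Cz/C4), leave-one-out
cross-validation, completely independent cross-database validation
(score a benchmark cohort against two databases and correlate the
paired z-scores per cell), and Gaussian coverage checks.

Because subject-level normative EEG data are generally not
redistributable, the package ships a first-class synthetic-data module
that generates band-power cohorts with a realistic age/sex structure
(slow-wave decline with age, fast-wave rise after 50, screened
questionnaire scores) and raw 19-channel signals with injectable blink
and movement artifacts — all with known ground truth, so every pipeline
stage is testable by parameter recovery.

## Worked example

```python
import qeegnorm as q
from qeegnorm.normdb import score_cohort

healthy, _, _ = q.generate_cohort(q.hc_spec(), seed=7)    # 260 subjects
patients, _, _ = q.generate_cohort(q.mdd_spec(), seed=8)  # 221 subjects

db = q.build_norms(healthy)                  # 5 age groups x 19 x 5 cells
z = score_cohort(patients, db)               # own-age-group z-scores
report = q.cohort_z_summary([z.loc[s] for s in z.index])

cell = report.cell_summary.loc[("Fz", "high-beta")]
print(f"Fz high-beta: mean z = {cell['mean_z']:.2f} "
      f"(SD {cell['sd_z']:.2f}), mean |z| = {cell['mean_abs_z']:.2f}")
region = report.regional_summary.loc[("frontal", "high-beta")]
print(f"frontal high-beta: mean z = {region['mean_z']:.2f}")
print(f"{len(report.flagged_cells())} of 95 cells flagged (mean z or |z| > 1)")
```

prints

```
Fz high-beta: mean z = 1.79 (SD 1.09), mean |z| = 1.85
frontal high-beta: mean z = 1.82
28 of 95 cells flagged (mean z or |z| > 1)
```

The patient preset injects a frontal-dominant beta/high-beta elevation
(+1.73 SD at Fz in high-beta); scoring the generated patients against
norms built from an independent healthy cohort recovers that shift in
the cohort-mean z, and flags exactly the fast-wave cells — the
depression signature the pipeline is designed to surface.

## Repository layout

- `src/qeegnorm/` — the library: `io_preprocess` (EDF/tabular reading,
  screening, 20-s-window artifact rejection, 60-s minimum-clean gate,
  exclusion ledger), `spectral` (Welch band power, regional means),
  `normdb` (norm construction, z / |z| scoring and cohort reports),
  `stats` (t tests from summaries, chi-square with cell comparisons,
  ANOVA + Bonferroni, Pearson r, Cronbach's α, LOWESS), `validation`
  (cross-database, leave-one-out, coverage audits), `synthetic`
  (cohort/signal generators).
- `analysis/01…06_*.py` — numbered drivers that run the study end to
  end on synthetic cohorts and write tables under `results/`.
- `qeeg` — a thin CLI over the library (`qeeg simulate-cohort`,
  `preprocess`, `bandpower`, `build-norms`, `score`, `validate-cross`,
  `validate-loo`).
- `docs/methods.md` — models, parameter choices, numerical decisions
  and known limitations.

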
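# Methods

This note documents the models and procedures implemented in
`qeegnorm`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Normative model

For a screened healthy cohort, the normative database stores per
(age group, electrode, band) cell the arithmetic mean μ and the
*sample* standard deviation σ (n−1 denominator) of absolute band power
in µV². Age groups default to five 10-year strata with integer-year
inclusive bounds (20–30, 31–40, 41–50, 51–60, 61–70); an age of 30
belongs to the first group, 31 to the second. Norms are age-stratified
only by default — sex-balanced recruitment is assumed rather than
sex-stratified norms — with a `by_sex` flag for the stratified variant.

A subject's score is z = (x − μ)/σ against their own age group's cell
(`own_group` mode). An `all_groups` mode scores each cell against all
five groups, which is the bookkeeping under which a cohort of n
subjects yields n × 19 × 5 × 5 z values; clinically meaningful reports
use `own_group`.

Using the n−1 estimator on both sides makes self-scoring exact: when
the construction cohort is scored against its own database, every
cell's z values have mean 0 and sample SD 1 to floating round-off.
This is the structural invariant the test suite asserts at 1e−10.

σ = 0 cells (possible only with degenerate input) are stored and
flagged, but any attempt to score against them raises an error rather
than returning ±∞.

Cohort reports aggregate mean and SD of z and of |z| per cell, flag
cells whose mean z or mean |z| exceeds 1 (the conventional
potential-abnormality threshold), and average cell means over five
scalp regions (frontal F3/F4/Fz, central C3/C4/Cz, parietal P3/P4/Pz,
temporal T3/T4/T5/T6, occipital O1/O2). The tabular report view shows
17 electrodes — Fp1/Fp2 are scored but omitted from the layout, which
mirrors common reporting practice for frontopolar sites while not
discarding data.

## Preprocessing

Recordings are 19-channel 10–20 montage, linked-ear reference, with a
sampling-rate floor of 60 Hz (Nyquist for the 30 Hz analysis edge;
typical acquisitions use 256 Hz). Artifact screening tiles the
recording into consecutive 20-s windows and rejects a window if any
channel exceeds ±100 µV or jumps by more than 50 µV between
consecutive samples. These two thresholds are a reproducible automated
surrogate for the manual artifact review that normative-database
practice typically relies on; both are configurable, and the gradient
check is evaluated within windows so that re-screening the
concatenation of retained windows is idempotent. The trailing partial
window is discarded, not padded. Subjects retaining less than 60 s of
clean data (inclusive gate: exactly 60 s passes) are excluded with
reason `artifact`, and all screening/exclusion decisions feed a ledger
whose stage arithmetic (recruited − screening exclusions = completed;
completed − EEG exclusions = final n) is validated.

Questionnaire screening is literal: healthy controls require BDI-II
< 14 *and* BAI < 8; patients require BDI-II > 14, BAI > 8 and a
primary diagnosis of MDD. Scores exactly at 14/8 fail both screens —
the boundary is genuinely ambiguous in common usage, and the strict
reading is applied symmetrically.

## Spectral estimation

Band power is estimated with Welch's method on clean segments only:
2-s epochs, 50% overlap, Hann taper, density scaling (µV²/Hz). The
2-s epoch gives 0.5 Hz resolution, sufficient for the 1 Hz band edges;
averaging periodograms across epochs (weighted by epoch count per
segment) stabilizes the estimate. Absolute band power is the
trapezoidal integral of the PSD over each band. Bands are labelled
half-open [low, high) so each shared edge (4, 8, 12, 25 Hz) belongs to
one band, but for the integral the shared-edge frequency carries zero
measure, and integrating with both endpoints included makes the five
band powers sum exactly to the 1–30 Hz total — the partition property
the tests assert. Frequencies below 1 Hz and above 30 Hz never enter
any band. Powers are reported in raw µV² by default; a log10 mode
exists for pipelines that prefer the log scale but is not used in the
analyses here.

Segments shorter than one epoch are skipped; a subject with no usable
epoch raises an estimation error rather than returning zeros.

## Statistics

- Two-sample t tests operate on (n, mean, SD) summaries so published
  tables can be fed in directly: pooled (df = n₁+n₂−2) and Welch
  (Welch–Satterthwaite fractional df). Both are cross-checked in the
  tests against scipy's raw-data and from-stats routines.
- Chi-square is Pearson's, uncorrected by default (a Yates flag
  exists); cell-wise "which cells drive the association" uses adjusted
  standardized residuals (O−E)/√(E(1−row/n)(1−col/n)) with a |1.96|
  cutoff.
- One-way ANOVA is the standard between-subjects F; post hoc
  comparisons are all pairwise pooled t tests with Bonferroni
  multiplication capped at 1. Sphericity corrections are not
  implemented: sphericity is undefined for a between-subjects one-way
  design.
- Cronbach's α = k/(k−1)·(1 − Σ item variances / variance of case
  totals) with n−1 variances; in this pipeline the items are C3, Cz,
  C4 and the cases are participants, computed per band on absolute
  power (the data scale is a documented assumption). Cross-checked
  against pingouin.
- LOWESS age trends use the statsmodels tricube local-linear smoother.
- All p-values are two-sided and unadjusted; the cross-database
  correlation matrix is reported raw, without multiple-testing
  correction.

## Validation machinery

*Completely independent cross-validation*: a benchmark cohort is
scored (own group) against two databases and per (electrode, band) the
Pearson r between the paired z vectors is computed across subjects.
Within one age group the two z's are affine functions of the same
power, so r is driven entirely by the databases' per-group (μ, σ)
estimation noise. With databases built from cohorts of ~26 subjects
per age group, that noise puts typical per-cell r near 0.95, and the
minimum over 95 cells reliably falls in the high 0.8s — an intrinsic
property of the sample sizes, not an implementation artifact. The
second database is synthesized (independent half-cohort or perturbed
norms) since commercial databases do not publish their parameters.

*Leave-one-out*: each subject is scored against norms rebuilt from
their age group minus themselves, computed via a mean/variance
downdate (identical to brute-force rebuilding, which the tests verify
at 1e−9, but O(n) instead of O(n²)). Groups need ≥ 3 subjects so the
reduced norms keep n ≥ 2.

*Coverage audit*: fractions of values within μ ± kσ for k = 1, 2, 3,
with closed intervals (a value exactly at μ ± σ counts as inside,
matching "within the range of"). For Gaussian data these converge to
68.26%, 95.44% and 99.74%.

## Synthetic data

The cohort generator draws band powers at the feature level: per
(age group, electrode, band) cell, a normal with the age-trended mean
and SD, truncated at 0 by redraw. Defaults: baseline means delta 20,
theta 12, alpha 15, beta 8, high-beta 4 µV² — typical eyes-closed
adult magnitudes — with SD = 25% of the mean; slow bands decline 2%
per age-group step and fast bands rise 5% from the 51–60 group, the
qualitative age structure seen in normative cohorts. The 25% spread
keeps every cell ≥ 4 SD above zero, so the truncation is a negligible
edge guard (≈3×10⁻⁵ rejection) and the cells are effectively Gaussian
— deliberately matching the Gaussian reference model the z machinery
assumes. Real absolute power is right-skewed with larger
between-subject spread (which is why some databases log-transform
first); passing tests on these cohorts therefore demonstrate the
pipeline's statistical machinery, not robustness to real-data
skewness.

The healthy preset has 260 subjects (84/47/55/49/25 per age group,
130 F / 130 M) and screened questionnaire scores from truncated
normals (BDI-II mean 4.23 SD 3.52, BAI 1.95/1.93, integer scores
redrawn until they satisfy the screen — note the [0, 14) truncation
raises the realized BDI-II mean by ≈0.7 above the nominal 4.23; tests
compare against the truncated-normal mean). The patient preset has
221 subjects (65/39/55/37/25; 163 F / 58 M; BDI-II 31.93/10.50, BAI
22.28/9.91) and shifts each cell's mean by δ·σ, where the default δ
pattern is a frontal-dominant beta/high-beta elevation (up to +1.77 SD)
with near-zero slow-wave shifts — the depression signature the scorer
should recover. Cells are drawn independently across electrodes (no
volume-conduction correlation), so internal-consistency coefficients
computed *on synthetic cohorts* are near zero by construction; α is
validated by oracle equivalence on hand matrices instead.

The signal generator synthesizes each channel as a sum over bands of
FFT-shaped band-limited Gaussian noise scaled so the realized band
variance equals the target power exactly, with a 0.5 Hz guard margin
inside each band's edges so spectral-leakage stays attributable to the
band (round-trip calibration through the Welch estimator is within 5%
on 60-s signals). Blinks are 300–500 µV Gaussian-envelope lobes
(σ = 0.15 s) on the frontal channels; movements are broadband bursts
on all channels. There is no dipole/forward modelling and no eyes-open
condition.

## Analysis problem sizes

The numbered analysis drivers and the acceptance script use the preset
cohort sizes (260 healthy / 221 patients) throughout; the Gaussian
coverage audit uses a 1,250-subject cohort (250 per group, ≈119,000
z values), and the half-split cross-database check uses 130 subjects
per half with a 200-subject benchmark.

## Known limitations

- Artifact criteria are amplitude/gradient surrogates for expert
  manual review; no ocular ICA/regression correction is attempted.
- Norms assume the recorded linked-ear reference; no re-referencing.
- The Gaussian cell model ignores the right skew of real absolute
  power; a log-transform mode exists but is not the default.
- Synthetic electrodes are independent within subject, so
  reliability coefficients on synthetic cohorts underestimate real
  ones.
- Relative power, power ratios, coherence, phase and asymmetry
  metrics are out of scope.
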
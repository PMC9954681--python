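"""Synthetic cohorts and raw EEG signals with known ground truth.

Real normative-database cohorts are not redistributable, so every input
the pipeline needs is generated here: band-power cohorts with the
study-like age/sex structure (slow-wave decline with age, fast-wave
rise in the oldest groups, an MDD band-power shift expressed in SD
units), questionnaire metadata that respects the recruitment screens,
and raw multichannel signals built from band-limited Gaussian noise
with injectable blink/movement artifacts.  All generators are
deterministic under their seed and return the ground truth used, so
parameter-recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SpecError
from .io_preprocess import EDUCATION_LEVELS, EEGRecording, SubjectRecord
from .montage import CHANNELS_10_20
from .normdb import DEFAULT_AGE_GROUPS, AgeGroupScheme
from .spectral import DEFAULT_BANDS, BandPowerRecord, BandScheme

#: Frontal channels that receive eye-blink artifacts.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8")

#: Baseline absolute power per band: (mean, SD) in µV², typical
#: eyes-closed adult magnitudes.  The 25% between-subject spread keeps
#: each cell effectively Gaussian (zero-truncation is a negligible edge
#: guard), matching the Gaussian structure the z-score machinery assumes.
DEFAULT_BASELINE: dict[str, tuple[float, float]] = {
    "delta": (20.0, 5.0),
    "theta": (12.0, 3.0),
    "alpha": (15.0, 3.75),
    "beta": (8.0, 2.0),
    "high-beta": (4.0, 1.0),
}

_SLOW_TREND = (1.00, 0.98, 0.96, 0.94, 0.92)   # -2% per group step
_FAST_TREND = (1.00, 1.00, 1.00, 1.05, 1.05)   # +5% from the 51-60 group

#: Age-trend multipliers per band across the five age groups: slow
#: waves decline with age, fast waves rise slightly after 50.
DEFAULT_AGE_TREND: dict[str, tuple[float, ...]] = {
    "delta": _SLOW_TREND,
    "theta": _SLOW_TREND,
    "alpha": _SLOW_TREND,
    "beta": _FAST_TREND,
    "high-beta": _FAST_TREND,
}

#: Healthy-cohort group sizes (n_female, n_male) per age group.
HC_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "20-30": (40, 44), "31-40": (23, 24), "41-50": (26, 29),
    "51-60": (26, 23), "61-70": (15, 10),
}

#: Patient-cohort group sizes (n_female, n_male) per age group.
MDD_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "20-30": (41, 24), "31-40": (33, 6), "41-50": (43, 12),
    "51-60": (28, 9), "61-70": (18, 7),
}

_HC_EDU_WEIGHTS = (2, 4, 32, 33, 113, 76)
_MDD_EDU_WEIGHTS = (6, 20, 66, 32, 77, 20)

#: MDD band-power shift per electrode, in SD units, per band
#: (delta, theta, alpha, beta, high-beta): near-zero slow-wave shifts,
#: beta/high-beta elevation strongest frontally.
MDD_DELTA_PRESET: dict[str, tuple[float, float, float, float, float]] = {
    "Fz": (-0.11, -0.03, 0.07, 1.22, 1.73),
    "F3": (-0.08, -0.02, 0.09, 1.21, 1.77),
    "F4": (-0.17, -0.03, 0.06, 1.26, 1.72),
    "F7": (-0.08, -0.06, 0.06, 1.02, 1.42),
    "F8": (-0.15, -0.10, 0.03, 0.90, 1.17),
    "Cz": (-0.18, -0.06, 0.05, 1.12, 1.13),
    "C3": (-0.15, -0.01, 0.08, 0.86, 1.34),
    "C4": (-0.16, 0.00, 0.11, 0.88, 1.19),
    "Pz": (-0.09, -0.05, 0.02, 0.72, 1.24),
    "P3": (-0.11, -0.04, 0.05, 0.67, 1.43),
    "P4": (-0.09, -0.02, 0.06, 0.70, 1.25),
    "T3": (-0.20, -0.04, 0.12, 0.95, 1.11),
    "T4": (-0.19, -0.11, 0.06, 0.93, 1.12),
    "T5": (-0.16, -0.03, 0.09, 0.67, 0.93),
    "T6": (-0.10, 0.03, 0.14, 0.95, 1.12),
    "O1": (-0.02, 0.00, 0.08, 0.67, 0.96),
    "O2": (-0.08, -0.03, 0.07, 0.57, 0.96),
}


@dataclass
class CohortSpec:
    """Ground-truth description of a synthetic cohort."""

    group: str = "HC"
    group_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(HC_GROUP_SIZES))
    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE))
    age_trend: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_TREND))
    delta: dict[tuple[str, str], float] = field(default_factory=dict)
    bdi: tuple[float, float] = (4.23, 3.52)
    bai: tuple[float, float] = (1.95, 1.93)
    education_weights: tuple[float, ...] = _HC_EDU_WEIGHTS
    electrodes: tuple[str, ...] = CHANNELS_10_20
    bands: BandScheme = DEFAULT_BANDS
    age_scheme: AgeGroupScheme = DEFAULT_AGE_GROUPS

    def __post_init__(self) -> None:
        for label, (nf, nm) in self.group_sizes.items():
            if nf < 0 or nm < 0:
                raise SpecError(f"negative n in group {label}")
            if nf + nm < 2:
                raise SpecError(f"group {label} needs n >= 2")
        for band, (mean, sd) in self.baseline.items():
            if sd <= 0:
                raise SpecError(f"band {band}: SD must be > 0")

    @property
    def n_subjects(self) -> int:
        return sum(nf + nm for nf, nm in self.group_sizes.values())


def hc_spec(**overrides) -> CohortSpec:
    """Healthy-control preset: 260 subjects, 84/47/55/49/25 per group."""
    return CohortSpec(**overrides)


def mdd_spec(**overrides) -> CohortSpec:
    """Patient preset: 221 subjects with the beta/high-beta elevation."""
    delta = {
        (electrode, band): value
        for electrode, values in MDD_DELTA_PRESET.items()
        for band, value in zip(DEFAULT_BANDS.names, values)
    }
    defaults = dict(
        group="MDD",
        group_sizes=dict(MDD_GROUP_SIZES),
        delta=delta,
        bdi=(31.93, 10.50),
        bai=(22.28, 9.91),
        education_weights=_MDD_EDU_WEIGHTS,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def cell_truth(spec: CohortSpec) -> pd.DataFrame:
    """Per-(age group, electrode, band) true mean, SD and shift."""
    rows = []
    for gi, (label, _, _) in enumerate(spec.age_scheme.groups):
        if label not in spec.group_sizes:
            continue
        for band in spec.bands.names:
            base_mean, base_sd = spec.baseline[band]
            mult = spec.age_trend[band][gi]
            for electrode in spec.electrodes:
                shift = spec.delta.get((electrode, band), 0.0)
                rows.append({
                    "group": label, "electrode": electrode, "band": band,
                    "mean": base_mean * mult + shift * base_sd * mult,
                    "sd": base_sd * mult,
                    "delta": shift,
                })
    return pd.DataFrame(rows).set_index(["group", "electrode", "band"])


def generate_questionnaires(spec: CohortSpec, n: int,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Integer BDI-II and BAI scores that satisfy the group's screen.

    Scores are drawn from the group's (mean, SD), rounded, and redrawn
    until they land in [0, 63] and on the correct side of the 14/8
    cut-offs (strictly below for HC, strictly above for MDD).
    """
    cuts = {"bdi": 14, "bai": 8}
    out = []
    for name, (mean, sd) in (("bdi", spec.bdi), ("bai", spec.bai)):
        cut = cuts[name]
        if spec.group == "HC" and mean >= cut:
            import warnings

            warnings.warn(f"HC {name} mean {mean} at/above the cut {cut}: "
                          f"high rejection rate", stacklevel=2)
        scores = np.empty(n, dtype=int)
        remaining = np.arange(n)
        for _ in range(10000):
            draws = np.rint(rng.normal(mean, sd, remaining.size)).astype(int)
            if spec.group == "HC":
                ok = (draws >= 0) & (draws < cut)
            else:
                ok = (draws > cut) & (draws <= 63)
            scores[remaining[ok]] = draws[ok]
            remaining = remaining[~ok]
            if remaining.size == 0:
                break
        else:
            raise SpecError(f"{name} spec incompatible with the "
                            f"{spec.group} screen")
        out.append(scores)
    return out[0], out[1]


def generate_cohort(spec: CohortSpec, seed: int = 0
                    ) -> tuple[list[BandPowerRecord], list[SubjectRecord],
                               pd.DataFrame]:
    """Draw a full cohort at the band-power feature level.

    Per (age group, electrode, band) cell, powers are drawn from a
    normal truncated at 0 (redraw, not clip) with the age-trended mean;
    MDD subjects get the mean shifted by delta * sigma.  Returns the
    band-power records, subject metadata, and the ground-truth table.
    """
    rng = np.random.default_rng(seed)
    truth = cell_truth(spec)
    bounds = {label: (lo, hi) for label, lo, hi in spec.age_scheme.groups}
    edu_p = np.asarray(spec.education_weights, dtype=float)
    edu_p = edu_p / edu_p.sum()

    records: list[BandPowerRecord] = []
    subjects: list[SubjectRecord] = []
    counter = 0
    for label, (n_f, n_m) in spec.group_sizes.items():
        lo, hi = bounds[label]
        n = n_f + n_m
        ages = rng.integers(lo, hi + 1, size=n)
        sexes = np.array(["F"] * n_f + ["M"] * n_m)
        bdi, bai = generate_questionnaires(spec, n, rng)
        edu = rng.choice(len(EDUCATION_LEVELS), size=n, p=edu_p)
        cells = truth.loc[label]
        cell_keys = list(cells.index)
        means = cells["mean"].to_numpy()
        sds = cells["sd"].to_numpy()
        draws = rng.normal(means, sds, size=(n, len(cell_keys)))
        for _ in range(1000):
            bad = draws <= 0
            if not bad.any():
                break
            draws[bad] = rng.normal(np.broadcast_to(means, draws.shape)[bad],
                                    np.broadcast_to(sds, draws.shape)[bad])
        else:
            raise SpecError("band-power truncation at 0 failed to converge")
        for i in range(n):
            counter += 1
            sid = f"{spec.group}-{counter:04d}"
            power = dict(zip(cell_keys, draws[i]))
            records.append(BandPowerRecord(
                subject_id=sid, age=int(ages[i]), power=power,
                sex=str(sexes[i]), group=spec.group,
                clean_seconds_used=60.0))
            subjects.append(SubjectRecord(
                subject_id=sid, age=int(ages[i]), sex=str(sexes[i]),
                bdi_ii=int(bdi[i]), bai=int(bai[i]), group=spec.group,
                education=EDUCATION_LEVELS[edu[i]]))
    return records, subjects, truth


@dataclass
class ArtifactEvent:
    """A transient contaminant: blink (frontal) or movement (global)."""

    time_seconds: float
    kind: str  # "blink" | "movement"
    amplitude: float = 400.0

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "movement"):
            raise SpecError(f"unknown artifact kind {self.kind!r}")


@dataclass
class SignalSpec:
    """Description of a raw synthetic recording."""

    duration_seconds: float = 300.0
    sampling_rate: float = 256.0
    band_targets: dict[str, float] = field(
        default_factory=lambda: {band: mean for band, (mean, _)
                                 in DEFAULT_BASELINE.items()})
    artifacts: list[ArtifactEvent] = field(default_factory=list)
    channels: tuple[str, ...] = CHANNELS_10_20
    bands: BandScheme = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0:
            raise SpecError("duration must be > 0")
        if any(v < 0 for v in self.band_targets.values()):
            raise SpecError("band power targets must be >= 0")
        if self.sampling_rate < 2 * self.bands.high_edge:
            raise SpecError(
                f"sampling rate {self.sampling_rate} Hz too low for the "
                f"{self.bands.high_edge} Hz band edge")


def generate_signal(spec: SignalSpec, seed: int = 0) -> EEGRecording:
    """Synthesize a raw multichannel recording.

    Each channel is a sum over bands of band-limited Gaussian noise
    (FFT-shaped, scaled so the realized band variance equals the
    target power exactly), plus injected artifacts: a blink is a
    300-500 µV low-frequency lobe on the frontal channels, a movement
    a broadband high-amplitude burst on every channel.

    Band noise is shaped with a small guard margin (0.5 Hz, or a
    quarter of the band width for narrow bands) inside each band's
    edges, so that spectral-estimation leakage stays attributable to
    the band rather than spilling into its neighbours at the shared
    edge.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_seconds * spec.sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    edges = {name: (lo, hi) for name, lo, hi in spec.bands.bands}
    data = np.zeros((len(spec.channels), n))
    for ci in range(len(spec.channels)):
        for band, target in spec.band_targets.items():
            if target <= 0:
                continue
            lo, hi = edges[band]
            margin = min(0.5, (hi - lo) / 4)
            spectrum = np.fft.rfft(rng.standard_normal(n))
            spectrum[(freqs < lo + margin) | (freqs >= hi - margin)] = 0.0
            x = np.fft.irfft(spectrum, n)
            var = x.var()
            if var > 0:
                data[ci] += x * np.sqrt(target / var)

    t = np.arange(n) / spec.sampling_rate
    frontal = [i for i, ch in enumerate(spec.channels)
               if ch in FRONTAL_CHANNELS]
    for event in spec.artifacts:
        if event.kind == "blink":
            lobe = event.amplitude * np.exp(
                -0.5 * ((t - event.time_seconds) / 0.15) ** 2)
            data[frontal] += lobe
        else:  # movement
            envelope = np.exp(-0.5 * ((t - event.time_seconds) / 0.25) ** 2)
            burst = envelope * rng.standard_normal(n)
            data += event.amplitude * burst
    return EEGRecording(subject_id=f"synthetic-{seed}",
                        channels=list(spec.channels),
                        sampling_rate=spec.sampling_rate, data=data)
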
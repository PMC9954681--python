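"""Reading, screening and artifact rejection for resting-state EEG.

The pipeline ingests 19-channel linked-ear referenced recordings
(EDF or a plain tabular format), screens subjects on age and on the
Beck depression / anxiety questionnaires, rejects artifact windows,
and enforces a minimum amount of clean data per subject.  Every
exclusion is tallied into an :class:`ExclusionLedger` whose stage
arithmetic is checked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    ConfigError,
    InsufficientCleanDataError,
    LedgerError,
    MontageError,
)
from .montage import canonical_label

EDUCATION_LEVELS: tuple[str, ...] = (
    "primary school",
    "junior high school",
    "senior/vocational high school",
    "junior college",
    "university",
    "graduate school",
)


@dataclass
class EEGRecording:
    """A multichannel resting-state EEG recording.

    ``data`` is an (n_channels, n_samples) array of amplitudes in µV,
    row order matching ``channels``.
    """

    subject_id: str
    channels: list[str]
    sampling_rate: float
    data: np.ndarray
    reference: str = "linked-ear"
    eyes_condition: str = "closed"

    def __post_init__(self) -> None:
        self.channels = [canonical_label(c) for c in self.channels]
        if len(set(self.channels)) != len(self.channels):
            raise MontageError("duplicate channel labels")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ConfigError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if self.data.shape[1] == 0:
            raise ConfigError("recording has zero samples")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.eyes_condition not in ("closed", "open"):
            raise ConfigError("eyes_condition must be 'closed' or 'open'")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SubjectRecord:
    """Demographics and questionnaire scores for one participant.

    BDI-II and BAI are 21-item Beck inventories with total scores in
    [0, 63].  ``diagnosis`` is the primary clinical diagnosis and
    defaults to the subject's group label.
    """

    subject_id: str
    age: int
    sex: str
    bdi_ii: int
    bai: int
    group: str
    education: str = "university"
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ConfigError("age must be >= 0")
        if self.sex not in ("F", "M"):
            raise ConfigError("sex must be 'F' or 'M'")
        for name, score in (("bdi_ii", self.bdi_ii), ("bai", self.bai)):
            if not 0 <= score <= 63:
                raise ConfigError(f"{name}={score} outside [0, 63]")
        if self.group not in ("HC", "MDD"):
            raise ConfigError("group must be 'HC' or 'MDD'")
        if self.education.lower() not in EDUCATION_LEVELS:
            raise ConfigError(f"unknown education level {self.education!r}")
        self.education = self.education.lower()
        if self.diagnosis is None:
            self.diagnosis = self.group


@dataclass
class CleanSegmentSet:
    """Artifact-free sample intervals of one recording.

    Intervals are 0-based half-open ``[start, end)`` sample indices,
    sorted and non-overlapping.
    """

    subject_id: str
    sampling_rate: float
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if start < prev_end or end <= start:
                raise ConfigError("segments must be sorted, non-overlapping")
            prev_end = end

    @property
    def total_clean_seconds(self) -> float:
        return sum(e - s for s, e in self.segments) / self.sampling_rate


@dataclass
class ScreeningConfig:
    """Age window and questionnaire cut-offs used at recruitment.

    Healthy controls must score strictly below both cut-offs; patients
    strictly above both.  Scores exactly at a cut-off fail both screens.
    """

    age_min: int = 20
    age_max: int = 70
    bdi_cut: int = 14
    bai_cut: int = 8


@dataclass
class ExclusionLedger:
    """Stage-by-stage accounting of cohort recruitment.

    Invariants: ``recruited - excluded_screening = completed_eeg`` and
    ``completed_eeg - excluded_eeg = final_n``.
    """

    recruited: int
    excluded_screening: dict[str, int] = field(default_factory=dict)
    completed_eeg: int = 0
    excluded_eeg: dict[str, int] = field(default_factory=dict)
    final_n: int = 0

    def __post_init__(self) -> None:
        n_screen = sum(self.excluded_screening.values())
        n_eeg = sum(self.excluded_eeg.values())
        if self.recruited - n_screen != self.completed_eeg:
            raise LedgerError(
                f"recruited {self.recruited} - screening exclusions "
                f"{n_screen} != completed {self.completed_eeg}"
            )
        if self.completed_eeg - n_eeg != self.final_n:
            raise LedgerError(
                f"completed {self.completed_eeg} - EEG exclusions "
                f"{n_eeg} != final {self.final_n}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def read_recording(path: str | Path, format: str = "tabular",
                   min_sampling_rate: float = 60.0) -> EEGRecording:
    """Read an EEG recording from disk and validate it.

    ``format="edf"`` uses MNE's EDF reader (amplitudes converted to µV).
    ``format="tabular"`` expects a CSV with one column per electrode
    (header = 10-20 labels, one row per sample) and a JSON sidecar
    ``<stem>.json`` holding ``sampling_rate``, ``subject_id`` and
    ``eyes_condition``.

    A sampling rate below ``min_sampling_rate`` (Nyquist requirement for
    the 30 Hz analysis edge) raises :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = list(raw.ch_names)
        rate = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # volts -> µV
        rec = EEGRecording(subject_id=path.stem, channels=channels,
                           sampling_rate=rate, data=data)
    elif format == "tabular":
        import pandas as pd

        frame = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        rec = EEGRecording(
            subject_id=str(meta.get("subject_id", path.stem)),
            channels=list(frame.columns),
            sampling_rate=float(meta.get("sampling_rate", 256.0)),
            data=frame.to_numpy().T,
            reference=meta.get("reference", "linked-ear"),
            eyes_condition=meta.get("eyes_condition", "closed"),
        )
    else:
        raise ConfigError(f"unknown format {format!r}")
    if rec.sampling_rate < min_sampling_rate:
        raise ConfigError(
            f"sampling rate {rec.sampling_rate} Hz below the "
            f"{min_sampling_rate} Hz Nyquist requirement"
        )
    return rec


def write_tabular(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the tabular CSV + JSON-sidecar format."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.channels).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps({
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "reference": rec.reference,
        "eyes_condition": rec.eyes_condition,
    }))


def screen_subject(record: SubjectRecord, role: str,
                   thresholds: ScreeningConfig | None = None
                   ) -> tuple[bool, str]:
    """Apply the recruitment screen for the given role ("HC" or "MDD").

    Returns ``(accept, reason)`` where ``reason`` is "ok" on acceptance
    or names the first failed rule (age, bdi, bai, diagnosis).
    """
    thr = thresholds or ScreeningConfig()
    if not thr.age_min <= record.age <= thr.age_max:
        return False, "age"
    if role == "HC":
        if record.bdi_ii >= thr.bdi_cut:
            return False, "bdi"
        if record.bai >= thr.bai_cut:
            return False, "bai"
        return True, "ok"
    if role == "MDD":
        if record.bdi_ii <= thr.bdi_cut:
            return False, "bdi"
        if record.bai <= thr.bai_cut:
            return False, "bai"
        if record.diagnosis != "MDD":
            return False, "diagnosis"
        return True, "ok"
    raise ConfigError(f"unknown screening role {role!r}")


def reject_artifacts(rec: EEGRecording, window_seconds: float = 20.0,
                     amplitude_limit: float = 100.0,
                     gradient_limit: float = 50.0) -> CleanSegmentSet:
    """Tile the recording into fixed windows and drop contaminated ones.

    A window is rejected if any channel exceeds ``amplitude_limit`` µV
    in absolute value, or jumps by more than ``gradient_limit`` µV
    between consecutive samples within the window.  The trailing partial
    window is discarded.  Adjacent surviving windows are merged.
    """
    win = int(round(window_seconds * rec.sampling_rate))
    if win <= 0 or rec.n_samples < win:
        raise ConfigError("recording shorter than one window")
    segments: list[tuple[int, int]] = []
    for start in range(0, rec.n_samples - win + 1, win):
        block = rec.data[:, start:start + win]
        if np.abs(block).max() > amplitude_limit:
            continue
        if win > 1 and np.abs(np.diff(block, axis=1)).max() > gradient_limit:
            continue
        if segments and segments[-1][1] == start:
            segments[-1] = (segments[-1][0], start + win)
        else:
            segments.append((start, start + win))
    return CleanSegmentSet(subject_id=rec.subject_id,
                           sampling_rate=rec.sampling_rate,
                           segments=segments)


def enforce_minimum_clean(segs: CleanSegmentSet,
                          minimum_seconds: float = 60.0) -> CleanSegmentSet:
    """Pass the segment set through iff it holds at least the minimum.

    The gate is inclusive: exactly ``minimum_seconds`` passes.  Failure
    raises :class:`InsufficientCleanDataError` tagged ``artifact`` for
    the exclusion ledger.
    """
    if segs.total_clean_seconds >= minimum_seconds:
        return segs
    raise InsufficientCleanDataError(
        f"subject {segs.subject_id}: {segs.total_clean_seconds:.1f} clean "
        f"seconds < required {minimum_seconds:.1f}",
        reason="artifact",
    )


def tally_exclusions(
    screening_decisions: list[tuple[str, bool, str]],
    eeg_decisions: list[tuple[str, bool, str]],
) -> ExclusionLedger:
    """Build the exclusion ledger from per-subject stage decisions.

    ``screening_decisions`` covers every recruited subject; every
    screening-accepted subject must appear exactly once in
    ``eeg_decisions`` (and nobody else may).
    """
    accepted = {sid for sid, ok, _ in screening_decisions if ok}
    eeg_ids = [sid for sid, _, _ in eeg_decisions]
    if sorted(accepted) != sorted(eeg_ids):
        raise LedgerError(
            "EEG-stage decisions do not cover exactly the screening-"
            "accepted subjects"
        )
    excluded_screening: dict[str, int] = {}
    for _, ok, reason in screening_decisions:
        if not ok:
            excluded_screening[reason] = excluded_screening.get(reason, 0) + 1
    excluded_eeg: dict[str, int] = {}
    final_n = 0
    for _, ok, reason in eeg_decisions:
        if ok:
            final_n += 1
        else:
            excluded_eeg[reason] = excluded_eeg.get(reason, 0) + 1
    return ExclusionLedger(
        recruited=len(screening_decisions),
        excluded_screening=excluded_screening,
        completed_eeg=len(eeg_decisions),
        excluded_eeg=excluded_eeg,
        final_n=final_n,
    )
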
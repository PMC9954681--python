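"""Absolute band power per electrode from clean EEG segments.

Power spectral density is estimated with Welch's method (averaged
tapered periodograms) on the clean segments only, and absolute band
power in µV² is the integral of the PSD over each band.  The default
band scheme is delta 1-4, theta 4-8, alpha 8-12, beta 12-25 and
high-beta 25-30 Hz; bands are labelled half-open [low, high) so shared
edges belong to the band whose lower edge they equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .exceptions import ConfigError, EstimationError, RegionError
from .io_preprocess import CleanSegmentSet, EEGRecording
from .montage import REGIONS


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands, half-open [low, high)."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if low >= high:
                raise ConfigError(f"band {name}: low {low} >= high {high}")
            if low < prev_high:
                raise ConfigError(f"band {name} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def low_edge(self) -> float:
        return self.bands[0][1]

    @property
    def high_edge(self) -> float:
        return self.bands[-1][2]


DEFAULT_BANDS = BandScheme((
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 25.0),
    ("high-beta", 25.0, 30.0),
))


@dataclass
class BandPowerRecord:
    """One subject's absolute power (µV²) per (electrode, band) cell."""

    subject_id: str
    age: int
    power: dict[tuple[str, str], float]
    clean_seconds_used: float = 0.0
    sex: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        for cell, value in self.power.items():
            if value < 0:
                raise ConfigError(f"negative power at {cell}")

    def electrodes(self) -> list[str]:
        return list(dict.fromkeys(e for e, _ in self.power))

    def bands(self) -> list[str]:
        return list(dict.fromkeys(b for _, b in self.power))


def band_power(rec: EEGRecording, segs: CleanSegmentSet,
               scheme: BandScheme = DEFAULT_BANDS,
               epoch_seconds: float = 2.0,
               overlap_fraction: float = 0.5,
               taper: str = "hann",
               log10_transform: bool = False) -> BandPowerRecord:
    """Estimate absolute band power from the clean segments of a recording.

    Each clean segment is chopped into overlapping epochs of
    ``epoch_seconds``; tapered periodograms are averaged (Welch, density
    scaling, µV²/Hz) across all epochs of all usable segments, and band
    power is the trapezoidal integral of the PSD over each band.
    Segments shorter than one epoch are skipped; if no segment is
    usable, :class:`EstimationError` is raised.

    With ``log10_transform`` the returned cells are log10(power + 1e-12),
    for pipelines that prefer the log scale; the default is raw µV².
    """
    if rec.sampling_rate < 2 * scheme.high_edge:
        raise ConfigError(
            f"sampling rate {rec.sampling_rate} Hz below Nyquist for the "
            f"{scheme.high_edge} Hz band edge"
        )
    if not 0 <= overlap_fraction < 1:
        raise ConfigError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(epoch_seconds * rec.sampling_rate))
    noverlap = int(round(nperseg * overlap_fraction))
    step = nperseg - noverlap

    psd_sum = None
    freqs = None
    total_epochs = 0
    used_samples = 0
    for start, end in segs.segments:
        if end - start < nperseg:
            continue
        n_epochs = 1 + (end - start - nperseg) // step
        f, pxx = welch(rec.data[:, start:end], fs=rec.sampling_rate,
                       window=taper, nperseg=nperseg, noverlap=noverlap,
                       scaling="density")
        psd_sum = pxx * n_epochs if psd_sum is None else psd_sum + pxx * n_epochs
        freqs = f
        total_epochs += n_epochs
        used_samples += end - start
    if total_epochs == 0:
        raise EstimationError(
            f"subject {segs.subject_id}: no clean segment holds a full "
            f"{epoch_seconds}-s epoch"
        )
    psd = psd_sum / total_epochs

    power: dict[tuple[str, str], float] = {}
    for name, low, high in scheme.bands:
        mask = (freqs >= low) & (freqs <= high)
        if mask.sum() < 2:
            raise EstimationError(
                f"frequency resolution too coarse for band {name}"
            )
        band = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
        for ch, value in zip(rec.channels, band):
            power[(ch, name)] = float(np.log10(value + 1e-12)
                                      if log10_transform else value)
    return BandPowerRecord(
        subject_id=rec.subject_id,
        age=0,
        power=power,
        clean_seconds_used=used_samples / rec.sampling_rate,
    )


def total_power(rec: EEGRecording, segs: CleanSegmentSet,
                scheme: BandScheme = DEFAULT_BANDS,
                **kwargs) -> dict[str, float]:
    """Integral of the PSD over the scheme's full range, per channel."""
    wide = BandScheme((("total", scheme.low_edge, scheme.high_edge),))
    rec_total = band_power(rec, segs, scheme=wide, **kwargs)
    return {ch: rec_total.power[(ch, "total")] for ch in rec.channels}


def regional_mean(values: "BandPowerRecord | dict[tuple[str, str], float] | pd.Series",
                  regions: dict[str, tuple[str, ...]] | None = None
                  ) -> dict[tuple[str, str], float]:
    """Average per-(electrode, band) values over scalp regions.

    Accepts a :class:`BandPowerRecord`, a plain ``{(electrode, band):
    value}`` mapping, or a pandas Series with an (electrode, band)
    MultiIndex.  Returns ``{(region, band): mean}``.
    """
    if isinstance(values, BandPowerRecord):
        table = values.power
    elif isinstance(values, pd.Series):
        table = {tuple(k): v for k, v in values.items()}
    else:
        table = dict(values)
    regions = regions or REGIONS
    bands = list(dict.fromkeys(b for _, b in table))
    out: dict[tuple[str, str], float] = {}
    for region, electrodes in regions.items():
        for band in bands:
            try:
                cells = [table[(e, band)] for e in electrodes]
            except KeyError as exc:
                raise RegionError(
                    f"region {region!r} needs electrode {exc.args[0][0]!r} "
                    f"which is absent"
                ) from None
            out[(region, band)] = float(np.mean(cells))
    return out


def powers_to_frame(records: list[BandPowerRecord]) -> pd.DataFrame:
    """Tidy cohort table: subject_id, age, sex, group, electrode, band, power_uv2."""
    rows = []
    for rec in records:
        for (electrode, band), value in rec.power.items():
            rows.append({
                "subject_id": rec.subject_id, "age": rec.age,
                "sex": rec.sex, "group": rec.group,
                "electrode": electrode, "band": band, "power_uv2": value,
            })
    return pd.DataFrame(rows)


def powers_from_frame(frame: pd.DataFrame) -> list[BandPowerRecord]:
    """Inverse of :func:`powers_to_frame`."""
    records = []
    for sid, sub in frame.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        records.append(BandPowerRecord(
            subject_id=str(sid),
            age=int(first["age"]),
            sex=str(first.get("sex", "")),
            group=str(first.get("group", "")),
            power={(r.electrode, r.band): float(r.power_uv2)
                   for r in sub.itertuples()},
        ))
    return records
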
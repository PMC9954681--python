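"""The 19-channel international 10-20 montage and its regional groupings.

Everything in the pipeline is keyed by these electrode labels; the five
scalp regions are the frontal/central/parietal/temporal/occipital
groupings used for regional band-power and z-score summaries.
"""

from __future__ import annotations

from .exceptions import MontageError

#: Canonical labels of the 19-channel 10-20 montage, in conventional order.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T3", "T4", "T5", "T6",
    "Pz", "P3", "P4", "O1", "O2",
)

#: Regional electrode groupings for scalp-region summaries.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "Pz"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "occipital": ("O1", "O2"),
}

_CANONICAL = {label.upper(): label for label in CHANNELS_10_20}


def canonical_label(label: str) -> str:
    """Normalize a channel label to canonical 10-20 capitalization.

    Raises
    ------
    MontageError
        If the label (case-insensitively) is not one of the 19 montage
        channels.
    """
    key = label.strip().upper()
    # common EDF spellings such as "EEG Fp1-LE"
    if key.startswith("EEG "):
        key = key[4:]
    key = key.split("-")[0].strip()
    try:
        return _CANONICAL[key]
    except KeyError:
        raise MontageError(
            f"channel {label!r} is not in the 19-channel 10-20 montage"
        ) from None
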
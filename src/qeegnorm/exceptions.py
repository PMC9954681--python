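"""Exception hierarchy for the qeegnorm pipeline."""


class QeegError(Exception):
    """Base class for all qeegnorm errors."""


class MontageError(QeegError):
    """A channel label is not part of the 19-channel 10-20 montage."""


class ConfigError(QeegError):
    """A configuration value is invalid (sampling rate, smoother fraction, ...)."""


class InsufficientCleanDataError(QeegError):
    """A recording fails the minimum-clean-data gate.

    Carries ``reason`` so the exclusion ledger can tag the subject.
    """

    def __init__(self, message: str, reason: str = "artifact"):
        super().__init__(message)
        self.reason = reason


class LedgerError(QeegError):
    """Exclusion-ledger stage counts are inconsistent."""


class EstimationError(QeegError):
    """Spectral estimation could not produce any usable epochs."""


class RegionError(QeegError):
    """A regional aggregate references an electrode that is absent."""


class BuildError(QeegError):
    """Normative-database construction failed (e.g. an undersized age group)."""


class AgeAssignmentError(QeegError):
    """An age falls outside every group of the age-group scheme."""


class ScoringError(QeegError):
    """Z-scoring hit a degenerate cell (sigma = 0) or a missing cell."""


class DegenerateDataError(QeegError):
    """A statistic is undefined on the given data (zero variance etc.)."""


class SpecError(QeegError):
    """A synthetic-data specification is impossible."""
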
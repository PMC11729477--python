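"""Exception hierarchy for the gaitcom pipeline.

Every stage raises a subclass of :class:`GaitcomError` so that the CLI can
distinguish pipeline failures from programming errors.
"""


class GaitcomError(Exception):
    """Base class for all gaitcom errors."""


class ConfigurationError(GaitcomError):
    """Invalid simulation or run configuration."""


class DataError(GaitcomError):
    """Malformed or insufficient input data (missing markers, short series)."""


class ModelError(GaitcomError):
    """Body-model violation (wrong segment count, mass fractions off unity)."""


class FilterSpecError(GaitcomError):
    """Filter specification outside the valid range (e.g. cutoff >= Nyquist)."""


class DetectionError(GaitcomError):
    """Gait-event detection failed (no events, no periodicity)."""


class SynchronizationError(GaitcomError):
    """Cross-system event pairing produced no pairs within tolerance."""


class StatisticError(GaitcomError):
    """Degenerate statistical input (zero variance, empty pooling)."""


class DomainError(GaitcomError):
    """Query outside the valid domain (e.g. time outside the trial span)."""
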
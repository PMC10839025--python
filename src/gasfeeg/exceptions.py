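"""Exception hierarchy for the gasfeeg pipeline.

Every stage raises a dedicated subclass of :class:`GasfeegError` so callers
can distinguish configuration mistakes from degenerate data and from
pipeline-state errors.
"""


class GasfeegError(Exception):
    """Base class for all package errors."""


class SignalReadError(GasfeegError):
    """A delimited-text signal file could not be parsed."""


class ChannelIndexError(GasfeegError):
    """Requested column is absent from a signal file."""


class ConfigError(GasfeegError):
    """Invalid configuration value."""


class DegenerateSignalError(GasfeegError):
    """Signal or epoch carries no usable information (constant / zero power)."""


class VocabularyError(GasfeegError):
    """Visual vocabulary could not be built."""


class EncodingError(GasfeegError):
    """Descriptor/vocabulary mismatch while encoding a histogram."""


class ScoringError(GasfeegError):
    """Chi-square feature scoring is undefined for the given table."""


class SelectionError(GasfeegError):
    """Feature-selection request out of range."""


class SplitError(GasfeegError):
    """Train/test partition failed (e.g. a class missing from a side)."""


class TrainingError(GasfeegError):
    """Classifier training is impossible on the given table."""


class EvaluationError(GasfeegError):
    """Model and feature table are incompatible at evaluation time."""


class RocError(GasfeegError):
    """ROC curve undefined (needs at least one positive and one negative)."""


class SweepError(GasfeegError):
    """Noise sweep invoked without the required frozen artifacts."""
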
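"""Exception types raised across the package.

Every error that a pipeline stage can produce is a subclass of
:class:`NbnScreenError`, so callers (and the CLI) can catch one type.
"""


class NbnScreenError(Exception):
    """Base class for all package errors."""


class FormatError(NbnScreenError):
    """A string or file did not match the expected format."""


class VariantTableError(NbnScreenError):
    """A variant table failed validation; message carries the row number."""


class DomainError(NbnScreenError):
    """An argument lies outside its mathematical domain."""


class GatingError(NbnScreenError):
    """Flow-cytometry gating removed every event."""


class InsufficientEventsError(NbnScreenError):
    """Too few gated events to summarize a fluorescence ratio."""


class SampleError(NbnScreenError):
    """A barcode-count sample is unusable (e.g. zero total reads)."""


class PairingError(NbnScreenError):
    """A treated sample has no matching day-0 counterpart."""


class UndefinedStatisticError(NbnScreenError):
    """A statistic is undefined for the given data (zero variance, empty)."""


class ConfigError(NbnScreenError):
    """A configuration value violates its documented range."""
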
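"""Exception hierarchy shared by all pipeline stages."""


class PrepcircError(Exception):
    """Base class for all package errors."""


class SessionFormatError(PrepcircError):
    """A session directory is missing a file or a file has the wrong schema."""


class SessionValidationError(PrepcircError):
    """A session violates a structural invariant (unsorted spikes, bad ids, ...)."""


class ConfigError(PrepcircError):
    """Invalid generator or stage configuration."""


class GenerationError(PrepcircError):
    """Synthetic data could not be generated under the requested parameters."""


class InsufficientDataError(PrepcircError):
    """An operation was called with too few spikes/trials/events."""


class DegenerateUnitError(PrepcircError):
    """A unit's activity is degenerate for the requested operation (e.g. zero SD)."""


class EmptyAlignmentError(PrepcircError):
    """No event survived the alignment window restriction."""
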
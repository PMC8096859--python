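"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`BiodacError`, so callers can catch one type at the CLI boundary.
"""


class BiodacError(Exception):
    """Base class for all errors raised by biodac."""


class ConfigurationError(BiodacError, ValueError):
    """A parameter or hardware setting is outside its allowed range."""


class DomainError(BiodacError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class UnreachableTargetError(BiodacError, ValueError):
    """A requested output amplitude cannot be produced by any analog setting."""


class DegenerateInputError(BiodacError, ValueError):
    """An input signal carries no usable information (e.g. all zeros)."""


class ProtocolError(BiodacError, RuntimeError):
    """A bench protocol could not be completed on the given recording."""


class FormatError(BiodacError, ValueError):
    """A file is in an unsupported encoding or violates a format limit."""


class PlaybackError(BiodacError, RuntimeError):
    """Streaming to a playback backend failed part-way through.

    Carries the number of samples that were delivered before the failure.
    """

    def __init__(self, message: str, samples_delivered: int = 0):
        super().__init__(message)
        self.samples_delivered = samples_delivered
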
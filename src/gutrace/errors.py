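"""Exception hierarchy shared by all gutrace modules."""


class GutraceError(Exception):
    """Base class for all errors raised by gutrace."""


class FormatError(GutraceError):
    """A file could not be parsed into the expected layout."""


class AlignmentError(GutraceError):
    """Table and metadata share no samples."""


class DataError(GutraceError):
    """Input values violate a precondition of the requested computation."""


class UsageError(GutraceError):
    """The caller passed an invalid parameter (unknown rank, bad epsilon, ...)."""
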
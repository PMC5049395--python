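"""Exception hierarchy shared across the pipeline stages."""


class PoolmapError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgument(PoolmapError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleRequest(PoolmapError, ValueError):
    """The request is well-formed but cannot be satisfied by the data."""


class FormatError(PoolmapError, ValueError):
    """A file does not conform to the expected format."""


class ModelError(PoolmapError, ValueError):
    """A gene model violates its structural invariants."""


class UnsupportedEdit(PoolmapError, ValueError):
    """A transcript edit falls outside what the model supports."""
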
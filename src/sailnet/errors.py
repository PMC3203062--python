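"""Exception hierarchy.

All package-specific errors derive from :class:`SailnetError` so callers
(and the command line front end) can distinguish user-facing problems from
genuine bugs.
"""


class SailnetError(Exception):
    """Base class for all errors raised by this package."""


class ShapeError(SailnetError, ValueError):
    """Array arguments have mutually inconsistent shapes."""


class ValidationError(SailnetError, ValueError):
    """A value violates a documented invariant (non-finite, negative, ...)."""


class ConfigError(SailnetError, ValueError):
    """A configuration object or file is invalid."""


class CheckpointError(SailnetError, RuntimeError):
    """A checkpoint file is missing, corrupted, or of the wrong schema."""


class StreamExhaustedError(SailnetError, RuntimeError):
    """The stimulus stream ended before training consumed its budget."""
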
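"""Exception hierarchy for the screen pipeline.

Parse errors (exit code 2) are raised while reading inputs; stage errors
(exit code 3) while computing. ``MirscreenError`` is the common base so
callers can catch everything from this package in one clause.
"""


class MirscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(MirscreenError):
    """Invalid configuration (simulation or run parameters)."""


class InputError(MirscreenError):
    """Invalid value passed to a computation."""


class ParseError(MirscreenError):
    """Malformed input file (bad column, duplicate id, illegal character)."""


class PlateQCError(MirscreenError):
    """A plate fails quality control (too few controls, degenerate controls)."""


class StageError(MirscreenError):
    """A pipeline stage failed; message is tagged with the stage name."""
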
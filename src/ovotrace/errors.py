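"""Exception hierarchy shared across the package."""


class OvotraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OvotraceError):
    """Experiment configuration is missing, malformed, or inconsistent."""


class ValidationError(OvotraceError, ValueError):
    """A value violates a documented precondition or invariant."""


class FormatError(OvotraceError):
    """An input file does not follow the expected on-disk layout."""


class FrameReadError(FormatError):
    """A specific frame of an image sequence could not be read.

    Carries the zero-based frame index so batch logs can name the
    offending file.
    """

    def __init__(self, frame_index: int, message: str = ""):
        self.frame_index = frame_index
        super().__init__(message or f"frame {frame_index} could not be read")


class EggNotFoundError(OvotraceError):
    """No candidate egg region rose above background in a sequence."""


class MigrationError(OvotraceError):
    """A stored dataset was written with an incompatible layout version."""
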
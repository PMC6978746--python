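"""Exception hierarchy for the pipeline."""


class GestureError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GestureError):
    """Inconsistent configuration, e.g. channel-count mismatch."""


class DegenerateSignalError(GestureError):
    """An operation is undefined on the given signal (e.g. all-zero after
    offset removal, so normalization has no scale)."""


class TrainingError(GestureError):
    """A classifier cannot be trained on the given database."""


class MissingClassError(TrainingError):
    """A calibration recording does not contain every expected gesture class."""


class ParseError(GestureError):
    """A file does not conform to the expected on-disk format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
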
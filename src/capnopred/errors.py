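"""Exception hierarchy shared across the package."""


class CapnopredError(Exception):
    """Base class for all package-specific errors."""


class ExtractionError(CapnopredError):
    """Capnogram phase segmentation or line fitting failed.

    Carries ``window`` describing the fitting window that could not be
    populated, so callers can tell which phase was degenerate.
    """

    def __init__(self, message: str, window: str | None = None):
        super().__init__(message)
        self.window = window


class PreprocessingError(CapnopredError):
    """Raw CO2 sequence could not be prepared for the network."""


class TrainingDivergedError(CapnopredError):
    """Network training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


class NotFittedError(CapnopredError):
    """A model was used before being trained."""


class SchemaError(CapnopredError):
    """A CSV input did not match the expected column schema."""
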
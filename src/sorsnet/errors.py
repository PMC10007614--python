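"""Exception hierarchy shared across the pipeline stages."""


class SorsnetError(Exception):
    """Base class for all package errors."""


class ConfigError(SorsnetError, ValueError):
    """A configuration value violates its contract."""


class InputError(SorsnetError, ValueError):
    """An input array or label violates a precondition."""


class ROIError(SorsnetError, ValueError):
    """The laser point sits too close to the scan edge for the requested ROI."""


class SampleRejectionError(SorsnetError, ValueError):
    """Every spatial position of a sample was flagged anomalous."""


class SchemaError(SorsnetError, ValueError):
    """A container file is missing a required array or attribute."""


class TrainingError(SorsnetError, RuntimeError):
    """Optimization diverged (non-finite loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class StateError(SorsnetError, RuntimeError):
    """An operation requires a trained/fitted object."""
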
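"""Exception hierarchy shared by all pipeline stages."""


class ThetaScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ThetaScreenError):
    """An input file does not match the expected tabular contract."""


class ConfigError(ThetaScreenError):
    """A configuration value is missing, malformed or inconsistent."""


class LayoutError(ThetaScreenError):
    """A plate map is invalid or does not cover the feature data."""


class UnknownReferenceError(ThetaScreenError):
    """A configuration entry names a compound or cell line that does not exist."""


class PipelineError(ThetaScreenError):
    """A computation stage cannot proceed (degenerate or insufficient data)."""


class StageError(ThetaScreenError):
    """Wraps any stage failure in the end-to-end workflow.

    Attributes
    ----------
    stage : str
        Name of the failing stage.
    code : str
        Machine-readable error code (class name of the underlying error).
    """

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.code = type(cause).__name__
        super().__init__(f"stage '{stage}' failed [{self.code}]: {cause}")
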
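"""Exception hierarchy used across the package."""


class SLSKitError(Exception):
    """Base class for all package-specific errors."""


class SegmentationError(SLSKitError):
    """A trajectory cannot be split into down/up phases."""


class NoTurningPointError(SegmentationError):
    """The vertical series is monotone; there is no squat bottom."""


class UndefinedAngleError(SLSKitError):
    """A trajectory angle cannot be computed (e.g. zero vertical excursion)."""


class DegenerateDataError(SLSKitError):
    """A statistic is undefined on the supplied data."""


class ParseError(SLSKitError):
    """A data file does not match the expected schema."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            ctx += f":{line}]" if line is not None else "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class PipelineError(SLSKitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
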
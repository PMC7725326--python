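"""Exception types shared across the package."""


class PathTraceError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PathTraceError):
    """Malformed Newick input; carries the offending position when known."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class FormatError(PathTraceError):
    """Malformed tabular or XML input file."""


class ParameterError(PathTraceError):
    """Invalid parameter value (e.g. non-positive alpha or e-value cutoff)."""


class MissingDataError(PathTraceError):
    """Referenced identifiers absent from the supplied data."""


class PipelineError(PathTraceError):
    """A pipeline stage failed; message names the stage and the cause."""
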
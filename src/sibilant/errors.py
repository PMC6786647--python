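"""Package exception types."""


class ParameterError(ValueError):
    """A physical or schedule parameter is outside its valid range."""


class GeometryError(ValueError):
    """Duct/constriction geometry is inconsistent (e.g. R_min > R_p)."""


class FlowRecordError(ValueError):
    """A flow/velocity text record could not be parsed.

    Carries the 1-based line number of the offending row when applicable.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
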
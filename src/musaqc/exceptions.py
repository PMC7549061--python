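"""Exception types shared across the pipeline stages."""


class InvalidParameterError(ValueError):
    """A simulation or analysis parameter is outside its admissible range."""


class MalformedInputError(ValueError):
    """Input records violate a structural precondition (ordering, format)."""


class VcfParseError(MalformedInputError):
    """A VCF line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ConsistencyError(ValueError):
    """Two inputs that must describe the same sites disagree."""


class InsufficientSitesError(ValueError):
    """Too few sites remain for a statistical fit to be meaningful."""
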
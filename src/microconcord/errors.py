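"""Exception hierarchy shared across the package."""


class MicroconcordError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicroconcordError, ValueError):
    """An input file violates its declared format or an invariant."""


class ParameterError(MicroconcordError, ValueError):
    """A function argument is outside its valid domain."""


class DataError(MicroconcordError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""
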
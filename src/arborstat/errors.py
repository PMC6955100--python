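"""Exception hierarchy shared across the package."""


class ArborstatError(Exception):
    """Base class for all package-specific errors."""


class StructureError(ArborstatError):
    """A neuron tree violates its structural invariants (cycles, multiple
    roots, dangling parents, disconnected components)."""


class ParseError(ArborstatError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MetadataError(ArborstatError):
    """Specimen metadata missing, malformed, or outside the controlled
    vocabulary."""


class ConfigurationError(ArborstatError):
    """Invalid analysis / sampling / generator configuration."""


class SampleSizeError(ArborstatError):
    """A statistical operation received fewer observations than it needs."""
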
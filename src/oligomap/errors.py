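"""Exception hierarchy shared across the package."""


class OligoMapError(Exception):
    """Base class for all errors raised by oligomap."""


class ConfigError(OligoMapError):
    """A configuration problem: missing column, bad prefix map, bad option."""


class ValidationError(OligoMapError):
    """Input data violates an invariant (bad sequence, inconsistent table)."""


class ParseError(OligoMapError):
    """A file could not be parsed in its declared format."""


class MalformedHitError(OligoMapError):
    """An alignment hit has internally inconsistent coordinates."""


class CoordinateError(OligoMapError):
    """A derived genomic coordinate falls outside the sequence (position < 1)."""


class DuplicateIDError(OligoMapError):
    """Identifiers collide where uniqueness is required."""


class GenerationError(OligoMapError):
    """The synthetic-fixture generator could not satisfy its constraints."""
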
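"""Exception hierarchy for omicslink."""


class OmicsLinkError(Exception):
    """Base class for all omicslink errors."""


class ConfigError(OmicsLinkError, ValueError):
    """Invalid or internally inconsistent configuration."""


class BlastParseError(OmicsLinkError, ValueError):
    """Malformed BLAST tabular input (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class IntegrityError(OmicsLinkError, ValueError):
    """Referential-integrity violation between tables (unknown IDs, inconsistent counts)."""


class DomainError(OmicsLinkError, ValueError):
    """Value outside the mathematical domain of an operation."""
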
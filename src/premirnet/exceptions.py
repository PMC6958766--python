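"""Exception hierarchy shared across the package."""


class PremirnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PremirnetError):
    """A file could not be parsed (malformed FASTA, table, tool output)."""


class ValidationError(PremirnetError):
    """Input violates a domain invariant (alphabet, lengths, balance...)."""


class ConfigurationError(PremirnetError):
    """A required external dependency or configuration item is missing."""


class TrainingDivergedError(PremirnetError):
    """Optimization produced a non-finite loss."""
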
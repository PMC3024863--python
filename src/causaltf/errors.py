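"""Exception hierarchy shared across the package."""


class CausalTFError(Exception):
    """Base class for all package errors."""


class ParseError(CausalTFError):
    """A malformed input file (bad column count, empty identifier, ...)."""


class ConfigurationError(CausalTFError):
    """Inconsistent options, e.g. a score threshold without a score column."""


class ValidationError(CausalTFError):
    """Input data violating a structural contract."""


class UnknownIdentifierError(CausalTFError, KeyError):
    """Lookup of an identifier the network has never seen."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class StatisticalError(CausalTFError):
    """A statistical procedure called with too little data."""


class UndefinedScoreError(CausalTFError):
    """A score whose denominator is empty (0/0)."""
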